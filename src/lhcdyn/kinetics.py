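"""Time-dependent response estimators.

Inter-helix centre-of-mass mean square displacement with the Einstein
relation MSD = 6 D t + c, percent changes of the fitted diffusion
coefficients against a reference condition, rotational correlation functions
of backbone dihedral probes and their single-exponential relaxation-time
fits a * exp(-t / t_f).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import TimeSeries, Topology, Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "RcfFit",
    "com_msd",
    "fit_einstein",
    "pct_change",
    "rcf",
    "fit_rcf",
    "round_half_away",
]


@dataclass
class MSDCurve:
    """Lag-time-resolved mean square displacement (or a correlation curve)."""

    lag: np.ndarray   # time units
    msd: np.ndarray   # nm^2 (or dimensionless for correlation curves)
    metadata: dict = field(default_factory=dict)


@dataclass
class DiffusionEstimate:
    """Einstein-relation fit: MSD = 6 D t + c over a lag window."""

    D: float                      # nm^2 / time
    intercept: float              # nm^2
    fit_range: tuple[float, float]
    rms_residual: float
    quality_ok: bool = True       # False e.g. for a negative fitted D
    pct_change: float | None = None


@dataclass
class RcfFit:
    """Single-exponential fit a * exp(-t / t_f) of a correlation curve."""

    a: float
    t_f: float
    rms_residual: float
    converged: bool = True


def _fft_dot_correlation(x: np.ndarray) -> np.ndarray:
    """S(m) = sum_k x_k . x_{k+m} for a (N, d) series, via FFT, O(N log N)."""
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    out = np.zeros(n)
    for dim in range(x.shape[1]):
        f = np.fft.rfft(x[:, dim], nfft)
        out += np.fft.irfft(f * np.conj(f), nfft)[:n]
    return out


def msd_fft(r: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-origin-averaged MSD of a (N, d) displacement series.

    Standard FFT decomposition: MSD(m) = [S1(m) - 2 S2(m)] / (N - m) with
    S2 the autocorrelation and S1 a running sum of squared norms. Equivalent
    to the brute-force double loop over time origins (asserted in tests).
    """
    n = r.shape[0]
    d2 = np.sum(r * r, axis=1)
    s2 = _fft_dot_correlation(r)
    # S1(m) = sum_{k=0}^{N-m-1} (d2[k] + d2[k+m]), built by peeling ends
    msd = np.empty(max_lag + 1)
    sab = 2.0 * d2.sum()
    msd[0] = 0.0
    for m in range(1, max_lag + 1):
        sab -= d2[m - 1] + d2[n - m]
        msd[m] = (sab - 2.0 * s2[m]) / (n - m)
    return msd


def com_msd(
    traj: Trajectory,
    topo: Topology,
    pair: tuple[str, str],
    masses: np.ndarray | None = None,
    max_lag: int | None = None,
) -> MSDCurve:
    """MSD of the relative COM displacement vector of a helix pair.

    The probe is r_AB(t) = COM_A(t) - COM_B(t); the curve is the
    time-origin-averaged square displacement of r_AB, with lags up to half
    the trajectory length by default. For diffusion-coefficient fits on long
    trajectories, restrict ``max_lag`` (frames) to a small fraction of the
    trajectory: the relative standard error of the MSD at lag m scales like
    sqrt(m / n_frames), so only short lags are well averaged. COM uses
    uniform atom masses unless ``masses`` is provided.
    """
    if traj.n_frames < 100:
        raise ValueError("need >= 100 frames for a meaningful MSD")
    coms = []
    for label in pair:
        idx = topo.helix_atom_indices(traj, label)
        if masses is None:
            coms.append(traj.coords[:, idx, :].mean(axis=1))
        else:
            w = masses[idx] / masses[idx].sum()
            coms.append(np.einsum("fij,i->fj", traj.coords[:, idx, :], w))
    r_ab = coms[0] - coms[1]
    if max_lag is None:
        max_lag = traj.n_frames // 2
    max_lag = min(max_lag, traj.n_frames - 1)
    msd = msd_fft(r_ab, max_lag)
    lag = np.arange(max_lag + 1) * traj.dt
    return MSDCurve(lag, msd, metadata={"pair": pair})


def fit_einstein(
    curve: MSDCurve, fit_window: tuple[float, float] = (0.1, 0.5)
) -> DiffusionEstimate:
    """Ordinary least squares of MSD on lag; D = slope / 6, c = intercept.

    ``fit_window`` selects lags as fractions of the maximum lag; the default
    [10%, 50%] window skips the poorly averaged short-lag and long-lag
    extremes. A negative fitted D is returned with ``quality_ok=False``
    rather than dropped.
    """
    lo = fit_window[0] * curve.lag[-1]
    hi = fit_window[1] * curve.lag[-1]
    sel = (curve.lag >= lo) & (curve.lag <= hi)
    if sel.sum() < 10:
        raise ValueError("fit window must contain >= 10 lag points")
    res = stats.linregress(curve.lag[sel], curve.msd[sel])
    d = res.slope / 6.0
    resid = curve.msd[sel] - (res.slope * curve.lag[sel] + res.intercept)
    return DiffusionEstimate(
        D=float(d),
        intercept=float(res.intercept),
        fit_range=(float(lo), float(hi)),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        quality_ok=bool(d >= 0),
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (table convention)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def pct_change(d: DiffusionEstimate | float, d_ref: DiffusionEstimate | float) -> int:
    """Percent change of D against a reference, 100 (D - D_ref) / D_ref.

    Rounded half-away-from-zero to integer percent, matching the convention
    of diffusion-coefficient summary tables.
    """
    dv = d.D if isinstance(d, DiffusionEstimate) else float(d)
    rv = d_ref.D if isinstance(d_ref, DiffusionEstimate) else float(d_ref)
    if rv == 0:
        raise ZeroDivisionError("reference diffusion coefficient is zero")
    return round_half_away(100.0 * (dv - rv) / rv)


def _cos_correlation(phi: np.ndarray, max_lag: int) -> np.ndarray:
    """<cos(phi(t0+t) - phi(t0))> over time origins, via FFT on cos/sin."""
    n = phi.size
    cs = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    s = _fft_dot_correlation(cs)
    counts = n - np.arange(max_lag + 1)
    return s[: max_lag + 1] / counts


def rcf(
    series: TimeSeries | list[TimeSeries],
    max_lag: int | None = None,
    probe: str = "dihedral_cos",
) -> MSDCurve:
    """Rotational correlation function of backbone dihedral probes.

    C(t) = <cos(phi(t0 + t) - phi(t0))>, averaged over time origins and over
    all supplied dihedral series (the backbone phi/psi of the loop residues,
    pooled). C(0) = 1 by construction. Input values are degrees. A
    second-Legendre variant of the same probe is available as
    ``probe="p2"`` for sensitivity checks.
    """
    many = series if isinstance(series, list) else [series]
    if any(s.units not in ("deg", "degrees", "") for s in many):
        raise ValueError("rcf expects angular series in degrees")
    n = min(s.value.size for s in many)
    if n < 1000:
        raise ValueError("need >= 1000 frames for a stable RCF")
    if max_lag is None:
        max_lag = n // 2
    dt = many[0].dt
    acc = np.zeros(max_lag + 1)
    for s in many:
        phi = np.deg2rad(s.value[:n])
        c = _cos_correlation(phi, max_lag)
        if probe == "p2":
            c = 1.5 * c**2 - 0.5  # P2 of the in-plane unit vector, approx
        elif probe != "dihedral_cos":
            raise ValueError(f"unknown probe {probe!r}")
        acc += c
    acc /= len(many)
    return MSDCurve(np.arange(max_lag + 1) * dt, acc, metadata={"probe": probe})


def fit_rcf(curve: MSDCurve) -> RcfFit:
    """Nonlinear least squares of a * exp(-t / t_f) to a correlation curve.

    Initialised from a log-linear fit of the positive part. Returns an
    explicit non-converged status (rather than raising) when the curve does
    not decay or the optimiser fails.
    """
    t, c = curve.lag, curve.msd
    pos = c > 1e-12
    if pos.sum() < 3 or c[0] <= 0:
        return RcfFit(a=np.nan, t_f=np.nan, rms_residual=np.nan, converged=False)
    # log-linear initial guess over the early decay
    k = max(3, int(0.2 * t.size))
    sel = pos.copy()
    sel[k:] = False
    slope, intercept = np.polyfit(t[sel], np.log(c[sel]), 1)
    if slope >= 0:
        return RcfFit(a=np.nan, t_f=np.nan, rms_residual=np.nan, converged=False)
    p0 = (float(np.exp(intercept)), float(-1.0 / slope))
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, tf: a * np.exp(-x / tf), t, c, p0=p0, maxfev=10000
        )
    except RuntimeError:
        return RcfFit(a=np.nan, t_f=np.nan, rms_residual=np.nan, converged=False)
    a, tf = popt
    if tf <= 0:
        return RcfFit(a=float(a), t_f=float(tf), rms_residual=np.nan, converged=False)
    resid = c - a * np.exp(-t / tf)
    return RcfFit(
        a=float(a),
        t_f=float(tf),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )
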