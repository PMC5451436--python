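"""Group-group nonbonded interaction energies and their autocorrelation.

Per-frame Coulomb + Lennard-Jones cross energies between two named atom
groups (e.g. the chlorophyll pair adjacent to helix D against a carotenoid),
their normalized fluctuation autocorrelation C(t), and a slow-to-fast ranking
of relaxation curves by integrated correlation time. No periodic boundary
conditions and no cutoff by default: the synthetic boxes are small and
aperiodic. A plain distance cutoff is available for parity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology, TopologyError, Trajectory
from .kinetics import _fft_dot_correlation

__all__ = [
    "COULOMB_CONSTANT",
    "EnergySeries",
    "AcfCurve",
    "SingularGeometryError",
    "pair_energy",
    "energy_acf",
    "average_acf",
    "compare_relaxation",
]

#: k_e = 1/(4 pi eps0) in kJ mol^-1 nm e^-2 (the MD convention).
COULOMB_CONSTANT = 138.935458

#: Pair distances below this (nm) are treated as overlapping atoms.
MIN_DISTANCE_NM = 1e-4


class SingularGeometryError(ValueError):
    """Raised when two interacting atoms (nearly) overlap."""


@dataclass
class EnergySeries:
    """Per-frame interaction energy decomposition, kJ/mol."""

    t: np.ndarray
    e_coul: np.ndarray
    e_lj: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def e_total(self) -> np.ndarray:
        return self.e_coul + self.e_lj

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class AcfCurve:
    """Normalized fluctuation autocorrelation, c(0) = 1."""

    lag: np.ndarray
    c: np.ndarray
    metadata: dict = field(default_factory=dict)

    def integrated_time(self) -> tuple[float, bool]:
        """Integrated correlation time, rectangle rule up to the first zero
        crossing; falls back to the full range (flagged) if c never crosses 0.
        """
        dt = float(self.lag[1] - self.lag[0]) if self.lag.size > 1 else 1.0
        neg = np.nonzero(self.c <= 0)[0]
        end = int(neg[0]) if neg.size else self.c.size
        crossed = bool(neg.size)
        return float(np.sum(self.c[:end]) * dt), crossed


def pair_energy(
    traj: Trajectory,
    topo: Topology,
    group_a: str,
    group_b: str,
    cutoff: float | None = None,
) -> EnergySeries:
    """Coulomb + LJ cross-interaction energy of two atom groups per frame.

    E_coul = k_e sum q_i q_j / r_ij and
    E_lj = sum 4 eps_ij [(sig_ij/r_ij)^12 - (sig_ij/r_ij)^6] over all
    cross-pairs, with Lorentz-Berthelot combination (arithmetic sigma,
    geometric epsilon). ``cutoff`` (nm) zeroes pair contributions beyond the
    given distance when set.
    """
    for name in (group_a, group_b):
        if name not in topo.groups:
            raise TopologyError(f"group {name!r} not defined in topology")
    ia, ib = topo.groups[group_a], topo.groups[group_b]
    if np.intersect1d(ia, ib).size:
        raise TopologyError(f"groups {group_a!r} and {group_b!r} overlap")
    if topo.charges is None or topo.lj_sigma is None or topo.lj_epsilon is None:
        raise TopologyError("charges and LJ parameters must be bound for pair_energy")
    topo.bind(traj)

    q = topo.charges
    qq = COULOMB_CONSTANT * np.outer(q[ia], q[ib])
    sig = 0.5 * (topo.lj_sigma[ia][:, None] + topo.lj_sigma[ib][None, :])
    eps = np.sqrt(topo.lj_epsilon[ia][:, None] * topo.lj_epsilon[ib][None, :])

    xa = traj.coords[:, ia, :]
    xb = traj.coords[:, ib, :]
    diff = xa[:, :, None, :] - xb[:, None, :, :]
    r = np.linalg.norm(diff, axis=3)
    if np.any(r < MIN_DISTANCE_NM):
        f, i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise SingularGeometryError(
            f"atoms {ia[i]} and {ib[j]} overlap (r = {r[f, i, j]:.2e} nm) "
            f"in frame {f}"
        )
    mask = np.ones_like(r, dtype=bool) if cutoff is None else (r <= cutoff)
    sr6 = (sig[None] / r) ** 6
    e_c = np.sum(np.where(mask, qq[None] / r, 0.0), axis=(1, 2))
    e_l = np.sum(np.where(mask, 4.0 * eps[None] * (sr6 * sr6 - sr6), 0.0), axis=(1, 2))
    return EnergySeries(
        t=traj.times,
        e_coul=e_c,
        e_lj=e_l,
        metadata={"groups": (group_a, group_b), "cutoff": cutoff},
    )


def energy_acf(
    series: EnergySeries | np.ndarray,
    dt: float | None = None,
    component: str = "total",
    max_lag: int | None = None,
    min_frames: int = 1000,
) -> AcfCurve:
    """Normalized autocorrelation of the interaction-energy fluctuations.

    C(t) = <dE(t0) dE(t0+t)> / <dE^2> with dE = E - mean(E), averaged over
    time origins. ``component`` selects total (default), coul or lj.
    """
    if isinstance(series, EnergySeries):
        e = {"total": series.e_total, "coul": series.e_coul, "lj": series.e_lj}[component]
        dt = series.dt
    else:
        e = np.asarray(series, dtype=float)
        if dt is None:
            dt = 1.0
    n = e.size
    if n < min_frames:
        raise ValueError(f"need >= {min_frames} frames for a stable ACF")
    de = e - e.mean()
    if np.allclose(de, 0):
        raise ValueError("zero-variance series: ACF undefined")
    if max_lag is None:
        max_lag = n // 2
    s = _fft_dot_correlation(de[:, None])
    counts = n - np.arange(max_lag + 1)
    c = s[: max_lag + 1] / counts
    c /= c[0]
    return AcfCurve(np.arange(max_lag + 1) * dt, c, metadata={"component": component})


def average_acf(curves: list[AcfCurve]) -> AcfCurve:
    """Mean of per-replicate normalized ACFs on a common lag grid.

    Replicates are averaged after normalization (never the ACF of the
    concatenated series, which would correlate across replicate boundaries).
    """
    n = min(c.lag.size for c in curves)
    lag = curves[0].lag[:n]
    for c in curves[1:]:
        if not np.allclose(c.lag[:n], lag):
            raise ValueError("ACF curves must share a common lag grid")
    mean = np.mean([c.c[:n] for c in curves], axis=0)
    return AcfCurve(lag, mean, metadata={"n_replicates": len(curves)})


def compare_relaxation(curves: list[AcfCurve]) -> list[dict]:
    """Rank relaxation curves slow -> fast by integrated correlation time.

    tau_int = sum C(t) dt up to the first zero crossing. A slower decay
    (larger tau_int) reads as closer packing of the interacting groups.
    Returns one record per curve with its rank (ties share a rank and are
    flagged).
    """
    if len(curves) < 2:
        raise ValueError("need >= 2 curves to compare")
    taus = [c.integrated_time() for c in curves]
    order = np.argsort([-t for t, _ in taus], kind="stable")
    records = []
    ranks = np.empty(len(curves), dtype=int)
    rank = 0
    prev_tau = None
    for pos, idx in enumerate(order):
        tau = taus[idx][0]
        if prev_tau is None or not np.isclose(tau, prev_tau):
            rank = pos
        ranks[idx] = rank
        prev_tau = tau
    for i, (tau, crossed) in enumerate(taus):
        records.append(
            {
                "index": i,
                "tau_int": tau,
                "rank": int(ranks[i]),
                "zero_crossing_found": crossed,
                "tied": int(np.sum(ranks == ranks[i])) > 1,
            }
        )
    return sorted(records, key=lambda r: r["rank"])
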