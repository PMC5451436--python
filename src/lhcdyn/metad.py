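"""Well-tempered metadynamics over a single collective variable (CV).

An overdamped (Euler-Maruyama) Langevin integrator propagates the CV on an
analytic potential U(s) plus a history-dependent bias V(s, t) built from
Gaussian hills. Hills are deposited every ``pace`` steps with the
well-tempered height schedule

    w_k = w0 * exp(-V(s_k, t_k) / (k_B * dT)),   dT = (gamma - 1) * T,

so revisited regions receive ever-smaller hills and the bias converges to
-(1 - 1/gamma) F(s). The free energy is reconstructed from the hills log as
F(s) = -(gamma / (gamma - 1)) V(s, t_end), anchored to min 0. A two-window
mean-free-energy difference dE(t) between named CV ranges serves as the
convergence diagnostic.

For speed the running bias is cached on a fine grid (each hill is added to
the grid once; per-step lookups are O(1) linear interpolation); tests assert
the cache agrees with direct summation over hills.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import KB_KJ_PER_MOL_K, TimeSeries
from .synthetic import PotentialSpec

__all__ = [
    "MetadConfig",
    "HillsLog",
    "FreeEnergyProfile",
    "IntegratorInstabilityError",
    "run_wtmetad",
    "bias_potential",
    "reconstruct_fes",
    "delta_e_convergence",
    "write_hills",
    "read_hills",
]


class IntegratorInstabilityError(RuntimeError):
    """Raised when a single step moves the CV further than domain/10."""


@dataclass
class MetadConfig:
    """Well-tempered metadynamics and Langevin-integrator parameters.

    Defaults follow common practice for a soft, nm-scale CV: modest initial
    hills (1.2 kJ/mol), width about the thermal CV fluctuation (0.05 nm),
    bias factor 10 for barriers of a few k_B T, deposition every 500 steps.
    ``friction`` is the inverse CV mobility (kJ/mol time nm^-2); the free
    diffusion coefficient of the CV is k_B T / friction.
    """

    temperature: float = 310.0      # K
    bias_factor: float = 10.0       # gamma, dimensionless > 1
    hill_height: float = 1.2        # w0, kJ/mol
    hill_width: float = 0.05        # sigma_G, nm
    pace: int = 500                 # steps between depositions
    dt: float = 5e-5                # time units per step
    friction: float = 1.0           # kJ/mol time / nm^2
    n_steps: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1")
        if self.hill_height < 0 or self.hill_width <= 0:
            raise ValueError("hill height must be >= 0 (0 = unbiased Langevin) "
                             "and width > 0")
        if self.dt <= 0 or self.pace < 1 or self.n_steps < 1:
            raise ValueError("dt, pace and n_steps must be positive")

    @property
    def kt(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature

    @property
    def delta_t(self) -> float:
        """Well-tempered fictitious temperature boost (gamma - 1) T, in K."""
        return (self.bias_factor - 1.0) * self.temperature


@dataclass
class HillsLog:
    """Deposited Gaussians: time, CV center, width and (decayed) height."""

    time: np.ndarray
    center: np.ndarray
    width: np.ndarray
    height: np.ndarray

    def __len__(self) -> int:
        return self.time.size

    def upto(self, t: float) -> "HillsLog":
        sel = self.time <= t
        return HillsLog(self.time[sel], self.center[sel], self.width[sel], self.height[sel])


@dataclass
class FreeEnergyProfile:
    """Free energy vs the CV, anchored to min(F) = 0."""

    s: np.ndarray
    f: np.ndarray
    convergence: TimeSeries | None = None
    metadata: dict = field(default_factory=dict)

    def barrier(self) -> float:
        """max(F) - min(F) between the two outermost local minima."""
        f = self.f
        mins = [
            i
            for i in range(1, f.size - 1)
            if f[i] <= f[i - 1] and f[i] <= f[i + 1]
        ]
        if len(mins) < 2:
            return float(f.max() - f.min())
        lo, hi = mins[0], mins[-1]
        inner = f[lo : hi + 1]
        return float(inner.max() - min(f[lo], f[hi]))


def bias_potential(hills: HillsLog, s: np.ndarray) -> np.ndarray:
    """Direct summation of the logged hills on arbitrary CV points."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    v = np.zeros_like(s)
    for c, w, h in zip(hills.center, hills.width, hills.height):
        v += h * np.exp(-((s - c) ** 2) / (2.0 * w * w))
    return v


def run_wtmetad(
    potential: PotentialSpec,
    cfg: MetadConfig,
    s0: float | None = None,
    cv_stride: int = 100,
) -> tuple[TimeSeries, HillsLog]:
    """Propagate the CV under U(s) + V_bias(s, t) and log every hill.

    Overdamped Langevin step: ds = (F_pot + F_bias)/friction dt
    + sqrt(2 k_B T dt / friction) xi. Reflective walls at the potential's
    domain edges keep the (physically bounded) CV inside. With
    ``hill_height`` -> 0 this reduces to plain Langevin sampling of
    exp(-U / k_B T). The CV series is subsampled every ``cv_stride`` steps.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = potential.domain
    span = hi - lo
    mob = 1.0 / cfg.friction
    noise_sigma = np.sqrt(2.0 * cfg.kt * cfg.dt * mob)
    kb_dt = KB_KJ_PER_MOL_K * cfg.delta_t

    # bias cache on a fine grid (~sigma_G/10 spacing)
    n_grid = max(64, int(np.ceil(span / (cfg.hill_width / 10.0))) + 1)
    grid = np.linspace(lo, hi, n_grid)
    dg = grid[1] - grid[0]
    v_grid = np.zeros(n_grid)
    f_grid = np.zeros(n_grid)  # bias force -dV/ds on the grid

    s = 0.5 * (potential.minima[0] + potential.minima[1]) if s0 is None else float(s0)
    s = min(max(s, lo), hi)
    max_step = span / 10.0

    deposit = cfg.hill_height > 0
    n_hills = cfg.n_steps // cfg.pace if deposit else 0
    h_time = np.empty(n_hills)
    h_center = np.empty(n_hills)
    h_height = np.empty(n_hills)
    k_hill = 0

    n_cv = cfg.n_steps // cv_stride
    cv = np.empty(n_cv)
    noise = rng.normal(0.0, noise_sigma, size=cfg.n_steps)

    for step in range(cfg.n_steps):
        # linear interpolation of the cached bias force
        g = (s - lo) / dg
        i = int(g)
        if i >= n_grid - 1:
            i = n_grid - 2
        frac = g - i
        fb = f_grid[i] * (1.0 - frac) + f_grid[i + 1] * frac
        ds = mob * (potential.force(s) + fb) * cfg.dt + noise[step]
        if abs(ds) > max_step:
            raise IntegratorInstabilityError(
                f"step {step}: |ds| = {abs(ds):.3g} nm exceeds domain/10 = "
                f"{max_step:.3g} nm; reduce dt"
            )
        s += ds
        # reflective walls
        if s < lo:
            s = 2.0 * lo - s
        elif s > hi:
            s = 2.0 * hi - s

        if deposit and (step + 1) % cfg.pace == 0 and k_hill < n_hills:
            g = (s - lo) / dg
            i = int(g)
            if i >= n_grid - 1:
                i = n_grid - 2
            frac = g - i
            v_here = v_grid[i] * (1.0 - frac) + v_grid[i + 1] * frac
            h = cfg.hill_height * np.exp(-v_here / kb_dt)
            arg = (grid - s) / cfg.hill_width
            gauss = h * np.exp(-0.5 * arg * arg)
            v_grid += gauss
            # bias force -dV/ds of the new hill on the grid
            f_grid += gauss * (grid - s) / (cfg.hill_width**2)
            h_time[k_hill] = (step + 1) * cfg.dt
            h_center[k_hill] = s
            h_height[k_hill] = h
            k_hill += 1

        if (step + 1) % cv_stride == 0:
            cv[(step + 1) // cv_stride - 1] = s

    hills = HillsLog(
        time=h_time[:k_hill],
        center=h_center[:k_hill],
        width=np.full(k_hill, cfg.hill_width),
        height=h_height[:k_hill],
    )
    cv_series = TimeSeries(
        t=(np.arange(n_cv) + 1) * cv_stride * cfg.dt,
        value=cv,
        units="nm",
        metadata={"cv_stride": cv_stride, "seed": cfg.seed},
    )
    return cv_series, hills


def reconstruct_fes(
    hills: HillsLog,
    cfg: MetadConfig,
    grid: np.ndarray,
) -> FreeEnergyProfile:
    """Free energy from a hills log: F = -(gamma/(gamma-1)) V_bias, min 0."""
    if len(hills) == 0:
        raise ValueError("empty hills log: nothing to reconstruct")
    grid = np.asarray(grid, dtype=float)
    scale = cfg.bias_factor / (cfg.bias_factor - 1.0)
    f = -scale * bias_potential(hills, grid)
    f -= f.min()
    return FreeEnergyProfile(grid, f, metadata={"n_hills": len(hills)})


def delta_e_convergence(
    hills: HillsLog,
    cfg: MetadConfig,
    window_a: tuple[float, float],
    window_b: tuple[float, float],
    checkpoints: np.ndarray,
    grid: np.ndarray,
) -> TimeSeries:
    """dE(t) = mean F over window_a - mean F over window_b vs run time.

    At every checkpoint the free energy is reconstructed from the hills
    deposited so far. A checkpoint is undefined (NaN, listed in metadata)
    while a window has not yet been visited by any hill — the bias carries no
    information there.
    """
    grid = np.asarray(grid, dtype=float)
    a_lo, a_hi = window_a
    b_lo, b_hi = window_b
    if a_hi <= a_lo or b_hi <= b_lo:
        raise ValueError("windows must be non-empty ranges")
    if min(a_lo, b_lo) < grid.min() or max(a_hi, b_hi) > grid.max() or (
        a_lo < b_hi and b_lo < a_hi
    ):
        raise ValueError("windows must be disjoint and inside the grid")
    sel_a = (grid >= a_lo) & (grid <= a_hi)
    sel_b = (grid >= b_lo) & (grid <= b_hi)
    if not sel_a.any() or not sel_b.any():
        raise ValueError("windows must contain grid points")

    scale = cfg.bias_factor / (cfg.bias_factor - 1.0)
    values = np.full(len(checkpoints), np.nan)
    undefined = []
    for k, t in enumerate(checkpoints):
        part = hills.upto(float(t))
        visited_a = np.any((part.center >= a_lo) & (part.center <= a_hi))
        visited_b = np.any((part.center >= b_lo) & (part.center <= b_hi))
        if len(part) == 0 or not (visited_a and visited_b):
            undefined.append(float(t))
            continue
        f = -scale * bias_potential(part, grid)
        f -= f.min()
        values[k] = f[sel_a].mean() - f[sel_b].mean()
    return TimeSeries(
        t=np.asarray(checkpoints, dtype=float),
        value=values,
        units="kJ/mol",
        metadata={"window_a": window_a, "window_b": window_b, "undefined_at": undefined},
    )


def write_hills(hills: HillsLog, path) -> None:
    """HILLS-style whitespace log: time, center, width, height."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time center sigma height\n")
        for row in zip(hills.time, hills.center, hills.width, hills.height):
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_hills(path) -> HillsLog:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        return HillsLog(*(np.empty(0),) * 4)
    return HillsLog(data[:, 0], data[:, 1], data[:, 2], data[:, 3])
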