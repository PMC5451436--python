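"""Synthetic ground-truth generators for every input the pipeline consumes.

Real antenna-protein trajectories are produced by large membrane MD setups
that are far outside desk scale. Each generator here emulates one statistical
feature of those systems with *known* parameters, so every downstream
estimator can be tested for parameter recovery:

* a Cα-only protein whose short lumen-exposed helix ("helix D") jumps between
  a lumen-facing (L) and a membrane-facing (M) position — two-state Markov
  switching along the membrane normal, plus isotropic thermal noise;
* a pair of atom groups in free Brownian motion with a known diffusion
  coefficient (the Einstein-relation fixture);
* Ornstein-Uhlenbeck dihedral/energy series with a known relaxation time;
* an analytic quartic double well with a known barrier (the metadynamics
  oracle).

All draws flow from one ``numpy.random.Generator`` seeded per call; a fixed
:class:`SyntheticSpec` therefore reproduces byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .core import AtomLabel, TimeSeries, Trajectory, wrap_degrees

__all__ = [
    "SyntheticSpec",
    "PotentialSpec",
    "InvalidSpecError",
    "gen_two_state_protein",
    "gen_brownian_pair",
    "gen_ou_series",
    "gen_double_well",
]


class InvalidSpecError(ValueError):
    """Raised when a SyntheticSpec violates a generator precondition."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Attributes
    ----------
    seed
        Seed for the per-call random generator.
    n_frames, dt
        Trajectory length and time units per frame.
    n_residues
        Chain length of the synthetic Cα protein.
    helix_ranges
        Helix label -> inclusive 1-based residue range; helix "D" drives the
        two-state motion.
    lm_amplitude
        Separation of the L and M helix-D positions along the membrane
        normal, nm. 0 disables the switching (degenerate static case).
    lm_populations
        Stationary occupancies (p_L, p_M); must sum to 1.
    switch_rate
        Two-state Markov switching rate per frame (transition probability
        scale; see :func:`gen_two_state_protein`).
    noise_sigma
        Per-coordinate isotropic Gaussian thermal noise, nm.
    diffusion_coeff
        Per-group Brownian diffusion coefficient, nm^2/time.
    relax_time
        Ornstein-Uhlenbeck relaxation time, time units.
    ou_sigma
        Stationary standard deviation of the OU series (degrees for the
        dihedral kind, kJ/mol for the energy kind).
    barrier, minima
        Double-well barrier height (kJ/mol) and minima positions (nm).
    asymmetry
        Energy offset U(min2) - U(min1) of the double well, kJ/mol.
    """

    seed: int = 0
    n_frames: int = 1000
    dt: float = 1.0
    n_residues: int = 60
    helix_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"A": (5, 20), "B": (25, 38), "D": (45, 54)}
    )
    lm_amplitude: float = 0.8
    lm_populations: tuple[float, float] = (0.5, 0.5)
    switch_rate: float = 0.1
    noise_sigma: float = 0.05
    diffusion_coeff: float = 5e-4
    relax_time: float = 10.0
    ou_sigma: float = 20.0
    barrier: float = 10.0
    minima: tuple[float, float] = (2.2, 2.9)
    asymmetry: float = 0.0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise InvalidSpecError("n_frames must be >= 1")
        if self.dt <= 0:
            raise InvalidSpecError("dt must be > 0")
        for label, (lo, hi) in self.helix_ranges.items():
            if lo < 1 or hi < lo or hi > self.n_residues:
                raise InvalidSpecError(
                    f"helix {label!r} range [{lo}, {hi}] outside [1, {self.n_residues}]"
                )
        p = np.asarray(self.lm_populations, dtype=float)
        if p.shape != (2,) or not np.isclose(p.sum(), 1.0):
            raise InvalidSpecError("lm_populations must be two values summing to 1")
        if self.lm_amplitude < 0:
            raise InvalidSpecError("lm_amplitude must be >= 0")
        if self.lm_amplitude > 0 and (np.any(p <= 0) or np.any(p >= 1)):
            raise InvalidSpecError("lm_populations must lie strictly inside (0, 1)")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")


def _reference_structure(n_residues: int) -> np.ndarray:
    """Deterministic Cα backbone: an ideal-helix-like curve, nm."""
    i = np.arange(n_residues)
    # 0.38 nm Ca-Ca rise projected on a gentle superhelical curve; the exact
    # shape is irrelevant, it only needs to be non-degenerate in 3-D.
    coords = np.stack(
        [
            0.6 * np.cos(2.0 * np.pi * i / 18.0),
            0.6 * np.sin(2.0 * np.pi * i / 18.0),
            0.15 * i,
        ],
        axis=1,
    )
    return coords


def _ca_labels(n_residues: int) -> list[AtomLabel]:
    return [AtomLabel(i + 1, "ALA", "CA") for i in range(n_residues)]


def _sample_markov_states(
    rng: np.random.Generator,
    n_frames: int,
    populations: tuple[float, float],
    rate: float,
) -> np.ndarray:
    """Two-state discrete-time Markov chain with given stationary occupancies.

    Transition probabilities P(i -> j) = rate * p_j for j != i, which leaves
    (p_0, p_1) stationary for any rate in (0, min(1/p_0, 1/p_1)].
    """
    p = np.asarray(populations, dtype=float)
    if rate <= 0 or rate * p.max() > 1:
        raise InvalidSpecError(
            f"switch_rate {rate} outside (0, {1.0 / p.max():.3g}] for populations {tuple(p)}"
        )
    states = np.empty(n_frames, dtype=int)
    states[0] = int(rng.random() < p[1])
    u = rng.random(n_frames - 1)
    for k in range(1, n_frames):
        other = 1 - states[k - 1]
        states[k] = other if u[k - 1] < rate * p[other] else states[k - 1]
    return states


def gen_two_state_protein(spec: SyntheticSpec) -> Trajectory:
    """Cα trajectory with two-state (L/M) helix-D displacement plus noise.

    Helix-D residues jump between two positions separated by
    ``spec.lm_amplitude`` along the membrane normal (z): the L state sits at
    the reference z, the M state at z - amplitude (membrane side negative
    shift relative to the lumen-facing reference is immaterial; the threshold
    convention in :class:`~lhcdyn.core.Topology` places M below L). Every
    atom carries isotropic Gaussian noise of ``spec.noise_sigma`` per
    coordinate. Frame 0 is the noiseless reference structure.

    The trajectory metadata records the ground truth: state sequence,
    amplitude, populations and the z midpoint usable as an L/M threshold.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ref = _reference_structure(spec.n_residues)
    if "D" not in spec.helix_ranges:
        raise InvalidSpecError('helix "D" must be present in helix_ranges')
    lo, hi = spec.helix_ranges["D"]
    d_atoms = np.arange(lo - 1, hi)  # Ca-only: atom index = residue index - 1

    coords = np.repeat(ref[None, :, :], spec.n_frames, axis=0)

    if spec.lm_amplitude > 0:
        states = _sample_markov_states(
            rng, spec.n_frames, spec.lm_populations, spec.switch_rate
        )
    else:
        states = np.zeros(spec.n_frames, dtype=int)
    # state 0 = L (reference z), state 1 = M (shifted towards the membrane)
    coords[:, d_atoms, 2] -= spec.lm_amplitude * states[:, None]

    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        noise[0] = 0.0  # frame 0 stays the exact reference
        coords += noise

    ref_z = ref[d_atoms, 2].mean()
    return Trajectory(
        coords,
        _ca_labels(spec.n_residues),
        dt=spec.dt,
        metadata={
            "generator": "gen_two_state_protein",
            "states": states,
            "lm_amplitude": spec.lm_amplitude,
            "lm_populations": tuple(spec.lm_populations),
            "noise_sigma": spec.noise_sigma,
            "lm_threshold_z": ref_z - spec.lm_amplitude / 2.0,
            "helix_d_range": (lo, hi),
        },
    )


def gen_brownian_pair(spec: SyntheticSpec, atoms_per_group: int = 4) -> Trajectory:
    """Two rigid atom groups whose centres diffuse independently.

    Each group's centre of mass performs free Brownian motion with the
    per-group coefficient ``spec.diffusion_coeff`` (nm^2/time). The relative
    displacement vector between the two centres then diffuses with
    coefficient 2 D; this factor is recorded in the output metadata as
    ``relative_diffusion_coeff`` and is the ground truth for the
    Einstein-relation fit.
    """
    spec.validate()
    if spec.diffusion_coeff < 0:
        raise InvalidSpecError("diffusion_coeff must be >= 0")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    step_sigma = np.sqrt(2.0 * spec.diffusion_coeff * spec.dt)

    # rigid internal geometry per group (tetrahedron-ish), nm
    local = 0.2 * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )[:atoms_per_group]
    offsets = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])

    coords = np.empty((n, 2 * atoms_per_group, 3))
    for g in range(2):
        steps = rng.normal(0.0, step_sigma, size=(n, 3)) if step_sigma > 0 else np.zeros((n, 3))
        steps[0] = 0.0
        com = offsets[g] + np.cumsum(steps, axis=0)
        coords[:, g * atoms_per_group : (g + 1) * atoms_per_group, :] = (
            com[:, None, :] + local[None, :, :]
        )

    labels = [
        AtomLabel(g + 1, f"GR{g + 1}", f"C{a + 1}")
        for g in range(2)
        for a in range(atoms_per_group)
    ]
    return Trajectory(
        coords,
        labels,
        dt=spec.dt,
        metadata={
            "generator": "gen_brownian_pair",
            "diffusion_coeff": spec.diffusion_coeff,
            "relative_diffusion_coeff": 2.0 * spec.diffusion_coeff,
            "note": "relative COM vector diffuses with 2D (sum of independent coefficients)",
        },
    )


def gen_ou_series(
    spec: SyntheticSpec, kind: Literal["dihedral", "energy"] = "dihedral"
) -> TimeSeries:
    """Ornstein-Uhlenbeck series with normalized ACF exp(-t/relax_time).

    Uses the exact one-step OU transition, so the lag-k autocorrelation is
    exp(-k dt / relax_time) at any dt. The dihedral kind is centred on a
    reference angle and wrapped to (-180, 180]; the energy kind is centred on
    an arbitrary offset (kJ/mol). The stationary standard deviation is
    ``spec.ou_sigma``.
    """
    spec.validate()
    if spec.relax_time <= 0:
        raise InvalidSpecError("relax_time must be > 0")
    if spec.relax_time <= spec.dt:
        warnings.warn(
            f"relax_time {spec.relax_time} <= dt {spec.dt}: correlation is "
            "under-resolved at this sampling interval",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    rho = np.exp(-spec.dt / spec.relax_time)
    innov_sigma = spec.ou_sigma * np.sqrt(1.0 - rho * rho)

    x = np.empty(n)
    x[0] = rng.normal(0.0, spec.ou_sigma)
    eps = rng.normal(0.0, innov_sigma, size=n - 1)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + eps[k - 1]

    if kind == "dihedral":
        value = wrap_degrees(x - 60.0)  # fluctuations about a -60 deg rotamer
        units = "deg"
    elif kind == "energy":
        value = x - 150.0
        units = "kJ/mol"
    else:
        raise InvalidSpecError(f"unknown series kind {kind!r}")

    return TimeSeries(
        t=np.arange(n) * spec.dt,
        value=value,
        units=units,
        metadata={
            "generator": "gen_ou_series",
            "kind": kind,
            "relax_time": spec.relax_time,
            "stationary_sigma": spec.ou_sigma,
        },
    )


@dataclass
class PotentialSpec:
    """An analytic 1-D potential with its exact free-energy reference.

    ``u`` and ``force`` are callables of the collective variable s (nm);
    ``grid``/``free_energy`` tabulate the exact F(s) = U(s) - min U on the
    domain (for a single overdamped particle the free energy along s *is* the
    potential). ``domain`` bounds the reflective integrator walls.
    """

    u: Callable[[np.ndarray], np.ndarray]
    force: Callable[[np.ndarray], np.ndarray]
    grid: np.ndarray
    free_energy: np.ndarray
    domain: tuple[float, float]
    minima: tuple[float, float]
    barrier: float

    def exact_on(self, s: np.ndarray) -> np.ndarray:
        return self.u(np.asarray(s)) - self.u(np.asarray(self.grid)).min()


def gen_double_well(spec: SyntheticSpec, n_grid: int = 1501) -> PotentialSpec:
    """Quartic double well with stated barrier, minima and optional tilt.

    With minima at a < b, midpoint m and half-separation w, the symmetric
    part is U0(s) = barrier * ((s-m)^2 - w^2)^2 / w^4, which is 0 at both
    minima and ``barrier`` at m. A linear tilt adds ``asymmetry`` kJ/mol to
    the second minimum: U = U0 + asymmetry * (s - a) / (2 w). The tilt shifts
    the stationary points slightly off a and b; the exact tabulated
    free-energy curve (not the nominal minima) is the test oracle.
    """
    spec.validate()
    a, b = spec.minima
    if not a < b:
        raise InvalidSpecError("minima must be distinct with min1 < min2")
    if spec.barrier <= 0:
        raise InvalidSpecError("barrier must be > 0")
    m = 0.5 * (a + b)
    w = 0.5 * (b - a)
    h = spec.barrier
    tilt = spec.asymmetry / (2.0 * w)

    w2 = w * w
    w4 = w2 * w2

    # plain arithmetic so scalar calls stay cheap in the integrator hot loop
    def u(s):
        x = s - m
        return h * (x * x - w2) ** 2 / w4 + tilt * (s - a)

    def force(s):
        x = s - m
        return -(4.0 * h * x * (x * x - w2) / w4 + tilt)

    pad = 0.3 * (b - a)
    domain = (a - pad, b + pad)
    # exact curve tabulated on the inter-minima range: for the symmetric well
    # max(F) - min(F) is then the barrier and the argmin sit at the minima
    grid = np.linspace(a, b, n_grid)
    fes = u(grid)
    fes = fes - fes.min()
    return PotentialSpec(
        u=u,
        force=force,
        grid=grid,
        free_energy=fes,
        domain=domain,
        minima=(a, b),
        barrier=h,
    )
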