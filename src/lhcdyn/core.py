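"""Core containers shared across the pipeline.

Conventions used throughout the package:

* lengths in nm (PDB files are converted from/to Å at the I/O boundary),
* angles in degrees, wrapped to (-180, 180],
* energies in kJ/mol,
* time in frame-indexed units with an explicit ``dt`` per trajectory/series,
* residue indices are 1-based and ranges are inclusive, matching the PDB
  convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomLabel",
    "Trajectory",
    "TimeSeries",
    "Topology",
    "KB_KJ_PER_MOL_K",
]

#: Boltzmann constant in kJ mol^-1 K^-1 (CODATA, via R/1000).
KB_KJ_PER_MOL_K = 0.008314462618


@dataclass(frozen=True)
class AtomLabel:
    """Identity of one atom: 1-based residue index, residue name, atom name."""

    residue_index: int
    residue_name: str
    atom_name: str


@dataclass
class Trajectory:
    """Ordered frames of labelled 3-D coordinates with a timestep.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.
    atom_labels
        One :class:`AtomLabel` per atom, shared by all frames.
    dt
        Time units per frame.
    metadata
        Free-form provenance (generator parameters, ground-truth values).
    """

    coords: np.ndarray
    atom_labels: list[AtomLabel]
    dt: float = 1.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] == 0:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != len(self.atom_labels):
            raise ValueError(
                f"{self.coords.shape[1]} atoms per frame but "
                f"{len(self.atom_labels)} atom labels"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory contains non-finite coordinates")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_indices(self) -> np.ndarray:
        """1-based residue index per atom."""
        return np.array([a.residue_index for a in self.atom_labels])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def atom_indices_for_residues(self, lo: int, hi: int) -> np.ndarray:
        """0-based atom indices whose residue index lies in [lo, hi]."""
        resid = self.residue_indices
        return np.nonzero((resid >= lo) & (resid <= hi))[0]


@dataclass
class TimeSeries:
    """A scalar time series with explicit units."""

    t: np.ndarray
    value: np.ndarray
    units: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have the same shape")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise ValueError("need >= 2 samples to define dt")
        return float(self.t[1] - self.t[0])


class TopologyError(ValueError):
    """Raised for invalid or inconsistent topology annotations."""


@dataclass
class Topology:
    """Helix/group annotations and nonbonded parameters for a trajectory.

    ``helix_ranges`` maps a helix label (the field's A-E nomenclature) to an
    inclusive 1-based residue range. ``groups`` name atom sets by 0-based atom
    index (e.g. chl613, chl614, Vio/Zea, Lut1). ``charges`` are in e,
    ``lj_sigma`` in nm, ``lj_epsilon`` in kJ/mol, one entry per atom when
    provided. The membrane is represented only by its normal axis and a z
    threshold separating the membrane-facing (M) from the lumen-facing (L)
    side; z is measured with the lumen on the negative side.
    """

    helix_ranges: dict[str, tuple[int, int]]
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    membrane_normal: str = "z"
    membrane_z_threshold: float | None = None

    _AXES = {"x": 0, "y": 1, "z": 2}

    def __post_init__(self) -> None:
        for label, (lo, hi) in self.helix_ranges.items():
            if lo < 1 or hi < lo:
                raise TopologyError(
                    f"helix {label!r}: invalid residue range [{lo}, {hi}]"
                )
        if self.membrane_normal not in self._AXES:
            raise TopologyError(
                f"membrane_normal must be one of {sorted(self._AXES)}, "
                f"got {self.membrane_normal!r}"
            )
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}
        for name in ("charges", "lj_sigma", "lj_epsilon"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.lj_sigma is not None and np.any(self.lj_sigma <= 0):
            raise TopologyError("lj sigma values must be > 0")
        if self.lj_epsilon is not None and np.any(self.lj_epsilon < 0):
            raise TopologyError("lj epsilon values must be >= 0")

    @property
    def normal_axis(self) -> int:
        return self._AXES[self.membrane_normal]

    def bind(self, traj: Trajectory) -> None:
        """Validate every annotation against a concrete trajectory.

        Raises :class:`TopologyError` naming the offending helix range, group
        member or parameter array.
        """
        n_res = int(traj.residue_indices.max())
        for label, (lo, hi) in self.helix_ranges.items():
            if hi > n_res:
                raise TopologyError(
                    f"helix {label!r}: residue range [{lo}, {hi}] exceeds "
                    f"last residue {n_res}"
                )
        for name, members in self.groups.items():
            bad = members[(members < 0) | (members >= traj.n_atoms)]
            if bad.size:
                raise TopologyError(
                    f"group {name!r} references unknown atom indices {bad.tolist()}"
                )
        for pname in ("charges", "lj_sigma", "lj_epsilon"):
            arr = getattr(self, pname)
            if arr is not None and arr.shape[0] != traj.n_atoms:
                raise TopologyError(
                    f"{pname}: {arr.shape[0]} entries for {traj.n_atoms} atoms"
                )

    def helix_atom_indices(self, traj: Trajectory, label: str) -> np.ndarray:
        if label not in self.helix_ranges:
            raise TopologyError(f"helix {label!r} not defined in topology")
        lo, hi = self.helix_ranges[label]
        idx = traj.atom_indices_for_residues(lo, hi)
        if idx.size == 0:
            raise TopologyError(f"helix {label!r} selects zero atoms")
        return idx


def wrap_degrees(angles: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles in degrees to the interval (-180, 180]."""
    return -(np.mod(-np.asarray(angles) + 180.0, 360.0) - 180.0)
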