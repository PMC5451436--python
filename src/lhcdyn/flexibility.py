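"""Per-residue flexibility statistics and conformation classification.

Implements the structural probes used to locate pH/ionic-strength-responsive
regions in the antenna proteins: rigid-body superposition, PCA-filtered Cα
RMSF, the Qres environment-similarity score, their combined
|ΔRMSF| x (1 - Qres) differential profile, gromos-style cluster averaging,
and the L/M (lumen- vs membrane-facing helix-D) state classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Topology, TopologyError, Trajectory

__all__ = [
    "ResidueProfile",
    "ClusterResult",
    "DegenerateFitError",
    "superpose",
    "rmsd",
    "plain_rmsf",
    "pca_rmsf",
    "qres",
    "flex_product",
    "cluster_average",
    "lm_fraction",
]


class DegenerateFitError(ValueError):
    """Raised when a superposition subset cannot define a rigid fit."""


@dataclass
class ResidueProfile:
    """A per-residue vector: RMSF (nm), Qres (dimensionless) or a product."""

    residue_index: np.ndarray  # 1-based
    value: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if self.residue_index.shape != self.value.shape:
            raise ValueError("residue_index and value must align")

    def peak_residue(self) -> int:
        """1-based residue index of the profile's global maximum."""
        return int(self.residue_index[np.argmax(self.value)])


@dataclass
class ClusterResult:
    """Greedy-centroid clustering of a superposed trajectory."""

    labels: np.ndarray          # cluster id per frame, 0-based
    averages: list[np.ndarray]  # mean structure per cluster, (n_atoms, 3) nm
    populations: np.ndarray     # fraction of frames per cluster
    centroids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_clusters(self) -> int:
        return len(self.averages)


def _ca_indices(traj: Trajectory) -> np.ndarray:
    idx = np.array(
        [i for i, a in enumerate(traj.atom_labels) if a.atom_name == "CA"]
    )
    if idx.size == 0:
        raise ValueError("trajectory has no CA atoms")
    return idx


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no refit) between two (n_atoms, 3) frames."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(
    traj: Trajectory,
    ref_frame: int = 0,
    atom_subset: np.ndarray | None = None,
) -> Trajectory:
    """Rigid-body (Kabsch) fit of every frame onto a reference frame.

    Rotation + translation only, no scaling, least-squares over
    ``atom_subset`` (all atoms by default). The transform fitted on the
    subset is applied to all atoms. The subset must contain at least three
    non-collinear atoms, otherwise the rotation is underdetermined.
    """
    subset = np.arange(traj.n_atoms) if atom_subset is None else np.asarray(atom_subset)
    if subset.size < 3:
        raise DegenerateFitError("superposition subset needs >= 3 atoms")
    ref = traj.coords[ref_frame, subset]
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise DegenerateFitError("superposition subset is collinear")

    out = np.empty_like(traj.coords)
    ref_mean = ref.mean(axis=0)
    for k in range(traj.n_frames):
        mob = traj.coords[k, subset]
        mob_mean = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob - mob_mean)
        out[k] = rot.apply(traj.coords[k] - mob_mean) + ref_mean
    return Trajectory(out, traj.atom_labels, dt=traj.dt, metadata=dict(traj.metadata))


def plain_rmsf(traj: Trajectory, ca_only: bool = True, weights: np.ndarray | None = None) -> ResidueProfile:
    """Per-residue Cα RMSF about the (frame-weighted) mean structure, nm.

    Frame weights default to uniform; the hook exists for reweighted
    ensembles.
    """
    idx = _ca_indices(traj) if ca_only else np.arange(traj.n_atoms)
    x = traj.coords[:, idx, :]
    w = np.full(traj.n_frames, 1.0 / traj.n_frames) if weights is None else (
        np.asarray(weights, dtype=float) / np.sum(weights)
    )
    mean = np.tensordot(w, x, axes=(0, 0))
    dev2 = np.sum((x - mean) ** 2, axis=2)
    msf = np.tensordot(w, dev2, axes=(0, 0))
    resid = traj.residue_indices[idx]
    return ResidueProfile(resid, np.sqrt(msf), kind="rmsf")


def pca_rmsf(
    traj: Trajectory,
    ca_only: bool = True,
    n_components: int | None = None,
    variance_cut: float = 0.75,
) -> ResidueProfile:
    """Cα RMSF of the trajectory reconstructed in a PCA subspace.

    Projecting on the top principal components strips uncorrelated thermal
    jitter while keeping the collective motions. With the full component set
    this reduces exactly to the plain RMSF. ``n_components`` defaults to the
    smallest number of components explaining ``variance_cut`` of the total
    variance; values above 3N are clipped with a warning.
    """
    idx = _ca_indices(traj) if ca_only else np.arange(traj.n_atoms)
    x = traj.coords[:, idx, :].reshape(traj.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD-based PCA; frames usually outnumber coordinates only at desk scale,
    # full_matrices=False keeps both regimes cheap
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if n_components is None:
        if total == 0:
            n_components = 1
        else:
            frac = np.cumsum(var) / total
            n_components = int(np.searchsorted(frac, variance_cut) + 1)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > s.size:
        warnings.warn(
            f"n_components={n_components} exceeds available modes {s.size}; clipped",
            stacklevel=2,
        )
        n_components = s.size
    proj = xc @ vt[:n_components].T @ vt[:n_components]
    recon = (proj + mean).reshape(traj.n_frames, idx.size, 3)
    dev2 = np.sum((recon - recon.mean(axis=0)) ** 2, axis=2)
    resid = traj.residue_indices[idx]
    return ResidueProfile(resid, np.sqrt(dev2.mean(axis=0)), kind="pca_rmsf")


def _mean_ca_structure(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    idx = _ca_indices(traj)
    return traj.coords[:, idx, :].mean(axis=0), traj.residue_indices[idx]


def qres(
    ensemble_a: Trajectory,
    ensemble_b: Trajectory,
    min_separation: int = 2,
    sigma_prefactor_nm: float = 0.1,
    sigma_exponent: float = 0.15,
    frame_averaged: bool = False,
) -> ResidueProfile:
    """Per-residue environment similarity Q between two ensembles.

    For each residue i, over partners j with ``|i - j| >= min_separation``::

        Q_i = < exp(-(r_ij - r'_ij)^2 / (2 sigma_ij^2)) >_j

    with r_ij the Cα-Cα distance in ensemble A's mean structure, r'_ij in
    ensemble B's, and sigma_ij = 0.1 nm * (1 + |i - j|)^0.15 (the standard
    1 Å prefactor converted to nm). Q_i is 1 when the residue's distance
    pattern is identical in both ensembles and decays towards 0 as the
    environment rearranges. A residue with no eligible partner gets Q_i = 1
    by convention. By default Q compares the two condition-mean structures;
    ``frame_averaged=True`` averages Q over per-frame structures paired with
    the other ensemble's mean instead.
    """
    ca_a, resid_a = _mean_ca_structure(ensemble_a)
    ca_b, resid_b = _mean_ca_structure(ensemble_b)
    if resid_a.size != resid_b.size:
        raise ValueError("ensembles must have matching residue counts")
    n = resid_a.size
    if n < 3:
        raise ValueError("too short a chain for Qres (need >= 3 residues)")

    def pair_dists(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)

    sep = np.abs(resid_a[:, None] - resid_a[None, :])
    eligible = sep >= min_separation
    sigma = sigma_prefactor_nm * (1.0 + sep) ** sigma_exponent

    def q_between(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        da, db = pair_dists(xa), pair_dists(xb)
        kern = np.exp(-((da - db) ** 2) / (2.0 * sigma**2))
        out = np.ones(n)
        counts = eligible.sum(axis=1)
        has = counts > 0
        out[has] = np.where(eligible, kern, 0.0).sum(axis=1)[has] / counts[has]
        return out

    if frame_averaged:
        idx_a = _ca_indices(ensemble_a)
        qs = [
            q_between(ensemble_a.coords[k, idx_a, :], ca_b)
            for k in range(ensemble_a.n_frames)
        ]
        q = np.mean(qs, axis=0)
    else:
        q = q_between(ca_a, ca_b)
    return ResidueProfile(resid_a, q, kind="qres")


def flex_product(
    low_ph: Trajectory,
    high_ph: Trajectory,
    n_components: int | None = None,
    superpose_first: bool = True,
    order: str = "diff_then_product",
) -> ResidueProfile:
    """Differential flexibility profile |RMSF_low - RMSF_high| x (1 - Qres).

    High values flag residues that are both more (or less) mobile *and*
    structurally rearranged between the two conditions — the signature of a
    protonation-responsive region. Both ensembles are superposed to the low
    ensemble's first frame on Cα before the statistics are taken. The
    alternative composition order (product per condition, then differenced)
    is available via ``order="product_then_diff"`` for comparison.
    """
    if superpose_first:
        ca = _ca_indices(low_ph)
        ref = low_ph
        low_ph = superpose(low_ph, 0, ca)
        # fit high ensemble onto the same reference frame
        high_tmp = Trajectory(
            np.concatenate([ref.coords[:1], high_ph.coords], axis=0),
            high_ph.atom_labels,
            dt=high_ph.dt,
        )
        high_ph = Trajectory(
            superpose(high_tmp, 0, ca).coords[1:], high_ph.atom_labels, dt=high_ph.dt
        )
    rmsf_low = pca_rmsf(low_ph, n_components=n_components)
    rmsf_high = pca_rmsf(high_ph, n_components=n_components)
    q = qres(low_ph, high_ph)
    if order == "diff_then_product":
        value = np.abs(rmsf_low.value - rmsf_high.value) * (1.0 - q.value)
    elif order == "product_then_diff":
        value = np.abs(
            rmsf_low.value * (1.0 - q.value) - rmsf_high.value * (1.0 - q.value)
        )
    else:
        raise ValueError(f"unknown order {order!r}")
    return ResidueProfile(rmsf_low.residue_index, value, kind="flex_product")


def cluster_average(traj: Trajectory, rmsd_cutoff: float) -> ClusterResult:
    """Gromos-style greedy centroid clustering on pairwise frame RMSD.

    Repeatedly takes the unassigned frame with the most unassigned
    neighbours within ``rmsd_cutoff`` (nm) as a cluster centroid, assigns its
    neighbourhood, and iterates. Assumes the trajectory is already
    superposed; RMSD is computed without refitting. Averages are per-cluster
    coordinate means.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be > 0")
    n = traj.n_frames
    x = traj.coords.reshape(n, -1)
    # pairwise RMSD in chunks to bound memory
    n_atoms = traj.n_atoms
    within = np.zeros((n, n), dtype=bool)
    chunk = max(1, int(2e7) // max(1, x.shape[1]))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d2 = np.sum((x[start:stop, None, :] - x[None, :, :]) ** 2, axis=2)
        within[start:stop] = d2 / n_atoms <= rmsd_cutoff**2

    labels = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cid = 0
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))
        members = within[center] & remaining
        members[center] = True
        labels[members] = cid
        centroids.append(center)
        remaining &= ~members
        cid += 1

    averages = [traj.coords[labels == c].mean(axis=0) for c in range(cid)]
    populations = np.bincount(labels, minlength=cid) / n
    return ClusterResult(labels, averages, populations, np.asarray(centroids))


def lm_fraction(traj: Trajectory, topo: Topology) -> dict:
    """Occupancy of the L (lumen-facing) / M (membrane-facing) helix-D states.

    A frame is labelled M when the helix-D centre of mass along the membrane
    normal lies below ``topo.membrane_z_threshold``, else L. The generator
    displaces the M state towards negative z, so "below threshold" is the
    membrane-facing conformation under this package's axis convention.
    Returns the two fractions, the per-frame labels and the L<->M transition
    count.
    """
    if topo.membrane_z_threshold is None:
        raise TopologyError("membrane_z_threshold is not configured")
    idx = topo.helix_atom_indices(traj, "D")
    com = traj.coords[:, idx, topo.normal_axis].mean(axis=1)
    is_m = com < topo.membrane_z_threshold
    transitions = int(np.sum(is_m[1:] != is_m[:-1]))
    return {
        "L": float(np.mean(~is_m)),
        "M": float(np.mean(is_m)),
        "labels": np.where(is_m, "M", "L"),
        "transitions": transitions,
    }
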