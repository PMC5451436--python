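"""Reading and writing the formats the pipeline touches.

Multi-model PDB (via biotite) is the canonical structure format; XYZ is the
lightweight alternative. Coordinates are nm in memory and Å on disk for PDB
(the PDB fixed-width field gives ~1e-4 nm round-trip precision). Topology and
synthetic specs travel as YAML, scalar time series as 2-column TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
import yaml
from biotite.structure.io.pdb import PDBFile

from .core import AtomLabel, TimeSeries, Topology, TopologyError, Trajectory

__all__ = [
    "FormatError",
    "read_trajectory",
    "write_trajectory",
    "load_topology",
    "read_timeseries",
    "write_timeseries",
]

NM_PER_ANGSTROM = 0.1


class FormatError(ValueError):
    """Raised for unparseable or internally inconsistent trajectory files."""


def _traj_to_stack(traj: Trajectory) -> struc.AtomArrayStack:
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord[:] = traj.coords / NM_PER_ANGSTROM
    stack.res_id = np.array([a.residue_index for a in traj.atom_labels])
    stack.res_name = np.array([a.residue_name for a in traj.atom_labels])
    stack.atom_name = np.array([a.atom_name for a in traj.atom_labels])
    stack.chain_id = np.full(traj.n_atoms, "A")
    stack.element = np.array(
        [(a.atom_name[:1] or "C") for a in traj.atom_labels]
    )
    stack.hetero = np.zeros(traj.n_atoms, dtype=bool)
    return stack


def _write_pdb(traj: Trajectory, path: Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_traj_to_stack(traj))
    pdb.write(str(path))


def _read_pdb(path: Path, dt: float) -> Trajectory:
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise FormatError(f"{path}: inconsistent models ({exc})") from exc
    if stack.stack_depth() == 0:
        raise FormatError(f"{path}: no models found")
    labels = [
        AtomLabel(int(r), str(rn), str(an))
        for r, rn, an in zip(stack.res_id, stack.res_name, stack.atom_name)
    ]
    return Trajectory(stack.coord * NM_PER_ANGSTROM, labels, dt=dt)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {k} dt={traj.dt:g} units=nm\n")
            for label, (x, y, z) in zip(traj.atom_labels, traj.coords[k]):
                fh.write(
                    f"{label.atom_name:<4s} {x:15.8f} {y:15.8f} {z:15.8f} "
                    f"{label.residue_index:d} {label.residue_name}\n"
                )


def _read_xyz(path: Path, dt: float) -> Trajectory:
    frames: list[np.ndarray] = []
    labels: list[AtomLabel] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    model = 0
    while pos < len(lines):
        if not lines[pos].strip():
            raise FormatError(f"{path}: blank model header at model {model + 1}")
        try:
            n_atoms = int(lines[pos].split()[0])
        except ValueError as exc:
            raise FormatError(
                f"{path}: bad atom count {lines[pos]!r} at model {model + 1}"
            ) from exc
        if pos + 2 + n_atoms > len(lines):
            raise FormatError(f"{path}: truncated model {model + 1}")
        coords = np.empty((n_atoms, 3))
        frame_labels: list[AtomLabel] = []
        for i in range(n_atoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: malformed atom line in model {model + 1}: "
                    f"{lines[pos + 2 + i]!r}"
                )
            coords[i] = [float(v) for v in parts[1:4]]
            resid = int(parts[4]) if len(parts) > 4 else i + 1
            resname = parts[5] if len(parts) > 5 else "UNK"
            frame_labels.append(AtomLabel(resid, resname, parts[0]))
        if not labels:
            labels = frame_labels
        elif n_atoms != len(labels):
            raise FormatError(
                f"{path}: model {model + 1} has {n_atoms} atoms, "
                f"model 1 has {len(labels)}"
            )
        frames.append(coords)
        pos += 2 + n_atoms
        model += 1
    if not frames:
        raise FormatError(f"{path}: no models found")
    return Trajectory(np.stack(frames), labels, dt=dt)


def read_trajectory(path: str | os.PathLike, format: str | None = None, dt: float = 1.0) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory.

    Frames are returned in file order; residue indices follow the file's
    1-based annotation. ``dt`` attaches the time units per frame (the formats
    themselves carry none).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(path, dt)
    if fmt == "xyz":
        return _read_xyz(path, dt)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB (Å on disk) or XYZ (nm)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")


def load_topology(path: str | os.PathLike) -> Topology:
    """Load and validate a YAML topology/annotation file.

    Schema::

        helices:                    # list, so duplicate labels are detectable
          - {label: A, start: 5, end: 20}
          - {label: D, start: 45, end: 54}
        groups:                     # 0-based atom indices
          chl613: [0, 1, 2]
        charges: [...]              # e, one per atom (optional)
        lj_sigma: [...]             # nm (optional)
        lj_epsilon: [...]           # kJ/mol (optional)
        membrane_normal: z
        membrane_z_threshold: 3.5   # nm (optional)

    Group/parameter consistency against a concrete trajectory is checked at
    bind time via :meth:`lhcdyn.core.Topology.bind`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "helices" not in raw:
        raise TopologyError(f"{path}: missing 'helices' section")
    helix_ranges: dict[str, tuple[int, int]] = {}
    for entry in raw["helices"]:
        label = str(entry["label"])
        if label in helix_ranges:
            raise TopologyError(f"{path}: duplicate helix label {label!r}")
        helix_ranges[label] = (int(entry["start"]), int(entry["end"]))
    return Topology(
        helix_ranges=helix_ranges,
        groups={str(k): np.asarray(v, dtype=int) for k, v in (raw.get("groups") or {}).items()},
        charges=raw.get("charges"),
        lj_sigma=raw.get("lj_sigma"),
        lj_epsilon=raw.get("lj_epsilon"),
        membrane_normal=raw.get("membrane_normal", "z"),
        membrane_z_threshold=raw.get("membrane_z_threshold"),
    )


def write_timeseries(series: TimeSeries, path: str | os.PathLike) -> None:
    """Write a scalar series as 2-column TSV (time, value)."""
    df = pd.DataFrame({"time": series.t, "value": series.value})
    with open(path, "w") as fh:
        fh.write(f"# units={series.units}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_timeseries(path: str | os.PathLike) -> TimeSeries:
    units = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            units = first.split("units=", 1)[-1].strip() if "units=" in first else ""
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    return TimeSeries(t=df["time"].to_numpy(), value=df["value"].to_numpy(), units=units)


def write_run_log(out_dir: str | os.PathLike, params: dict) -> Path:
    """Record run parameters and library versions to <out>/run.log."""
    import sys
    from datetime import datetime, timezone

    import biotite
    import scipy

    import lhcdyn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run.log"
    with open(path, "a") as fh:
        fh.write(f"[{datetime.now(timezone.utc).isoformat()}]\n")
        fh.write(
            f"versions: lhcdyn={lhcdyn.__version__} python={sys.version.split()[0]} "
            f"numpy={np.__version__} scipy={scipy.__version__} "
            f"pandas={pd.__version__} biotite={biotite.__version__}\n"
        )
        for k, v in params.items():
            fh.write(f"  {k} = {v}\n")
    return path
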