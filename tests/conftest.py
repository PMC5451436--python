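import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lhcdyn.core import AtomLabel, Topology, Trajectory
from lhcdyn.synthetic import SyntheticSpec, gen_two_state_protein


@pytest.fixture
def two_state_spec() -> SyntheticSpec:
    """Study conditions for the L/M two-state protein at desk scale."""
    return SyntheticSpec(
        seed=11,
        n_frames=800,
        n_residues=60,
        lm_amplitude=0.8,
        lm_populations=(0.5, 0.5),
        switch_rate=0.2,
        noise_sigma=0.05,
    )


@pytest.fixture
def two_state_traj(two_state_spec) -> Trajectory:
    return gen_two_state_protein(two_state_spec)


@pytest.fixture
def default_topology() -> Topology:
    """Helix annotations matching the synthetic generator's defaults."""
    return Topology(helix_ranges={"A": (5, 20), "B": (25, 38), "D": (45, 54)})


def make_trajectory(coords: np.ndarray, dt: float = 1.0) -> Trajectory:
    """A Ca-only trajectory with one residue per atom."""
    n_atoms = coords.shape[1]
    labels = [AtomLabel(i + 1, "ALA", "CA") for i in range(n_atoms)]
    return Trajectory(coords, labels, dt=dt)
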