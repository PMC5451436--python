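"""Superposition, RMSF/Qres profiles, clustering and L/M classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lhcdyn.core import Topology
from lhcdyn.flexibility import (
    DegenerateFitError,
    cluster_average,
    flex_product,
    lm_fraction,
    pca_rmsf,
    plain_rmsf,
    qres,
    rmsd,
    superpose,
)
from lhcdyn.synthetic import SyntheticSpec, gen_two_state_protein

from conftest import make_trajectory
from oracles import brute_qres, quaternion_superpose


def _random_structure(rng, n):
    return rng.normal(size=(n, 3))


class TestSuperpose:
    def test_identical_frame_rmsd_zero(self):
        rng = np.random.default_rng(0)
        x = _random_structure(rng, 10)
        traj = make_trajectory(np.stack([x, x]))
        fitted = superpose(traj)
        assert rmsd(fitted.coords[1], fitted.coords[0]) < 1e-12

    def test_rigid_rotation_removed(self):
        rng = np.random.default_rng(1)
        x = _random_structure(rng, 10)
        rot = Rotation.from_euler("z", 90, degrees=True)
        traj = make_trajectory(np.stack([x, rot.apply(x) + np.array([1.0, -2.0, 0.5])]))
        fitted = superpose(traj)
        assert rmsd(fitted.coords[1], fitted.coords[0]) < 1e-9

    def test_noisy_fit_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        x = _random_structure(rng, 30)
        noisy = x + rng.normal(0, 0.01, size=x.shape)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        moved = rot.apply(noisy) + np.array([0.3, 0.1, -0.2])
        traj = make_trajectory(np.stack([x, moved]))
        fitted = superpose(traj)
        oracle = quaternion_superpose(x, moved)
        assert np.abs(fitted.coords[1] - oracle).max() < 1e-9
        # post-fit RMSD close to the noise-model expectation sigma*sqrt(3)
        assert rmsd(fitted.coords[1], x) == pytest.approx(0.01 * np.sqrt(3), rel=0.25)

    def test_collinear_subset_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        traj = make_trajectory(np.stack([line, line]))
        with pytest.raises(DegenerateFitError):
            superpose(traj)


class TestPcaRmsf:
    def test_static_trajectory_zero_profile(self):
        x = np.zeros((10, 5, 3))
        prof = pca_rmsf(make_trajectory(x), n_components=3)
        assert np.allclose(prof.value, 0.0)

    def test_two_point_oscillation_closed_form(self):
        # one atom oscillating +/- d/2 along x: RMSF = d/2 for it, 0 elsewhere
        d = 0.4
        coords = np.zeros((50, 6, 3))
        coords[::2, 2, 0] = d / 2
        coords[1::2, 2, 0] = -d / 2
        prof = pca_rmsf(make_trajectory(coords), n_components=18)
        assert prof.value[2] == pytest.approx(d / 2)
        assert np.allclose(np.delete(prof.value, 2), 0.0)

    def test_full_component_set_equals_plain_rmsf(self, two_state_traj):
        sup = superpose(two_state_traj, 0, np.arange(40))
        full = pca_rmsf(sup, n_components=3 * sup.n_atoms)
        plain = plain_rmsf(sup)
        assert np.allclose(full.value, plain.value, atol=1e-10)

    def test_top_component_captures_helix_d(self, two_state_spec):
        traj = gen_two_state_protein(two_state_spec)
        sup = superpose(traj, 0, np.arange(40))
        top1 = pca_rmsf(sup, n_components=1)
        plain = plain_rmsf(sup)
        lo, hi = two_state_spec.helix_ranges["D"]
        sel = slice(lo - 1, hi)
        r = np.corrcoef(top1.value[sel], plain.value[sel])[0, 1]
        assert r > 0.95
        assert top1.peak_residue() in range(lo, hi + 1)

    def test_excess_components_clipped_with_warning(self):
        coords = np.random.default_rng(3).normal(size=(8, 4, 3))
        with pytest.warns(UserWarning, match="clipped"):
            pca_rmsf(make_trajectory(coords), n_components=1000)


class TestQres:
    def test_identical_ensembles_unity(self, two_state_traj):
        q = qres(two_state_traj, two_state_traj)
        assert np.allclose(q.value, 1.0)

    def test_five_residue_displacement_matches_pair_loop_oracle(self):
        xa = np.array([[0.4 * i, 0.0, 0.0] for i in range(5)])
        xb = xa.copy()
        xb[4, 1] += 1.0
        ta = make_trajectory(xa[None])
        tb = make_trajectory(xb[None])
        q = qres(ta, tb)
        oracle = brute_qres(xa, xb, np.arange(1, 6))
        assert np.allclose(q.value, oracle, atol=1e-12)
        # frozen oracle output for this geometry
        assert np.allclose(
            q.value,
            [0.69301822, 0.50662318, 0.50012339, 1.0, 0.03084926],
            atol=1e-7,
        )

    def test_partnerless_residue_convention(self):
        # chain of 3: the middle residue has no |i-j| >= 2 partner -> Q = 1
        xa = np.array([[0.0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]])
        xb = xa + np.array([0.0, 0.3, 0.0]) * np.array([[0], [1], [0]])
        q = qres(make_trajectory(xa[None]), make_trajectory(xb[None]))
        assert q.value[1] == 1.0

    def test_too_short_chain_rejected(self):
        xa = np.zeros((1, 2, 3))
        with pytest.raises(ValueError, match="too short"):
            qres(make_trajectory(xa), make_trajectory(xa))

    def test_symmetric_in_arguments(self, two_state_spec):
        a = gen_two_state_protein(two_state_spec)
        b = gen_two_state_protein(
            SyntheticSpec(seed=99, n_frames=200, lm_amplitude=0.0, noise_sigma=0.05)
        )
        assert np.allclose(qres(a, b).value, qres(b, a).value)


class TestFlexProduct:
    def test_identical_ensembles_zero(self, two_state_traj):
        prof = flex_product(two_state_traj, two_state_traj)
        assert np.allclose(prof.value, 0.0, atol=1e-12)

    def test_peak_in_helix_d_range(self, two_state_spec):
        lo, hi = two_state_spec.helix_ranges["D"]
        low = gen_two_state_protein(two_state_spec)
        high = gen_two_state_protein(
            SyntheticSpec(
                seed=two_state_spec.seed + 100,
                n_frames=two_state_spec.n_frames,
                lm_amplitude=0.0,
                noise_sigma=two_state_spec.noise_sigma,
            )
        )
        prof = flex_product(low, high)
        assert lo <= prof.peak_residue() <= hi
        assert np.all(prof.value >= 0)

    def test_monotone_in_displacement_amplitude(self, two_state_spec):
        lo, hi = two_state_spec.helix_ranges["D"]

        def peak(amplitude):
            low = gen_two_state_protein(
                SyntheticSpec(seed=21, n_frames=600, lm_amplitude=amplitude,
                              switch_rate=0.2, noise_sigma=0.05)
            )
            high = gen_two_state_protein(
                SyntheticSpec(seed=22, n_frames=600, lm_amplitude=0.0, noise_sigma=0.05)
            )
            prof = flex_product(low, high)
            return prof.value[lo - 1 : hi].max()

        assert peak(1.6) >= peak(0.8)


class TestClusterAverage:
    def test_static_trajectory_single_cluster(self):
        traj = make_trajectory(np.zeros((20, 5, 3)))
        res = cluster_average(traj, 0.1)
        assert res.n_clusters == 1
        assert res.populations[0] == 1.0

    def test_two_state_recovers_occupancies(self):
        spec = SyntheticSpec(
            seed=31, n_frames=600, lm_amplitude=0.8, lm_populations=(0.3, 0.7),
            switch_rate=0.2, noise_sigma=0.02,
        )
        traj = gen_two_state_protein(spec)
        sup = superpose(traj, 0, np.arange(40))  # fit on the static region
        res = cluster_average(sup, 0.15)
        assert res.n_clusters == 2
        n_eff = spec.n_frames * spec.switch_rate / (2.0 - spec.switch_rate)
        se = np.sqrt(0.3 * 0.7 / n_eff)
        assert abs(res.populations.max() - 0.7) < 3 * se
        # average structures differ by the L-M displacement at helix D
        dz = np.abs(res.averages[0] - res.averages[1])[:, 2]
        lo, hi = spec.helix_ranges["D"]
        assert dz[lo - 1 : hi].mean() == pytest.approx(0.8, rel=0.1)

    def test_large_cutoff_single_cluster(self, two_state_traj):
        res = cluster_average(two_state_traj, 100.0)
        assert res.n_clusters == 1

    def test_populations_sum_to_one_and_cutoff_monotone(self, two_state_traj):
        sup = superpose(two_state_traj, 0, np.arange(40))
        counts = []
        for cutoff in (0.05, 0.15, 0.5):
            res = cluster_average(sup, cutoff)
            assert res.populations.sum() == pytest.approx(1.0)
            assert np.all(res.labels >= 0)
            counts.append(res.n_clusters)
        assert counts == sorted(counts, reverse=True)

    def test_invalid_cutoff(self, two_state_traj):
        with pytest.raises(ValueError):
            cluster_average(two_state_traj, 0.0)


class TestLmFraction:
    def _topo(self, threshold):
        return Topology(helix_ranges={"D": (45, 54)}, membrane_z_threshold=threshold)

    def test_all_below_threshold_is_m(self, two_state_traj):
        fr = lm_fraction(two_state_traj, self._topo(1e6))
        assert fr["M"] == 1.0

    def test_threshold_at_minus_inf_is_l(self, two_state_traj):
        fr = lm_fraction(two_state_traj, self._topo(-1e6))
        assert fr["L"] == 1.0

    def test_recovers_generator_populations(self):
        spec = SyntheticSpec(
            seed=41, n_frames=4000, lm_amplitude=0.8, lm_populations=(0.3, 0.7),
            switch_rate=0.2, noise_sigma=0.05,
        )
        traj = gen_two_state_protein(spec)
        fr = lm_fraction(traj, self._topo(traj.metadata["lm_threshold_z"]))
        n_eff = spec.n_frames * spec.switch_rate / (2.0 - spec.switch_rate)
        se = np.sqrt(0.3 * 0.7 / n_eff)
        assert abs(fr["M"] - 0.7) < 3 * se
        assert abs(fr["L"] - 0.3) < 3 * se
        assert fr["transitions"] > 0

    def test_missing_threshold_is_configuration_error(self, two_state_traj):
        topo = Topology(helix_ranges={"D": (45, 54)})
        with pytest.raises(Exception, match="threshold"):
            lm_fraction(two_state_traj, topo)
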