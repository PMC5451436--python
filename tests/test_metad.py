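"""Well-tempered metadynamics: sampling, reconstruction, convergence."""

import numpy as np
import pytest

from lhcdyn.metad import (
    HillsLog,
    IntegratorInstabilityError,
    MetadConfig,
    bias_potential,
    delta_e_convergence,
    read_hills,
    reconstruct_fes,
    run_wtmetad,
    write_hills,
)
from lhcdyn.synthetic import PotentialSpec, SyntheticSpec, gen_double_well

from oracles import brute_bias_potential

WELL = gen_double_well(SyntheticSpec(barrier=10.0, minima=(2.2, 2.9)))


def _short_cfg(**kw):
    base = dict(n_steps=100_000, pace=200, seed=1)
    base.update(kw)
    return MetadConfig(**base)


def _harmonic(k=50.0, s0=2.5):
    def u(s):
        return 0.5 * k * (s - s0) ** 2

    def force(s):
        return -k * (s - s0)

    grid = np.linspace(s0 - 1.0, s0 + 1.0, 801)
    f = u(grid)
    return PotentialSpec(u, force, grid, f - f.min(), (s0 - 1.0, s0 + 1.0),
                         (s0, s0), 0.5 * k)


class TestRunWtmetad:
    def test_same_seed_identical_hills(self):
        cfg = _short_cfg(seed=3)
        _, h1 = run_wtmetad(WELL, cfg)
        _, h2 = run_wtmetad(WELL, cfg)
        assert np.array_equal(h1.center, h2.center)
        assert np.array_equal(h1.height, h2.height)

    def test_zero_hill_height_is_boltzmann_sampling(self):
        # bias-free limit: stationary CV histogram matches exp(-U/kT);
        # use a low-barrier well so both basins are crossed often
        pot = gen_double_well(SyntheticSpec(barrier=2.0, minima=(2.2, 2.9)))
        cfg = MetadConfig(hill_height=0.0, n_steps=2_000_000, seed=4)
        cv, hills = run_wtmetad(pot, cfg, cv_stride=20)
        assert len(hills) == 0
        edges = np.linspace(*pot.domain, 25)
        hist, _ = np.histogram(cv.value, bins=edges, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        boltz = np.exp(-pot.u(centers) / cfg.kt)
        boltz /= np.trapezoid(boltz, centers)
        sel = boltz > 0.05 * boltz.max()
        assert np.abs(hist[sel] - boltz[sel]).max() / boltz.max() < 0.1

    def test_enhanced_exploration_beyond_unbiased_range(self):
        k = 200.0
        pot = _harmonic(k=k)
        sigma_unbiased = np.sqrt(MetadConfig().kt / k)  # ~0.11 nm
        cv, _ = run_wtmetad(pot, _short_cfg(n_steps=400_000, seed=5))
        assert np.max(np.abs(cv.value - 2.5)) > 3 * sigma_unbiased

    def test_well_tempered_height_decay_at_fixed_point(self):
        _, hills = run_wtmetad(WELL, _short_cfg(n_steps=200_000, seed=6))
        cfg = _short_cfg()
        # the bias only grows, so the next-hill height at any fixed CV value
        # is non-increasing over time
        s_star = np.array([2.55])
        kb_dt = cfg.kt / cfg.temperature * cfg.delta_t
        heights = []
        for k in range(0, len(hills), 50):
            part = HillsLog(hills.time[:k], hills.center[:k], hills.width[:k],
                            hills.height[:k])
            v = bias_potential(part, s_star)[0]
            heights.append(cfg.hill_height * np.exp(-v / kb_dt))
        assert all(b <= a + 1e-12 for a, b in zip(heights, heights[1:]))
        assert np.all(hills.height > 0)

    def test_instability_aborts_with_diagnostic(self):
        cfg = MetadConfig(dt=0.05, n_steps=1000, seed=7)  # wildly too large dt
        with pytest.raises(IntegratorInstabilityError, match="reduce dt"):
            run_wtmetad(WELL, cfg)


class TestReconstructFes:
    def test_single_hill_closed_form(self):
        cfg = _short_cfg()
        hills = HillsLog(np.array([1.0]), np.array([2.5]), np.array([0.05]),
                         np.array([1.2]))
        grid = np.linspace(2.0, 3.0, 501)
        fes = reconstruct_fes(hills, cfg, grid)
        scale = cfg.bias_factor / (cfg.bias_factor - 1.0)
        # inverted scaled Gaussian anchored at 0: depth gamma/(gamma-1) * w0
        assert fes.f.max() == pytest.approx(scale * 1.2, rel=1e-4)
        assert grid[np.argmin(fes.f)] == pytest.approx(2.5, abs=2e-3)

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_fes(HillsLog(*(np.empty(0),) * 4), _short_cfg(),
                            np.linspace(2, 3, 10))

    def test_double_well_recovery(self):
        cfg = MetadConfig(seed=11)
        _, hills = run_wtmetad(WELL, cfg)
        fes = reconstruct_fes(hills, cfg, WELL.grid)
        diff = fes.f - WELL.free_energy
        diff -= diff.mean()
        rms = np.sqrt(np.mean(diff**2))
        assert rms < 0.5 * cfg.kt
        assert fes.barrier() == pytest.approx(10.0, rel=0.1)

    def test_symmetric_well_minima_balance(self):
        cfg = MetadConfig(seed=12)
        _, hills = run_wtmetad(WELL, cfg)
        fes = reconstruct_fes(hills, cfg, WELL.grid)
        f_at = np.interp([2.2, 2.9], fes.s, fes.f)
        assert abs(f_at[0] - f_at[1]) < 0.3 * cfg.kt

    def test_reconstruction_linearity_no_double_scaling(self):
        cfg = _short_cfg(seed=13)
        _, hills = run_wtmetad(WELL, cfg)
        grid = np.linspace(2.1, 3.0, 301)
        half = len(hills) // 2
        first = HillsLog(hills.time[:half], hills.center[:half],
                         hills.width[:half], hills.height[:half])
        second = HillsLog(hills.time[half:], hills.center[half:],
                          hills.width[half:], hills.height[half:])
        v_sum = bias_potential(first, grid) + bias_potential(second, grid)
        scale = cfg.bias_factor / (cfg.bias_factor - 1.0)
        expected = -scale * v_sum
        expected -= expected.min()
        fes = reconstruct_fes(hills, cfg, grid)
        assert np.allclose(fes.f, expected, atol=1e-10)

    def test_bias_cache_matches_direct_summation(self):
        cfg = _short_cfg(seed=14, n_steps=20_000)
        _, hills = run_wtmetad(WELL, cfg)
        s = np.linspace(*WELL.domain, 97)
        assert np.allclose(
            bias_potential(hills, s),
            brute_bias_potential(hills.center, hills.width, hills.height, s),
            rtol=1e-12,
        )


class TestDeltaEConvergence:
    def test_symmetric_well_converges_to_zero(self):
        cfg = MetadConfig(seed=15)
        _, hills = run_wtmetad(WELL, cfg)
        grid = np.linspace(*WELL.domain, 801)
        t_end = hills.time[-1]
        # windows mirrored about the barrier top at 2.55 nm
        series = delta_e_convergence(
            hills, cfg, (2.0, 2.5), (2.6, 3.1),
            checkpoints=np.linspace(0.1 * t_end, t_end, 12), grid=grid,
        )
        assert abs(series.value[-1]) < 0.75 * cfg.kt

    def test_asymmetric_offset_plateaus_at_exact_value(self):
        pot = gen_double_well(
            SyntheticSpec(barrier=10.0, minima=(2.2, 2.9), asymmetry=4.0)
        )
        cfg = MetadConfig(seed=16)
        _, hills = run_wtmetad(pot, cfg)
        grid = np.linspace(*pot.domain, 801)
        # equal-width windows mirrored about the midpoint and centred on the
        # minima: the symmetric quartic contribution cancels and the exact
        # window-mean gap equals the 4 kJ/mol tilt
        win_a, win_b = (2.8, 3.0), (2.1, 2.3)
        t_end = hills.time[-1]
        series = delta_e_convergence(
            hills, cfg, win_a, win_b, checkpoints=np.array([0.5 * t_end, t_end]),
            grid=grid,
        )
        exact = pot.exact_on(grid)
        sel_a = (grid >= win_a[0]) & (grid <= win_a[1])
        sel_b = (grid >= win_b[0]) & (grid <= win_b[1])
        exact_de = exact[sel_a].mean() - exact[sel_b].mean()
        assert exact_de == pytest.approx(4.0, abs=0.05)
        assert series.value[-1] == pytest.approx(exact_de, abs=0.5)

    def test_checkpoint_before_first_hill_flagged(self):
        cfg = _short_cfg(seed=17)
        _, hills = run_wtmetad(WELL, cfg)
        grid = np.linspace(*WELL.domain, 401)
        series = delta_e_convergence(
            hills, cfg, (2.0, 2.4), (2.7, 3.0),
            checkpoints=np.array([1e-6, hills.time[-1]]), grid=grid,
        )
        assert np.isnan(series.value[0])
        assert 1e-6 in series.metadata["undefined_at"]
        assert np.isfinite(series.value[1])

    def test_overlapping_windows_rejected(self):
        cfg = _short_cfg()
        hills = HillsLog(np.array([1.0]), np.array([2.5]), np.array([0.05]),
                         np.array([1.0]))
        with pytest.raises(ValueError, match="disjoint"):
            delta_e_convergence(hills, cfg, (2.0, 2.6), (2.5, 3.0),
                                np.array([1.0]), np.linspace(2, 3, 101))


def test_hills_file_round_trip(tmp_path):
    cfg = _short_cfg(seed=18, n_steps=20_000)
    _, hills = run_wtmetad(WELL, cfg)
    p = tmp_path / "HILLS"
    write_hills(hills, p)
    back = read_hills(p)
    assert np.allclose(back.center, hills.center, atol=1e-9)
    assert np.allclose(back.height, hills.height, rtol=1e-8)
    assert p.read_text().startswith("#! FIELDS time center sigma height")
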