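"""Delay embedding, simplex projection, and cross-map convergence sweeps."""

import numpy as np
import pytest

from pairflight import crossmap as cm
from simworlds import coupled_logistic_pair, logistic_map


class TestShadowManifold:
    def test_point_count_single_segment(self):
        man = cm.build_shadow_manifold(np.arange(100.0), E=3, tau=1)
        assert len(man) == 98  # L - (E-1) tau
        assert man.time_index[0] == 2 and man.time_index[-1] == 99

    def test_e1_is_the_series_itself(self):
        x = np.random.default_rng(0).normal(size=50)
        man = cm.build_shadow_manifold(x, E=1, tau=1)
        assert np.array_equal(man.points.ravel(), x)

    def test_segment_boundary_exclusion(self):
        # two segments of 50: 2 points lost per segment at E=3
        man = cm.build_shadow_manifold(np.arange(100.0), E=3, tau=1,
                                       segment_bounds=[0, 50])
        assert len(man) == 96

    def test_lag_ordering(self):
        x = np.arange(10.0)
        man = cm.build_shadow_manifold(x, E=3, tau=2)
        # first point at t=4: (x(4), x(2), x(0))
        assert man.points[0].tolist() == [4.0, 2.0, 0.0]

    def test_too_short_rejected(self):
        with pytest.raises(cm.InsufficientDataError):
            cm.build_shadow_manifold(np.arange(3.0), E=5, tau=1)


class TestSimplexProjection:
    def test_logistic_map_selects_low_dim_with_high_skill(self):
        x = logistic_map(500)
        e_star = cm.select_embedding_dim(x)
        assert e_star in (1, 2, 3)
        assert cm.simplex_forecast_skill(x, e_star) > 0.95

    def test_sine_wave_embeds_in_two_dims(self):
        t = np.arange(400)
        s = np.sin(2 * np.pi * t / 20)
        assert cm.simplex_forecast_skill(s, 2) > 0.99

    def test_iid_noise_still_returns_argmax(self):
        x = np.random.default_rng(1).normal(size=400)
        e_star = cm.select_embedding_dim(x)
        assert e_star in cm.EmbeddingConfig().E_grid
        assert cm.simplex_forecast_skill(x, e_star) < 0.5

    def test_too_short_series_names_feasible_e(self):
        with pytest.raises(cm.InsufficientDataError, match="feasible"):
            cm.select_embedding_dim(np.arange(12.0),
                                    cm.EmbeddingConfig(E_grid=(8, 9, 10)))


class TestCrossMapSkill:
    def test_self_cross_map_of_chaotic_series(self):
        x = logistic_map(500)
        man = cm.build_shadow_manifold(x, E=2, tau=1)
        assert cm.cross_map_skill(man, x) >= 0.99

    def test_negative_raw_correlation_clips_to_zero(self):
        # independent noise: frozen seed gives raw Pearson < 0 -> reported 0
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 300))
        man = cm.build_shadow_manifold(b, E=2, tau=1)
        raw = cm.cross_map_skill(man, a, clip=False)
        assert raw < 0
        assert cm.cross_map_skill(man, a) == 0.0

    def test_clip_is_the_only_zero_mechanism(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            a, b = np.random.default_rng(seed).normal(size=(2, 250))
            man = cm.build_shadow_manifold(b, E=2, tau=1)
            raw = cm.cross_map_skill(man, a, clip=False)
            clipped = cm.cross_map_skill(man, a)
            assert clipped == (raw if raw > 0 else 0.0)
            assert 0.0 <= clipped <= 1.0

    def test_affine_invariance_of_skill(self):
        x, y = coupled_logistic_pair(600, seed=3)
        man = cm.build_shadow_manifold(y, E=2, tau=1)
        base = cm.cross_map_skill(man, x)
        man_scaled = cm.build_shadow_manifold(5.0 * y - 2.0, E=2, tau=1)
        assert cm.cross_map_skill(man_scaled, 3.0 * x + 1.0) == pytest.approx(
            base, abs=1e-9)

    def test_small_library_rejected(self):
        man = cm.build_shadow_manifold(np.random.default_rng(0).normal(size=30),
                                       E=2, tau=1)
        with pytest.raises(cm.InsufficientDataError):
            cm.cross_map_skill(man, np.zeros(30), library_index=np.arange(3))


class TestCcmSweep:
    def test_window_accounting_worked_example(self):
        # length-100 series, L=10 -> windows {1..10}, {2..11}, ..., {91..100}
        assert len(cm._window_starts(100, 10)) == 91

    def test_full_length_library_is_single_window(self):
        x, y = coupled_logistic_pair(300, seed=4)
        cfg = cm.EmbeddingConfig(E_grid=(1, 2, 3))
        r_xy, _ = cm.ccm_sweep(x, y, L_grid=[300], config=cfg, id_a="X", id_b="Y")
        assert r_xy.n_windows.tolist() == [1]
        E = r_xy.E
        man = cm.build_shadow_manifold(y, E, 1)
        assert r_xy.skill_at_lmax == pytest.approx(cm.cross_map_skill(man, x))

    def test_direction_recovery_on_unidirectional_pair(self):
        wins = 0
        for seed in range(20):
            x, y = coupled_logistic_pair(1000, seed)
            cfg = cm.EmbeddingConfig(E_grid=(1, 2, 3, 4))
            r_xy, r_yx = cm.ccm_sweep(x, y, L_grid=[1000], config=cfg,
                                      id_a="X", id_b="Y")
            wins += r_xy.skill_at_lmax > r_yx.skill_at_lmax
        assert wins >= 19

    def test_direction_recovery_across_embedding_dims(self):
        for E in (2, 3, 4):
            wins = 0
            for seed in range(10):
                x, y = coupled_logistic_pair(1000, seed)
                man_y = cm.build_shadow_manifold(y, E, 1)
                man_x = cm.build_shadow_manifold(x, E, 1)
                wins += (cm.cross_map_skill(man_y, x)
                         > cm.cross_map_skill(man_x, y))
            assert wins >= 9

    def test_skill_grows_with_library_on_chaotic_self_map(self):
        x = logistic_map(800)
        cfg = cm.EmbeddingConfig(E_grid=(2,), max_windows=30)
        r, _ = cm.ccm_sweep(x, x, L_grid=[50, 200, 800], config=cfg)
        skills = r.skills
        assert np.all(np.diff(skills) >= -0.02)  # monotone within tolerance
        assert skills[-1] >= 0.99

    def test_small_l_skipped_with_warning(self):
        x, y = coupled_logistic_pair(300, seed=5)
        cfg = cm.EmbeddingConfig(E_grid=(3,))
        with pytest.warns(UserWarning, match="below embedding minimum"):
            r_xy, _ = cm.ccm_sweep(x, y, L_grid=[3, 300], config=cfg)
        assert r_xy.library_sizes.tolist() == [300]


class TestConvergence:
    def _mk(self, skills):
        s = np.asarray(skills, float)
        return cm.CCMResult(("a", "b"), cm.CONVENTION, 2, 1,
                            np.arange(len(s)), s, float(s[-1]))

    def test_converged_when_tail_settles(self):
        assert cm.assess_convergence(self._mk([0.2, 0.6, 0.74, 0.75])) == "converged"

    def test_increasing_when_still_rising(self):
        assert cm.assess_convergence(self._mk([0.2, 0.4, 0.6, 0.75])) == "increasing"

    def test_flat_zero_is_converged(self):
        assert cm.assess_convergence(self._mk([0.0, 0.0, 0.0, 0.0])) == "converged"

    def test_decreasing_tail_is_flat(self):
        assert cm.assess_convergence(self._mk([0.5, 0.6, 0.4])) == "flat"
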