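"""Spline resampling, curvature geometry, overlap windows, ensembles."""

import numpy as np
import pytest

from pairflight import kinematics as kin
from conftest import pair_record_with_overlap_length, smooth_raw_trajectory


def _circle_raw(R=1.0, omega=2 * np.pi, rate=60.0, duration=1.0, pair_id="c"):
    t = np.arange(int(duration * rate) + 1) / rate
    pos = np.c_[R * np.cos(omega * t), R * np.sin(omega * t), np.zeros_like(t)]
    return kin.RawTrajectory(pair_id, 1, t, pos, rate)


class TestSplineResample:
    def test_cubic_polynomial_reproduced_exactly(self):
        # a cubic spline interpolant reproduces cubic paths and derivatives
        t = np.linspace(0, 1, 61)
        coef = np.array([[1, 2, 3], [0.5, -1, 2], [0.2, 0.3, -0.4], [0.1, 0.6, 0.05]])
        pos = sum(coef[i][None, :] * t[:, None] ** i for i in range(4))
        out = kin.fit_spline_and_resample(
            kin.RawTrajectory("p", 1, t, pos, 60), 180)
        tt = out.times[:, None]
        exact_p = sum(coef[i][None, :] * tt ** i for i in range(4))
        exact_v = sum(i * coef[i][None, :] * tt ** (i - 1) for i in range(1, 4))
        exact_a = sum(i * (i - 1) * coef[i][None, :] * tt ** (i - 2) for i in range(2, 4))
        assert np.allclose(out.position, exact_p, rtol=1e-9, atol=1e-9)
        assert np.allclose(out.velocity, exact_v, rtol=1e-9, atol=1e-9)
        assert np.allclose(out.acceleration, exact_a, rtol=1e-9, atol=1e-9)

    def test_circle_speed_recovered(self):
        # uniform circular motion R=1, omega=2*pi -> speed 2*pi away from ends
        out = kin.fit_spline_and_resample(_circle_raw(), 180)
        interior = out.speed[10:-10]
        assert np.max(np.abs(interior - 2 * np.pi)) / (2 * np.pi) < 1e-3

    def test_grid_count_1s_at_180hz(self):
        out = kin.fit_spline_and_resample(_circle_raw(duration=1.0), 180)
        assert len(out) == 181

    def test_resample_on_own_grid_reproduces_knots(self):
        raw = smooth_raw_trajectory("p", 1, 0.0, 1.0, seed=3, rate=60)
        out = kin.fit_spline_and_resample(raw, 60)
        assert np.allclose(out.position, raw.positions, rtol=1e-9, atol=1e-9)

    def test_too_few_samples_rejected(self):
        t = np.array([0.0, 0.1, 0.2])
        pos = np.zeros((3, 3))
        pos[:, 0] = t
        with pytest.raises(kin.UnusableTrajectoryError):
            kin.fit_spline_and_resample(kin.RawTrajectory("p", 1, t, pos, 10), 60)

    def test_non_monotone_times_rejected(self):
        t = np.array([0.0, 0.2, 0.1, 0.3])
        pos = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(kin.InputError):
            kin.RawTrajectory("p", 1, t, pos, 10)


class TestCurvature:
    def test_closed_forms(self):
        # circle of radius 2: rho = 0.5; straight line: rho = 0; helix (1,1): 0.5
        t = np.linspace(0, 2 * np.pi, 200)
        v_circ = np.c_[-2 * np.sin(t), 2 * np.cos(t), np.zeros_like(t)]
        a_circ = np.c_[-2 * np.cos(t), -2 * np.sin(t), np.zeros_like(t)]
        assert np.allclose(kin.compute_curvature(v_circ, a_circ), 0.5, rtol=1e-9)

        v_line = np.tile([3.0, 4.0, 0.0], (50, 1))
        a_line = np.zeros((50, 3))
        assert np.allclose(kin.compute_curvature(v_line, a_line), 0.0, atol=1e-12)

        v_helix = np.c_[-np.sin(t), np.cos(t), np.ones_like(t)]
        a_helix = np.c_[-np.cos(t), -np.sin(t), np.zeros_like(t)]
        assert np.allclose(kin.compute_curvature(v_helix, a_helix), 0.5, rtol=1e-9)

    def test_decomposition_identities(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(100, 3))
        a = rng.normal(size=(100, 3))
        curv, a_t, a_n, valid = kin.compute_curvature(v, a, full=True)
        assert valid.all()
        # a_t + a_n reconstructs a; a_n orthogonal to v; rho >= 0
        assert np.allclose(a_t + a_n, a, rtol=1e-9)
        dots = np.einsum("ij,ij->i", a_n, v)
        scale = np.linalg.norm(a_n, axis=1) * np.linalg.norm(v, axis=1)
        assert np.max(np.abs(dots) / np.maximum(scale, 1e-300)) < 1e-9
        assert (curv >= 0).all()

    def test_rigid_motion_invariance(self):
        # curvature is invariant under rotation + translation of the path
        rng = np.random.default_rng(2)
        raw = smooth_raw_trajectory("p", 1, 0.0, 1.0, seed=5)
        base = kin.fit_spline_and_resample(raw, 180).curvature
        for _ in range(3):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            moved = kin.RawTrajectory(
                "p", 1, raw.times, raw.positions @ q.T + rng.normal(size=3),
                raw.native_rate)
            rotated = kin.fit_spline_and_resample(moved, 180).curvature
            assert np.allclose(rotated, base, rtol=1e-9, atol=1e-12)

    def test_scaling_and_time_shift(self):
        raw = smooth_raw_trajectory("p", 1, 0.0, 1.0, seed=6)
        base = kin.fit_spline_and_resample(raw, 180).curvature
        s = 2.5  # spatial scaling by s scales curvature by 1/s
        scaled = kin.RawTrajectory("p", 1, raw.times, raw.positions * s,
                                   raw.native_rate)
        assert np.allclose(kin.fit_spline_and_resample(scaled, 180).curvature,
                           base / s, rtol=1e-9)
        shifted = kin.RawTrajectory("p", 1, raw.times + 7.0, raw.positions,
                                    raw.native_rate)
        assert np.allclose(kin.fit_spline_and_resample(shifted, 180).curvature,
                           base, rtol=1e-9, atol=1e-12)

    def test_slow_samples_marked_invalid(self):
        v = np.zeros((5, 3))
        v[2] = [1.0, 0, 0]
        a = np.ones((5, 3))
        curv, _, _, valid = kin.compute_curvature(v, a, full=True)
        assert valid.tolist() == [False, False, True, False, False]
        assert np.isnan(curv[0]) and np.isfinite(curv[2])


class TestOverlap:
    def test_trim_to_intersection(self):
        raw1 = smooth_raw_trajectory("p", 1, 0.0, 1.5, seed=1)
        raw2 = smooth_raw_trajectory("p", 2, 0.3, 2.0, seed=2)
        rec = kin.make_pair_record(raw1, raw2, 180)
        assert rec.overlap[0] == pytest.approx(0.3)
        assert rec.overlap[1] <= 1.5
        assert len(rec.series_1) == len(rec.series_2)
        trimmed = kin.extract_overlap(rec)
        assert len(trimmed.series_1) == len(rec.series_1)  # already aligned

    def test_extract_overlap_idempotent(self):
        rec = pair_record_with_overlap_length("p", 200, seed=4)
        once = kin.extract_overlap(rec)
        twice = kin.extract_overlap(once)
        assert np.array_equal(once.series_1.times, twice.series_1.times)
        assert np.array_equal(once.series_2.curvature, twice.series_2.curvature,
                              equal_nan=True)

    def test_disjoint_spans_excluded(self):
        raw1 = smooth_raw_trajectory("p", 1, 0.0, 0.5, seed=1)
        raw2 = smooth_raw_trajectory("p", 2, 1.0, 1.5, seed=2)
        with pytest.raises(kin.OverlapError):
            kin.make_pair_record(raw1, raw2, 180)


class TestEnsemble:
    def test_concatenation_accounting(self):
        # overlap lengths 100, 50, 70 -> length 220, segment bounds [0, 100, 150]
        pairs = [pair_record_with_overlap_length("a", 100, seed=10),
                 pair_record_with_overlap_length("b", 50, seed=20),
                 pair_record_with_overlap_length("c", 70, seed=30)]
        e1, e2 = kin.concatenate_ensemble(pairs, "curvature")
        assert len(e1) == len(e2) == 220
        assert e1.segment_bounds.tolist() == [0, 100, 150]
        assert e2.segment_bounds.tolist() == [0, 100, 150]
        # boundary mask: transitions out of each segment's last sample
        assert e1.boundary_mask().tolist() == [99, 149, 219]

    def test_single_pair_identity(self):
        rec = pair_record_with_overlap_length("a", 80, seed=11)
        e1, _ = kin.concatenate_ensemble([rec], "curvature")
        assert np.array_equal(e1.values, rec.series_1.curvature)

    def test_velocity_ensemble_is_3d(self):
        rec = pair_record_with_overlap_length("a", 60, seed=12)
        e1, e2 = kin.concatenate_ensemble([rec], "velocity")
        assert e1.values.shape == (60, 3) and e2.values.shape == (60, 3)

    def test_pair_order_is_by_id(self):
        pa = pair_record_with_overlap_length("a", 40, seed=13)
        pb = pair_record_with_overlap_length("b", 40, seed=14)
        e_ab, _ = kin.concatenate_ensemble([pa, pb], "curvature")
        e_ba, _ = kin.concatenate_ensemble([pb, pa], "curvature")
        assert np.array_equal(e_ab.values, e_ba.values)


class TestNormalize:
    def test_affine_standardization(self):
        ens = kin.EnsembleSeries(np.array([1.0, 2.0, 3.0]), np.array([0]), "x")
        out = kin.normalize(ens)
        assert out.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values.var(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert out.normalized

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=500)
        v = (v - v.mean()) / v.std(ddof=1)
        ens = kin.EnsembleSeries(v, np.array([0]), "x")
        out = kin.normalize(ens)
        assert np.allclose(out.values, v, atol=1e-12)

    def test_constant_series_rejected(self):
        ens = kin.EnsembleSeries(np.ones(10), np.array([0]), "x")
        with pytest.raises(kin.ZeroVarianceError):
            kin.normalize(ens)

    def test_per_segment_scope(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(5, 2, 50), rng.normal(-3, 0.5, 60)])
        ens = kin.EnsembleSeries(v, np.array([0, 50]), "x", pair_ids=("a", "b"))
        out = kin.normalize(ens, scope="per_segment")
        for lo, hi in ((0, 50), (50, 110)):
            assert out.values[lo:hi].mean() == pytest.approx(0.0, abs=1e-9)
            assert out.values[lo:hi].var(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestDerivedCsvOutputs:
    def test_kinematics_csv_columns(self, tmp_path):
        rec = pair_record_with_overlap_length("a", 50, seed=21)
        path = tmp_path / "kin.csv"
        kin.write_kinematics_csv(rec.series_1, path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == ["t", "x", "y", "z", "vx", "vy", "vz",
                          "ax", "ay", "az", "speed", "curvature"]
        assert len(path.read_text().splitlines()) == 51

    def test_ensemble_csv_has_segment_column(self, tmp_path):
        pairs = [pair_record_with_overlap_length("a", 30, seed=22),
                 pair_record_with_overlap_length("b", 20, seed=23)]
        e1, _ = kin.concatenate_ensemble(pairs, "curvature")
        path = tmp_path / "ens.csv"
        kin.write_ensemble_csv(e1, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "segment,curvature"
        segments = [int(l.split(",")[0]) for l in lines[1:]]
        assert segments == [0] * 30 + [1] * 20


class TestCsvRoundTrip:
    def test_write_read_write_byte_identical(self, tmp_path):
        trajs = [smooth_raw_trajectory("P000", 1, 0.0, 0.5, seed=1),
                 smooth_raw_trajectory("P000", 2, 0.2, 0.7, seed=2),
                 smooth_raw_trajectory("P001", 1, 0.0, 0.6, seed=3),
                 smooth_raw_trajectory("P001", 2, 0.1, 0.8, seed=4)]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        kin.write_trajectories(trajs, p1)
        back = kin.read_trajectories(p1)
        assert len(back) == 4
        kin.write_trajectories(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_text().splitlines()[0] == "pair_id,agent,t,x,y,z,behavior"
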