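"""Reconstruction-offset metrics, anatomical frames, knee angles, phases."""

import numpy as np
import pytest

import clusterpose as cp
from clusterpose import InvalidInputError
from clusterpose.metrics import (
    AnatomicalFrame,
    afoo,
    alro,
    anatomical_frame,
    config_spread,
    ero,
    kao,
    knee_angle_series,
    knee_angles,
    phase_partition,
    reconstruct_landmarks,
    summarize,
    tro,
)
from tests.test_rigid_core import random_rotation

RNG = np.random.default_rng(31)


class TestPointOffsets:
    def test_tro_zero_for_identical_series(self):
        t = RNG.normal(size=(10, 3))
        assert np.all(tro(t, t).values == 0)

    def test_tro_three_four_five(self):
        t = np.zeros((5, 3))
        np.testing.assert_allclose(
            tro(t, t + np.array([0.03, 0.04, 0.0])).values, 0.05, atol=1e-15
        )

    def test_tro_matches_per_step_norm(self):
        a, b = RNG.normal(size=(8, 3)), RNG.normal(size=(8, 3))
        expected = [np.sqrt(sum((a[i, k] - b[i, k]) ** 2 for k in range(3))) for i in range(8)]
        np.testing.assert_allclose(tro(a, b).values, expected, rtol=1e-14)

    def test_alro_mirrors_tro(self):
        a, b = RNG.normal(size=(6, 3)), RNG.normal(size=(6, 3))
        np.testing.assert_array_equal(alro(a, b, "FH").values, tro(a, b).values)
        assert alro(a, b, "FH").name == "ALRO:FH"


class TestEro:
    def test_identical_and_orthogonal(self):
        e = np.tile([1.0, 0, 0], (4, 1))
        assert np.all(ero(e, e, 1).values == 0)
        f = np.tile([0.0, 1, 0], (4, 1))
        np.testing.assert_allclose(ero(e, f, 1).values, 90.0)

    def test_rounding_above_one_clipped(self):
        v = np.array([[1.0, 1e-16, 0.0]])
        v_norm = v / np.linalg.norm(v) * (1 + 1e-16)
        assert ero(np.array([[1.0, 0, 0]]), v_norm, 1).values[0] == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_sign_flips(self):
        a = RNG.normal(size=(5, 3))
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        b = RNG.normal(size=(5, 3))
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        base = ero(a, b, 2).values
        np.testing.assert_allclose(ero(-a, b, 2).values, base, atol=1e-12)
        np.testing.assert_allclose(ero(-a, -b, 2).values, base, atol=1e-12)


class TestReconstructLandmarks:
    def test_ground_truth_pose_reproduces_landmarks(self, clean_trial):
        k = clean_trial.calibration_frame
        r_cal = clean_trial.true_rotations[k]
        t_cal = clean_trial.true_translations[k]
        r_ref = np.einsum("tij,kj->tik", clean_trial.true_rotations, r_cal)
        t_ref = clean_trial.true_translations - np.einsum("tij,j->ti", r_ref, t_cal)
        cal_lm = {n: p[k] for n, p in clean_trial.true_landmarks.items()}
        rec = reconstruct_landmarks(cal_lm, r_ref, t_ref)
        for name in cal_lm:
            np.testing.assert_allclose(rec[name], clean_trial.true_landmarks[name], atol=1e-12)

    def test_identity_and_pure_translation(self):
        lm = {"A": np.array([0.1, 0.2, 0.3])}
        n = 4
        eye = np.tile(np.eye(3), (n, 1, 1))
        zero = np.zeros((n, 3))
        np.testing.assert_array_equal(reconstruct_landmarks(lm, eye, zero)["A"][0], lm["A"])
        shift = np.tile([1.0, -2.0, 0.5], (n, 1))
        np.testing.assert_allclose(
            reconstruct_landmarks(lm, eye, shift)["A"] - lm["A"], shift, atol=1e-15
        )


class TestAnatomicalFrame:
    @pytest.mark.parametrize("segment", ["thigh", "shank"])
    def test_template_frame_aligns_with_segment_axes(self, segment):
        f = cp.build_frustum(segment)
        frame = anatomical_frame(f.landmarks, segment)
        np.testing.assert_allclose(frame.axes, np.eye(3), atol=1e-9)

    def test_equivariance_under_rigid_transform(self):
        f = cp.build_frustum("thigh")
        base = anatomical_frame(f.landmarks, "thigh")
        r = random_rotation(RNG)
        t = RNG.normal(size=3)
        moved = anatomical_frame({n: r @ p + t for n, p in f.landmarks.items()}, "thigh")
        np.testing.assert_allclose(moved.axes, r @ base.axes, atol=1e-12)
        np.testing.assert_allclose(moved.origin, r @ base.origin + t, atol=1e-12)

    def test_always_proper_rotation(self):
        f = cp.build_frustum("shank")
        for _ in range(10_000):
            r = random_rotation(RNG)
            t = RNG.normal(size=3)
            frame = anatomical_frame({n: r @ p + t for n, p in f.landmarks.items()}, "shank")
            assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_landmarks_rejected(self):
        lm = {"ME": np.zeros(3), "LE": np.zeros(3), "FH": np.array([0.0, 0, 1])}
        with pytest.raises(InvalidInputError):
            anatomical_frame(lm, "thigh")


def _frame(r=np.eye(3), o=np.zeros(3)):
    return AnatomicalFrame(o, np.asarray(r, dtype=float))


def _rot_y(deg):
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_x(deg):
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(deg):
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestKneeAngles:
    def test_identical_frames_zero(self):
        fe, aa, ie, gimbal = knee_angles(_frame(), _frame())
        assert (fe, aa, ie) == (0.0, 0.0, 0.0) and not gimbal

    def test_single_axis_rotations_map_to_single_angles(self):
        fe, aa, ie, _ = knee_angles(_frame(), _frame(_rot_y(30)))
        assert (fe, aa, ie) == pytest.approx((30.0, 0.0, 0.0), abs=1e-9)
        fe, aa, ie, _ = knee_angles(_frame(), _frame(_rot_x(10)))
        assert (fe, aa, ie) == pytest.approx((0.0, 10.0, 0.0), abs=1e-9)
        fe, aa, ie, _ = knee_angles(_frame(), _frame(_rot_z(-20)))
        assert (fe, aa, ie) == pytest.approx((0.0, 0.0, -20.0), abs=1e-9)

    def test_round_trip_recomposition(self):
        for _ in range(50):
            fe0, aa0, ie0 = RNG.uniform(-60, 60), RNG.uniform(-40, 40), RNG.uniform(-60, 60)
            r = _rot_y(fe0) @ _rot_x(aa0) @ _rot_z(ie0)
            fe, aa, ie, _ = knee_angles(_frame(), _frame(r))
            assert (fe, aa, ie) == pytest.approx((fe0, aa0, ie0), abs=1e-10)

    def test_gimbal_flagged(self):
        *_, gimbal = knee_angles(_frame(), _frame(_rot_x(90)))
        assert gimbal


class TestFrameOffsets:
    def test_afoo_zero_and_constant_shift(self):
        frames = [_frame(o=np.array([0.1 * i, 0, 0])) for i in range(5)]
        assert np.all(afoo(frames, frames).values == 0)
        shifted = [_frame(o=f.origin + np.array([0.01, 0, 0])) for f in frames]
        np.testing.assert_allclose(afoo(frames, shifted).values, 0.01, atol=1e-15)

    def test_afoo_zero_when_tro_and_ero_zero(self):
        f = cp.build_frustum("thigh")
        frames = [anatomical_frame(f.landmarks, "thigh")] * 3
        assert np.all(afoo(frames, [f_ for f_ in frames]).values == 0)

    def test_kao_zero_for_ground_truth_and_single_axis(self):
        tt = [_frame()] * 4
        ts = [_frame(_rot_y(20))] * 4
        series, true_angles, rec_angles = kao(tt, ts, tt, ts)
        for s in series:
            assert np.all(s.values == 0)
        np.testing.assert_allclose(true_angles[:, 0], 20.0, atol=1e-12)
        # a pure extra FE perturbation shows up in FE only
        ts_pert = [_frame(_rot_y(25))] * 4
        series, _, _ = kao(tt, ts, tt, ts_pert)
        np.testing.assert_allclose(series[0].values, 5.0, atol=1e-9)
        np.testing.assert_allclose(series[1].values, 0.0, atol=1e-9)
        np.testing.assert_allclose(series[2].values, 0.0, atol=1e-9)


class TestPhasesAndSummary:
    def test_sixty_forty_split(self):
        gc, stance, swing = phase_partition(0, 60, 100)
        assert stance.sum() == 60 and swing.sum() == 40
        assert not np.any(stance & swing)
        np.testing.assert_array_equal(stance | swing, gc)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(InvalidInputError):
            phase_partition(0, 100, 100)

    def test_constant_metrics(self):
        stance = np.zeros(10, dtype=bool)
        stance[:6] = True
        s = summarize(np.full((4, 10), 2.5), stance)
        for phase in ("GC", "StP", "SwP"):
            assert s.mean[phase] == 2.5 and s.std[phase] == 0.0
        two = summarize(np.vstack([np.full(10, 1.0), np.full(10, 3.0)]), stance)
        assert two.mean["GC"] == 2.0

    def test_matches_flat_array_oracle(self):
        vals = RNG.normal(size=(5, 20))
        stance = np.zeros(20, dtype=bool)
        stance[:12] = True
        s = summarize(vals, stance)
        assert s.mean["StP"] == pytest.approx(vals[:, :12].ravel().mean())
        assert s.std["SwP"] == pytest.approx(vals[:, 12:].ravel().std())

    def test_config_spread_zero_iff_identical_across_configs(self):
        stance = np.zeros(10, dtype=bool)
        stance[:6] = True
        vals = np.tile(RNG.normal(size=10), (4, 1))
        s = config_spread(vals, stance)
        assert all(v == 0.0 for v in s.std.values())
        vals2 = vals.copy()
        vals2[0] += 1.0
        assert config_spread(vals2, stance).std["GC"] > 0
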