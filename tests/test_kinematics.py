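"""Angle definitions, lean correction, reference-frame invariances."""

import math

import numpy as np
import pytest

from equispine import (
    ALL_VARIABLES,
    AngleErrorModel,
    LATERAL_VARIABLES,
    MarkerTrajectorySet,
    angle_error_bound,
    compute_all_variables,
    compute_spine_angles,
    lean_corrected_frame,
    mirror_lateral,
    pelvis_rotations,
    projected_spine_angle,
    segment_strides,
)
from equispine.kinematics import BodyFrameSeries
from equispine.segmentation import StrideSegmentation

from conftest import static_config, noise_free_config


def identity_frame(n: int, origin=None) -> BodyFrameSeries:
    """Body frame aligned with the lab axes (x cranial, y left, z up)."""
    return BodyFrameSeries(
        origin=np.zeros((n, 3)) if origin is None else np.broadcast_to(origin, (n, 3)).copy(),
        e_long=np.tile([1.0, 0.0, 0.0], (n, 1)),
        e_trans=np.tile([0.0, 1.0, 0.0], (n, 1)),
        e_vert=np.tile([0.0, 0.0, 1.0], (n, 1)),
        lean=np.zeros(n),
        valid=np.ones(n, dtype=bool),
    )


def dummy_seg(rate=100.0, f=1.4, n_strides=5) -> StrideSegmentation:
    period = int(round(rate / f))
    strides = [(i * period, (i + 1) * period) for i in range(n_strides)]
    return StrideSegmentation(
        strides=strides, start_side=["left"] * n_strides,
        f_hat=f, cutoff=0.7 * f, rate=rate,
    )


class TestAngleErrorBound:
    def test_back_segment_scale(self):
        assert angle_error_bound(AngleErrorModel(0.0032, 0.15)) == pytest.approx(1.2, abs=0.05)

    def test_long_segment_scale(self):
        assert angle_error_bound(AngleErrorModel(0.0032, 0.5)) == pytest.approx(0.4, abs=0.05)

    def test_error_free_limit(self):
        assert angle_error_bound(AngleErrorModel(0.0, 0.15)) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            angle_error_bound(AngleErrorModel(0.003, 0.0))


class TestProjectedAngle:
    def test_collinear_is_zero(self):
        f = identity_frame(1)
        for plane in ("FE", "LB"):
            a = projected_spine_angle(
                np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]), np.array([[2.0, 0, 0]]), f, plane
            )
            assert a[0] == pytest.approx(0.0, abs=1e-12)

    def test_dorsal_midpoint_positive_fe(self):
        f = identity_frame(1)
        a = projected_spine_angle(
            np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0.1]]), np.array([[2.0, 0, 0]]), f, "FE"
        )
        # brute force: 180 - included angle at the mid point
        expected = 180.0 - math.degrees(
            math.acos(np.dot([-1, -0.1], [1, -0.1]) / (np.hypot(1, 0.1) ** 2))
        )
        assert a[0] == pytest.approx(expected, abs=1e-9)
        assert a[0] == pytest.approx(11.42, abs=0.01)

    def test_left_midpoint_positive_lb(self):
        f = identity_frame(1)
        a = projected_spine_angle(
            np.array([[0.0, 0, 0]]), np.array([[1.0, 0.1, 0]]), np.array([[2.0, 0, 0]]), f, "LB"
        )
        assert a[0] == pytest.approx(11.42, abs=0.01)

    def test_oracle_agreement_on_random_triplets(self):
        """Brute-force plane projection + arccos oracle on 1,000 triplets."""
        rng = np.random.default_rng(42)
        n = 1000
        # random body frames: arbitrary azimuth and lean
        az = rng.uniform(0, 2 * np.pi, n)
        lean = rng.uniform(-20, 20, n)
        e_long = np.column_stack([np.cos(az), np.sin(az), np.zeros(n)])
        lam = np.radians(lean)
        left0 = np.column_stack([-np.sin(az), np.cos(az), np.zeros(n)])
        e_vert = np.cos(lam)[:, None] * [0, 0, 1.0] - np.sin(lam)[:, None] * left0
        e_trans = np.cross(e_vert, e_long)
        frame = BodyFrameSeries(
            origin=rng.normal(0, 1, (n, 3)), e_long=e_long, e_trans=e_trans,
            e_vert=e_vert, lean=lean, valid=np.ones(n, bool),
        )
        pc = rng.normal(0, 1, (n, 3))
        pm = rng.normal(0, 1, (n, 3))
        pd_ = rng.normal(0, 1, (n, 3))
        for plane, axis in (("FE", e_vert), ("LB", e_trans)):
            got = projected_spine_angle(pc, pm, pd_, frame, plane)
            for i in range(n):
                # independent oracle: explicit 2-D projection, arccos + side
                basis = np.vstack([e_long[i], axis[i]])
                c2, m2, d2 = (basis @ (p[i] - frame.origin[i]) for p in (pc, pm, pd_))
                va, vb = c2 - m2, d2 - m2
                cosang = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
                mag = 180.0 - math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                chord = d2 - c2
                side = (m2[1] - c2[1]) * chord[0] - (m2[0] - c2[0]) * chord[1]
                expected = mag * (1.0 if side * chord[0] >= 0 else -1.0)
                assert got[i] == pytest.approx(expected, abs=1e-9), (plane, i)

    def test_coincident_points_undefined(self):
        f = identity_frame(1)
        p = np.array([[1.0, 0, 0]])
        out = projected_spine_angle(p, p, np.array([[2.0, 0, 0]]), f, "FE")
        assert np.isnan(out[0])


class TestStaticPoses:
    def test_whole_back_fe_of_dipped_t15(self):
        """T15 4 cm below the withers-sacrum chord: the definitional oracle
        (180 deg minus the included angle) gives the sum of the two chord
        slopes, negative for extension."""
        n = 4
        pose = {
            "withers": np.tile([0.97, 0.0, 1.35], (n, 1)),
            "T15": np.tile([0.57, 0.0, 1.31], (n, 1)),
            "tuber_sacrale": np.tile([0.0, 0.0, 1.35], (n, 1)),
        }
        f = identity_frame(n)
        a = projected_spine_angle(pose["withers"], pose["T15"], pose["tuber_sacrale"], f, "FE")
        expected = -(math.degrees(math.atan(0.04 / 0.40)) + math.degrees(math.atan(0.04 / 0.57)))
        np.testing.assert_allclose(a, expected, atol=1e-9)
        assert a[0] < 0  # extension: mid marker below the chord

    def test_pelvis_pitch_oracle(self):
        n = 2
        # mid-coxae -> sacrale vector raised 30 deg from the body line
        arm = 0.2
        t = MarkerTrajectorySet(
            {
                "withers": np.tile([1.0, 0.0, 1.0], (n, 1)),
                "tuber_sacrale": np.tile([0.0, 0.0, 1.0], (n, 1)),
                "tuber_coxae_left": np.tile(
                    [arm * math.cos(math.radians(30)), 0.125, 1.0 - arm * math.sin(math.radians(30))],
                    (n, 1),
                ),
                "tuber_coxae_right": np.tile(
                    [arm * math.cos(math.radians(30)), -0.125, 1.0 - arm * math.sin(math.radians(30))],
                    (n, 1),
                ),
            },
            rate=100.0,
        )
        f = identity_frame(n)
        rot = pelvis_rotations(t, f)
        np.testing.assert_allclose(rot["pelvis_pitch"], 30.0, atol=1e-9)
        np.testing.assert_allclose(rot["pelvis_roll"], 0.0, atol=1e-9)
        np.testing.assert_allclose(rot["pelvis_yaw"], 0.0, atol=1e-9)

    def test_rigid_yaw_changes_only_yaw(self):
        n = 2
        base = {
            "withers": np.tile([1.0, 0.0, 1.0], (n, 1)),
            "tuber_sacrale": np.tile([0.0, 0.0, 1.0], (n, 1)),
            "tuber_coxae_left": np.tile([0.1, 0.125, 0.9], (n, 1)),
            "tuber_coxae_right": np.tile([0.1, -0.125, 0.9], (n, 1)),
        }
        f = identity_frame(n)
        rot0 = pelvis_rotations(MarkerTrajectorySet(base, 100.0), f)
        # yaw the pelvis cluster 5 deg tail-right about the vertical through TS
        ang = math.radians(5.0)  # tail right = cranial axis rotated toward left
        c, s = math.cos(ang), math.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        yawed = dict(base)
        for m in ("tuber_coxae_left", "tuber_coxae_right"):
            yawed[m] = (base[m] - base["tuber_sacrale"]) @ R.T + base["tuber_sacrale"]
        rot1 = pelvis_rotations(MarkerTrajectorySet(yawed, 100.0), f)
        np.testing.assert_allclose(rot1["pelvis_yaw"] - rot0["pelvis_yaw"], 5.0, atol=1e-9)
        np.testing.assert_allclose(rot1["pelvis_roll"], rot0["pelvis_roll"], atol=1e-9)
        # projected pitch shifts by sin(p)cos(p)(1 - cos(yaw)) ~ 0.11 deg at
        # 45 deg pitch: second-order projection shortening, not crosstalk
        np.testing.assert_allclose(rot1["pelvis_pitch"], rot0["pelvis_pitch"], atol=0.15)


class TestLeanCorrection:
    def test_upright_frame_is_lab_frame(self):
        cfg = static_config(mean_offsets={"pelvis_roll": {"straight": 0.0},
                                          "body_tracking": {"straight": 0.0}})
        from equispine import generate_trial

        t = generate_trial(cfg, "h1", 1, 1, "straight", seed=0)
        seg = segment_strides(t)
        f = lean_corrected_frame(t, seg)
        np.testing.assert_allclose(f.lean, 0.0, atol=1e-9)
        np.testing.assert_allclose(f.e_vert, np.tile([0, 0, 1.0], (t.n_frames, 1)), atol=1e-12)

    def test_vertical_axis_tilted_by_lean(self, left_trial_noise_free, left_seg):
        f = lean_corrected_frame(left_trial_noise_free, left_seg)
        cosang = np.einsum("ij,j->i", f.e_vert, [0, 0, 1.0])
        np.testing.assert_allclose(np.degrees(np.arccos(np.clip(cosang, -1, 1))),
                                   np.abs(f.lean), atol=1e-9)
        # axes orthonormal, right-handed
        np.testing.assert_allclose(np.einsum("ij,ij->i", f.e_long, f.e_vert), 0, atol=1e-12)
        np.testing.assert_allclose(np.cross(f.e_long, f.e_trans), f.e_vert, atol=1e-12)

    def test_rigid_roll_of_static_pose_cancels(self):
        """Rolling the whole horse 10 deg changes no spine angle once the
        reference frame is lean-corrected (crosstalk cancellation)."""
        from equispine import generate_trial

        cfg = static_config(mean_offsets={
            "pelvis_roll": {"straight": 0.0}, "lb_whole_back": {"straight": 6.0},
        })
        t0 = generate_trial(cfg, "h1", 1, 1, "straight", seed=0)
        seg0 = segment_strides(t0)
        ref = compute_spine_angles(t0, lean_corrected_frame(t0, seg0))

        cfg10 = static_config(mean_offsets={
            "pelvis_roll": {"straight": 10.0}, "lb_whole_back": {"straight": 6.0},
        })
        t10 = generate_trial(cfg10, "h1", 1, 1, "straight", seed=0)
        seg10 = segment_strides(t10)
        rolled = compute_spine_angles(t10, lean_corrected_frame(t10, seg10))
        for name in ref:
            np.testing.assert_allclose(rolled[name], ref[name], atol=0.05, err_msg=name)

    def test_crosstalk_without_correction(self):
        """Negative control: at 15 deg roll and 10 deg lateral bending the
        uncorrected FE angle is contaminated by > 0.5 deg; the corrected one
        stays below 0.1 deg."""
        from equispine import generate_trial

        cfg = static_config(mean_offsets={
            "pelvis_roll": {"straight": 15.0},
            "lb_whole_back": {"straight": 10.0},
            "fe_whole_back": {"straight": 0.0},
        })
        t = generate_trial(cfg, "h1", 1, 1, "straight", seed=0)
        seg = segment_strides(t)
        frame = lean_corrected_frame(t, seg)
        corrected = compute_spine_angles(t, frame)["fe_whole_back"]
        assert np.nanmax(np.abs(corrected)) < 0.1

        n = t.n_frames
        uncorrected_frame = BodyFrameSeries(
            origin=frame.origin, e_long=frame.e_long,
            e_trans=np.cross(np.tile([0, 0, 1.0], (n, 1)), frame.e_long),
            e_vert=np.tile([0, 0, 1.0], (n, 1)),
            lean=np.zeros(n), valid=frame.valid,
        )
        raw = compute_spine_angles(t, uncorrected_frame)["fe_whole_back"]
        assert np.nanmax(np.abs(raw)) > 0.5

    def test_window_saturation_gives_trial_mean(self):
        from equispine import generate_trial

        cfg = noise_free_config(trial_duration={"left": 4.0, "straight": 16.0, "right": 25.0})
        t = generate_trial(cfg, "h1", 1, 1, "left", seed=0)
        seg = dummy_seg(n_strides=1)
        seg.strides = [(0, t.n_frames)]  # window longer than the trial
        f = lean_corrected_frame(t, seg)
        from equispine.kinematics import pelvis_roll_lab

        mid = t.n_frames // 2
        # symmetric shrinking may drop a single edge sample of the window
        assert f.lean[mid] == pytest.approx(np.mean(pelvis_roll_lab(t)), abs=0.05)


class TestFrameInvariances:
    def test_lab_rotation_and_translation_invariance(self, left_trial_noise_free, left_seg):
        t = left_trial_noise_free
        base = compute_all_variables(t, left_seg)
        ang = np.radians(63.0)
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        shift = np.array([-7.0, 11.0, 0.4])
        moved = t.transformed(lambda p: p @ R.T + shift)
        seg2 = segment_strides(moved)
        out = compute_all_variables(moved, seg2)
        for name in ALL_VARIABLES:
            np.testing.assert_allclose(out[name], base[name], atol=1e-6, err_msg=name)

    def test_mirror_antisymmetry(self, left_trial_noise_free, left_seg):
        t = left_trial_noise_free
        base = compute_all_variables(t, left_seg)
        m = mirror_lateral(t)
        seg2 = segment_strides(m)
        out = compute_all_variables(m, seg2)
        for name in ALL_VARIABLES:
            sign = -1.0 if name in LATERAL_VARIABLES else 1.0
            np.testing.assert_allclose(out[name], sign * base[name], atol=1e-6, err_msg=name)


class TestHeadAndTracking:
    def test_head_on_axis_zero_swivel(self):
        n = 10
        t = MarkerTrajectorySet(
            {
                "withers": np.tile([1.0, 0, 1.4], (n, 1)),
                "head": np.tile([1.6, 0, 1.7], (n, 1)),
                "tuber_sacrale": np.column_stack(
                    [np.arange(n) * 0.03, np.zeros(n), np.full(n, 1.35)]
                ),
            },
            rate=100.0,
        )
        f = identity_frame(n)
        out = __import__("equispine").head_swivel_and_tracking(t, f)
        np.testing.assert_allclose(out["head_swivel"], 0.0, atol=1e-9)

    def test_straight_line_speed_and_tracking(self):
        n = 200
        v = 3.0
        x = np.arange(n) / 100.0 * v
        t = MarkerTrajectorySet(
            {
                "withers": np.column_stack([x + 1.0, np.zeros(n), np.full(n, 1.4)]),
                "head": np.column_stack([x + 1.6, np.zeros(n), np.full(n, 1.7)]),
                "tuber_sacrale": np.column_stack([x, np.zeros(n), np.full(n, 1.35)]),
            },
            rate=100.0,
        )
        f = identity_frame(n)
        out = __import__("equispine").head_swivel_and_tracking(t, f)
        np.testing.assert_allclose(out["speed"][2:-2], v, atol=1e-9)
        np.testing.assert_allclose(out["body_tracking"][2:-2], 0.0, atol=1e-9)

    def test_circular_speed_omega_r(self, left_trial_noise_free, left_seg):
        out = compute_all_variables(left_trial_noise_free, left_seg)
        # v = omega * r = 3.31 on the default left circle (the stride-window
        # smoothing shaves < 1.5% off the chord speed)
        core = slice(200, -200)
        assert np.nanmean(out["speed"][core]) == pytest.approx(3.31, rel=0.015)
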