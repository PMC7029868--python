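"""Geometric oracles for the kinematic feature model."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from signkin import kinematics as K
from signkin.containers import LANDMARK_INDEX
from signkin.errors import SingularGeometryError
from signkin.synthetic_data import forward_kinematics

from conftest import (
    make_recording,
    neutral_hand_positions,
    positions_dict_to_array,
    simple_trajectories,
)


def _transform(lm: dict, R=np.eye(3), t=np.zeros(3)) -> dict:
    return {name: R @ pos + t for name, pos in lm.items()}


class TestHandFrame:
    def test_axis_aligned_pose_gives_identity_frame(self, neutral_landmarks):
        frame = K.build_hand_frame(neutral_landmarks)
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(frame.origin, neutral_landmarks["PALM"])

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_transform_equivariance(self, neutral_landmarks, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-100, 100, 3)
        frame = K.build_hand_frame(_transform(neutral_landmarks, R, t))
        np.testing.assert_allclose(frame.rotation, R @ np.eye(3), atol=1e-9)

    def test_coincident_knuckles_raise(self, neutral_landmarks):
        lm = dict(neutral_landmarks)
        lm["M2"] = lm["M5"]
        with pytest.raises(SingularGeometryError):
            K.build_hand_frame(lm)


class TestForearmFrame:
    def test_axis_aligned_pose_gives_identity_frame(self, neutral_landmarks):
        frame = K.build_forearm_frame(neutral_landmarks)
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(frame.origin, neutral_landmarks["WR"])

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_transform_equivariance(self, neutral_landmarks, seed):
        rng = np.random.default_rng(seed + 100)
        R = Rotation.random(rng=rng).as_matrix()
        frame = K.build_forearm_frame(_transform(neutral_landmarks, R))
        np.testing.assert_allclose(frame.rotation, R, atol=1e-9)

    def test_coincident_elbow_and_styloid_raise(self, neutral_landmarks):
        lm = dict(neutral_landmarks)
        lm["EL"] = lm["US"]
        with pytest.raises(SingularGeometryError):
            K.build_forearm_frame(lm)


class TestWristAngles:
    def _frames(self, rel_rotation):
        fore = K.CoordinateFrame(
            X=[1, 0, 0], Y=[0, 1, 0], Z=[0, 0, 1], origin=[0, 0, 0]
        )
        R = rel_rotation
        hand = K.CoordinateFrame(X=R[:, 0], Y=R[:, 1], Z=R[:, 2], origin=[0, 0, 0])
        return hand, fore

    def test_identical_frames_give_zero(self):
        hand, fore = self._frames(np.eye(3))
        assert K.wrist_angles(hand, fore) == (0.0, 0.0)

    def test_pure_z_rotation_reads_as_flexion(self):
        R = Rotation.from_euler("Z", 30, degrees=True).as_matrix()
        hand, fore = self._frames(R)
        flexion, deviation = K.wrist_angles(hand, fore)
        np.testing.assert_allclose([flexion, deviation], [30.0, 0.0], atol=1e-9)

    def test_composed_zxy_rotation_recovered(self):
        R = Rotation.from_euler("ZXY", [20, 10, 5], degrees=True).as_matrix()
        hand, fore = self._frames(R)
        flexion, deviation = K.wrist_angles(hand, fore)
        np.testing.assert_allclose([flexion, deviation], [20.0, 10.0], atol=1e-9)

    def test_gimbal_configuration_flagged(self):
        R = Rotation.from_euler("ZXY", [15, 90, 0], degrees=True).as_matrix()
        hand, fore = self._frames(R)
        (flexion, deviation), flags = K.wrist_angles(hand, fore, return_flags=True)
        assert flags["gimbal"]
        np.testing.assert_allclose(deviation, 90.0, atol=1e-6)


class TestDigitOrientation:
    def _with_finger_segment(self, lm, digit, seg):
        """Place P so that (M - P) equals ``seg`` for the given finger."""
        lm = dict(lm)
        lm[f"P{digit}"] = lm[f"M{digit}"] - np.asarray(seg, dtype=float)
        return lm

    def test_segment_antiparallel_to_y_gives_180(self, neutral_landmarks):
        lm = self._with_finger_segment(neutral_landmarks, 3, [0, -40, 0])
        alpha, phi = K.digit_orientation_angles(lm)
        assert alpha[2] == pytest.approx(180.0)
        assert abs(phi[2]) == pytest.approx(180.0)

    def test_constructed_in_plane_angle_recovered(self, neutral_landmarks):
        angle = np.deg2rad(25.0)
        seg = 40 * np.array([np.sin(angle), np.cos(angle), 0.0])
        lm = self._with_finger_segment(neutral_landmarks, 2, seg)
        alpha, _ = K.digit_orientation_angles(lm)
        assert alpha[1] == pytest.approx(25.0, abs=1e-9)

    def test_segment_along_x_is_90_and_yz_projection_degenerate(
        self, neutral_landmarks
    ):
        lm = self._with_finger_segment(neutral_landmarks, 4, [40, 0, 0])
        alpha, phi, flags = K.digit_orientation_angles(lm, return_flags=True)
        assert alpha[3] == pytest.approx(90.0)
        assert flags["phi4"] and phi[3] == 0.0

    def test_thumb_planes_swapped(self, neutral_landmarks):
        # thumb segment M1 - D1 tilted toward +Z: angle appears in alpha1
        lm = dict(neutral_landmarks)
        angle = np.deg2rad(20.0)
        lm["D1"] = lm["M1"] - 50 * np.array([0.0, np.cos(angle), np.sin(angle)])
        alpha, phi = K.digit_orientation_angles(lm)
        assert alpha[0] == pytest.approx(20.0, abs=1e-9)
        assert phi[0] == pytest.approx(0.0, abs=1e-9)


class TestLinkAngles:
    def test_straight_finger_gives_180(self, neutral_landmarks):
        beta, theta = K.link_angles(neutral_landmarks)
        np.testing.assert_allclose(beta, 180.0)
        np.testing.assert_allclose(theta, 180.0)

    def test_right_angle_bend_at_p(self, neutral_landmarks):
        lm = dict(neutral_landmarks)
        # digit 3: place D perpendicular to the proximal segment at P
        lm["D3"] = lm["P3"] + np.array([30.0, 0.0, 0.0])
        beta, _ = K.link_angles(lm)
        assert beta[1] == pytest.approx(90.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_dot_product_reference(self, seed):
        rng = np.random.default_rng(seed)
        lm = neutral_hand_positions()
        for i in range(1, 6):
            for name in (f"P{i}", f"D{i}", f"EF{i}"):
                lm[name] = lm[name] + rng.uniform(-20, 20, 3)
        beta, theta = K.link_angles(lm)

        def ref_angle(u, v):
            c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            return np.degrees(np.arccos(np.clip(c, -1, 1)))

        for j, i in enumerate(range(2, 6)):
            expected = ref_angle(lm[f"P{i}"] - lm[f"D{i}"], lm[f"P{i}"] - lm[f"M{i}"])
            assert beta[j] == pytest.approx(expected, abs=1e-9)
            expected_t = ref_angle(
                lm[f"EF{i}"] - lm[f"D{i}"], lm[f"P{i}"] - lm[f"D{i}"]
            )
            assert theta[i - 1] == pytest.approx(expected_t, abs=1e-9)
        expected_t1 = ref_angle(lm["EF1"] - lm["D1"], lm["M1"] - lm["D1"])
        assert theta[0] == pytest.approx(expected_t1, abs=1e-9)


class TestDistances:
    def test_all_tips_at_palm_give_zero(self, neutral_landmarks):
        lm = dict(neutral_landmarks)
        for i in range(1, 6):
            lm[f"EF{i}"] = lm["PALM"]
        np.testing.assert_allclose(K.ef_distances(lm), 0.0)

    def test_3_4_5_triangle(self, neutral_landmarks):
        lm = dict(neutral_landmarks)
        lm["EF1"] = np.array([3.0, 4.0, 0.0])
        lm["EF2"] = np.zeros(3)
        assert K.ef_distances(lm)[0] == pytest.approx(5.0)

    def test_matches_norm_oracle_on_random_landmarks(self):
        rng = np.random.default_rng(9)
        lm = neutral_hand_positions()
        for name in lm:
            lm[name] = rng.uniform(-100, 100, 3)
        d = K.ef_distances(lm)
        efs = [lm[f"EF{i}"] for i in range(1, 6)]
        expected = [np.linalg.norm(efs[i] - efs[i + 1]) for i in range(4)]
        expected += [np.linalg.norm(ef - lm["PALM"]) for ef in efs]
        np.testing.assert_allclose(d, expected, atol=1e-12)


class TestExtractFeatures:
    def test_output_is_t_by_60(self, recording):
        fm = K.extract_features(recording)
        assert fm.values.shape == (recording.n_frames, 60)
        assert fm.columns == K.FEATURE_COLUMNS
        assert len(set(fm.groups)) == 5

    def test_recovers_generating_angles(self):
        tr = simple_trajectories(T=35)
        rec = _bimanual(tr)
        fm = K.extract_features(rec)
        col = {name: i for i, name in enumerate(fm.columns)}
        np.testing.assert_allclose(
            fm.values[:, col["R_wrist_flex"]], tr.wrist_flexion, atol=1e-6
        )
        np.testing.assert_allclose(
            fm.values[:, col["R_wrist_dev"]], tr.wrist_deviation, atol=1e-6
        )
        for i in range(1, 6):
            np.testing.assert_allclose(
                fm.values[:, col[f"R_alpha{i}"]], tr.alpha[:, i - 1], atol=1e-6
            )
            np.testing.assert_allclose(
                fm.values[:, col[f"R_phi{i}"]], tr.phi[:, i - 1], atol=1e-6
            )
            np.testing.assert_allclose(
                fm.values[:, col[f"R_theta{i}"]], tr.theta[:, i - 1], atol=1e-6
            )
        for j, i in enumerate(range(2, 6)):
            np.testing.assert_allclose(
                fm.values[:, col[f"R_beta{i}"]], tr.beta[:, j], atol=1e-6
            )

    def test_static_recording_gives_constant_columns(self, recording):
        static = make_recording(T=10)
        static.right.positions[:] = static.right.positions[0]
        static.left.positions[:] = static.left.positions[0]
        fm = K.extract_features(static)
        assert np.all(np.ptp(fm.values, axis=0) < 1e-9)

    def test_rigid_motion_invariance(self, recording):
        rng = np.random.default_rng(3)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-200, 200, 3)
        base = K.extract_features(recording).values
        moved = make_recording(T=30)
        for seq in (moved.right, moved.left):
            seq.positions = seq.positions @ R.T + t
        np.testing.assert_allclose(
            K.extract_features(moved).values, base, atol=1e-9
        )

    def test_uniform_scaling_scales_distances_only(self, recording):
        base = K.extract_features(recording)
        scaled = make_recording(T=30)
        for seq in (scaled.right, scaled.left):
            seq.positions = seq.positions * 2.0
        fm = K.extract_features(scaled)
        dist_cols = [g in ("ef_distance", "palm_distance") for g in base.groups]
        dist_cols = np.asarray(dist_cols)
        np.testing.assert_allclose(
            fm.values[:, dist_cols], 2.0 * base.values[:, dist_cols], rtol=1e-9
        )
        np.testing.assert_allclose(
            fm.values[:, ~dist_cols], base.values[:, ~dist_cols], atol=1e-9
        )

    def test_matches_per_frame_composition(self, recording):
        """Refactoring oracle: whole-sequence path == frame-by-frame path."""
        fm = K.extract_features(recording)
        seq = recording.right
        for t in (0, 7, 29):
            lm = {
                name: seq.positions[t, i]
                for name, i in LANDMARK_INDEX.items()
            }
            d = K.ef_distances(lm)
            hand = K.build_hand_frame(lm)
            fore = K.build_forearm_frame(lm)
            flex, dev = K.wrist_angles(hand, fore)
            alpha, phi = K.digit_orientation_angles(lm, hand)
            beta, theta = K.link_angles(lm)
            row = np.concatenate([d, [flex, dev], alpha, phi, beta, theta])
            np.testing.assert_allclose(fm.values[t, :30], row, atol=1e-9)

    def test_singular_frame_reported_with_index(self):
        rec = make_recording(T=10)
        idx = LANDMARK_INDEX["M2"]
        rec.right.positions[4, idx] = rec.right.positions[
            4, LANDMARK_INDEX["M5"]
        ]
        with pytest.raises(SingularGeometryError, match="frame 4"):
            K.extract_features(rec)


def _bimanual(tr):
    from signkin.containers import SignRecording, SkeletonSequence

    right = forward_kinematics(tr, hand="right", subject_id="S0", sign_label="x")
    left = SkeletonSequence(
        subject_id="S0",
        sign_label="x",
        hand="left",
        positions=right.positions + np.array([0.0, 0.0, -250.0]),
    )
    return SignRecording(subject_id="S0", sign_label="x", left=left, right=right)
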