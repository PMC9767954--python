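"""Geometric primitives and the 23-feature battery."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from handscreen import registry
from handscreen.errors import DegenerateGeometryError
from handscreen.geometry import (angle_between, compute_features,
                                 euclid_distance, joint_angle,
                                 palmar_abduction_angle, standardize_distance,
                                 tip_distance, webspace_angle)
from handscreen.landmarks import HandLandmarkSet, mirror_hand
from handscreen.synthetic import HandSkeleton, PoseParameters, forward_kinematics


class TestPrimitives:
    @pytest.mark.parametrize("v1, v2, expected", [
        ((1, 0, 0), (1, 0, 0), 0.0),
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (1, 1, 0), 45.0),
        ((1, 0, 0), (-1, 0, 0), 180.0),
    ])
    def test_angle_between_analytic(self, v1, v2, expected):
        assert angle_between(np.array(v1, float), np.array(v2, float)) == pytest.approx(expected, abs=1e-12)

    def test_angle_between_zero_vector_raises(self):
        with pytest.raises(DegenerateGeometryError, match="zero-length"):
            angle_between(np.zeros(3), np.ones(3))

    @pytest.mark.parametrize("p1, p2, expected", [
        ((0, 0, 0), (1, 2, 2), 3.0),
        ((1, 1, 1), (1, 1, 1), 0.0),
        ((1, 1, 1), (2, 2, 2), np.sqrt(3)),
    ])
    def test_euclid_distance_analytic(self, p1, p2, expected):
        assert euclid_distance(np.array(p1, float), np.array(p2, float)) == pytest.approx(expected)

    @pytest.mark.parametrize("d, s, expected", [(2.0, 2.0, 1.0), (0.0, 5.0, 0.0), (4.0, 2.0, 2.0)])
    def test_standardize_distance(self, d, s, expected):
        assert standardize_distance(d, s) == expected

    def test_standardize_by_zero_raises(self):
        with pytest.raises(DegenerateGeometryError):
            standardize_distance(1.0, 0.0)


class TestJointAngles:
    def test_straight_chain_reads_zero(self, flat_hand):
        from handscreen.geometry import JOINT_LANDMARKS

        for joint in JOINT_LANDMARKS:
            assert joint_angle(flat_hand, joint) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("joint, angle", [
        ("index_MCP", 19.02),   # a reported target-group mean as set-point
        ("ring_PIP", 13.81),
        ("thumb_IP", 40.0),
        ("little_DIP", 13.70),
    ])
    def test_forward_kinematic_round_trip(self, skeleton, joint, angle):
        pose = PoseParameters(flexion={joint: angle})
        lms = forward_kinematics(skeleton, pose)
        assert joint_angle(lms, joint) == pytest.approx(angle, abs=1e-6)

    def test_flexing_strictly_increases_angle(self, skeleton):
        sweep = [joint_angle(forward_kinematics(
            skeleton, PoseParameters(flexion={"index_MCP": a})), "index_MCP")
            for a in np.linspace(2, 80, 12)]
        assert np.all(np.diff(sweep) > 0)

    def test_unknown_joint_raises(self, flat_hand):
        with pytest.raises(DegenerateGeometryError, match="unknown joint"):
            joint_angle(flat_hand, "elbow")


class TestWebspace:
    def test_parallel_rays_read_zero(self):
        coords = np.zeros((21, 3))
        # fingers along +y, mutually offset in x: rays all parallel
        for base, x in [(5, 0.3), (9, 0.1), (13, -0.1), (17, -0.3)]:
            for k in range(4):
                coords[base + k] = [x, 1.0 + 0.2 * k, 0.0]
        coords[1:5] = [[0.5, 0.2 + 0.2 * k, 0.0] for k in range(4)]
        lms = HandLandmarkSet.from_array(coords, subject_id="S", hand_side="right",
                                         gesture="G2", repetition=1)
        assert webspace_angle(lms, "third") == pytest.approx(0.0, abs=1e-9)
        assert webspace_angle(lms, "fourth") == pytest.approx(0.0, abs=1e-9)

    def test_web4_target_round_trip(self, skeleton):
        # 8.33 deg: reported target-group mean for the fourth webspace
        pose = PoseParameters(
            flexion={"index_MCP": 15, "middle_MCP": 15, "ring_MCP": 15,
                     "little_MCP": 15},
            web3=4.0, web4=8.33)
        lms = forward_kinematics(skeleton, pose, gesture="G2")
        assert webspace_angle(lms, "fourth") == pytest.approx(8.33, abs=1e-6)
        assert webspace_angle(lms, "third") == pytest.approx(4.0, abs=1e-6)

    def test_abducting_little_moves_web4_not_web3(self, skeleton):
        base_flex = {"index_MCP": 15, "middle_MCP": 15, "ring_MCP": 15, "little_MCP": 15}
        webs = []
        for delta in (0.0, -4.0, -8.0):
            pose = PoseParameters(flexion=dict(base_flex),
                                  abduction={"little": delta})
            lms = forward_kinematics(skeleton, pose, gesture="G2")
            webs.append((webspace_angle(lms, "third"), webspace_angle(lms, "fourth")))
        web3s, web4s = zip(*webs)
        assert np.all(np.diff(web4s) > 0)  # moving away from the ring finger
        assert web3s[0] == web3s[1] == web3s[2]


class TestThumbFeatures:
    def test_in_plane_thumb_reads_zero_abduction(self, flat_hand):
        assert palmar_abduction_angle(flat_hand) == pytest.approx(0.0, abs=1e-9)

    def test_palmar_abduction_round_trip_and_sign(self, skeleton):
        # 19.95 deg elevation: reported non-target mean magnitude
        pose = PoseParameters(flexion={"thumb_CMC": 25, "thumb_MCP": 25, "thumb_IP": 40},
                              palmar_abduction=19.95)
        lms = forward_kinematics(skeleton, pose, gesture="G3")
        assert palmar_abduction_angle(lms) == pytest.approx(-19.95, abs=1e-6)

    def test_reducing_elevation_increases_feature(self, skeleton):
        vals = []
        for elev in (25.0, 15.0, 5.0):
            pose = PoseParameters(
                flexion={"thumb_CMC": 25, "thumb_MCP": 25, "thumb_IP": 40},
                palmar_abduction=elev)
            vals.append(palmar_abduction_angle(forward_kinematics(skeleton, pose)))
        assert np.all(np.diff(vals) > 0)

    def test_collinear_palm_raises(self):
        coords = np.zeros((21, 3))
        coords[:, 1] = np.arange(21)  # everything on the y-axis
        lms = HandLandmarkSet.from_array(coords + [[0, 0, 0]], subject_id="S",
                                         hand_side="right", gesture="G3", repetition=1)
        with pytest.raises(DegenerateGeometryError):
            palmar_abduction_angle(lms)

    def test_tip_distance_ratio_identity_and_zero(self):
        coords = np.random.default_rng(0).normal(size=(21, 3))
        coords[3] = [0, 0, 0]
        coords[4] = [1, 0, 0]       # thumb IP-TIP length 1
        coords[8] = [1, 0, 0]       # index tip on thumb tip
        lms = HandLandmarkSet.from_array(coords, subject_id="S", hand_side="right",
                                         gesture="G3", repetition=1)
        assert tip_distance(lms) == 0.0
        coords[8] = [2, 0, 0]       # gap equal to the standard length
        lms = HandLandmarkSet.from_array(coords, subject_id="S", hand_side="right",
                                         gesture="G3", repetition=1)
        assert tip_distance(lms) == pytest.approx(1.0)

    def test_tip_distance_scale_invariant(self, skeleton):
        pose = PoseParameters(flexion={"index_MCP": 30, "index_PIP": 55, "index_DIP": 35,
                                       "thumb_CMC": 28, "thumb_MCP": 25, "thumb_IP": 40})
        lms = forward_kinematics(skeleton, pose, gesture="G3")
        doubled = HandLandmarkSet.from_array(
            2.0 * lms.as_array(), subject_id="S", hand_side="right",
            gesture="G3", repetition=1)
        assert tip_distance(doubled) == pytest.approx(tip_distance(lms), abs=1e-12)


class TestFeatureBattery:
    @pytest.mark.parametrize("gesture, n_features", [("G1", 5), ("G2", 8), ("G3", 10)])
    def test_exact_feature_set_per_gesture(self, skeleton, gesture, n_features):
        pose = PoseParameters(flexion={"index_MCP": 20, "index_PIP": 50, "index_DIP": 30,
                                       "thumb_CMC": 25, "thumb_MCP": 20, "thumb_IP": 35})
        lms = forward_kinematics(skeleton, pose, gesture=gesture)
        fv = compute_features(lms)
        assert list(fv.values) == registry.feature_names(gesture)
        assert len(fv.values) == n_features
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_flat_hand_g1_all_zero(self, flat_hand):
        fv = compute_features(flat_hand)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in fv.values.values())

    def test_g2_sum_features_exact(self, skeleton):
        pose = PoseParameters(flexion={"ring_PIP": 13.81, "ring_DIP": 13.05,
                                       "little_PIP": 12.46, "little_DIP": 13.70})
        lms = forward_kinematics(skeleton, pose, gesture="G2")
        fv = compute_features(lms)
        assert fv["ag_ring"] == fv["ag_ring_PIP"] + fv["ag_ring_DIP"]
        assert fv["ag_ring"] == pytest.approx(26.86, abs=1e-6)
        assert fv["ag_little"] == fv["ag_little_PIP"] + fv["ag_little_DIP"]

    def test_g3_sums_and_signs(self, skeleton):
        pose = PoseParameters(flexion={"thumb_CMC": 28, "thumb_MCP": 24, "thumb_IP": 42,
                                       "index_MCP": 33, "index_PIP": 70, "index_DIP": 37})
        fv = compute_features(forward_kinematics(skeleton, pose, gesture="G3"))
        assert fv["ag_thumb"] == fv["ag_thumb_CMC"] + fv["ag_thumb_MCP"] + fv["ag_thumb_IP"]
        assert fv["ag_index"] == fv["ag_index_MCP"] + fv["ag_index_PIP"] + fv["ag_index_DIP"]
        for name in ("ag_thumb_CMC", "ag_thumb_MCP", "ag_thumb_IP",
                     "ag_index_MCP", "ag_index_PIP", "ag_index_DIP"):
            assert fv[name] <= 0.0
        assert fv["ag_thumb_MCP"] == pytest.approx(-24.0, abs=1e-6)

    @pytest.mark.parametrize("gesture", ["G1", "G2", "G3"])
    def test_rigid_motion_and_reflection_invariance(self, skeleton, gesture):
        pose = PoseParameters(flexion={"index_MCP": 20, "index_PIP": 45, "index_DIP": 25,
                                       "thumb_CMC": 25, "thumb_MCP": 20, "thumb_IP": 35,
                                       "ring_PIP": 12, "ring_DIP": 9})
        lms = forward_kinematics(skeleton, pose, gesture=gesture)
        base = compute_features(lms).values

        rot = Rotation.from_euler("xyz", [31.0, -17.0, 59.0], degrees=True)
        moved = HandLandmarkSet.from_array(
            lms.as_array() @ rot.as_matrix().T + np.array([0.4, -1.2, 2.0]),
            subject_id="S", hand_side="right", gesture=gesture, repetition=1)
        for name, val in compute_features(moved).values.items():
            assert val == pytest.approx(base[name], abs=1e-9)

        mirrored = mirror_hand(lms)  # left-handed copy of the same hand
        for name, val in compute_features(mirrored).values.items():
            assert val == pytest.approx(base[name], abs=1e-12)
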