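import copy

import numpy as np
import pytest

import condylefit as cf
from condylefit._geometry import pose_matrix
from condylefit.model import (
    _dh_from_frames,
    build_dh,
    dh_matrix,
    keypoint_array,
    straighten_initial_posture,
)

from conftest import build
from oracles import fk_sequential_oracle, rodrigues

ALL_MOBILE = {n: True for n in cf.DOF_NAMES}


class TestBuildChain:
    def test_axes_structure(self, chain_r2):
        for joint in cf.JOINTS:
            yaw = chain_r2.dof(f"{joint}-yaw").axis
            pitch = chain_r2.dof(f"{joint}-pitch").axis
            assert abs(np.linalg.norm(yaw) - 1) < 1e-12
            assert abs(np.dot(pitch, yaw)) < 1e-12
            if joint != "TiTar":
                roll = chain_r2.dof(f"{joint}-roll").axis
                assert abs(np.dot(pitch, roll)) < 1e-12

    def test_yaw_axis_from_condyles(self, fly_oblique):
        chain = build(fly_oblique, "R1")
        jl = chain.landmarks.joints["FeTi"]
        expected = (jl.condyle_b - jl.condyle_a) / np.linalg.norm(jl.condyle_b - jl.condyle_a)
        assert np.allclose(chain.dof("FeTi-yaw").axis, expected, atol=1e-12)

    def test_titar_has_no_roll(self, chain_r2):
        assert "TiTar-roll" not in chain_r2.dof_names
        assert len(chain_r2.dofs) == 14

    def test_unknown_leg_raises(self, fly_oblique):
        with pytest.raises(ValueError, match="no leg"):
            cf.build_chain(fly_oblique, "R9")

    def test_unknown_dof_in_config_raises(self, fly_oblique):
        with pytest.raises(ValueError, match="unknown DOF"):
            cf.build_chain(fly_oblique, "R2", {"TiTar-roll": True})

    def test_parallel_yaw_and_segment_raises(self, fly_orthogonal):
        fly = copy.deepcopy(fly_orthogonal)
        jl = fly.legs["R2"].joints["FeTi"]
        seg = np.array([0.0, 0.0, 1.0])  # segment direction is vertical
        jl.condyle_a = jl.center - 0.02 * seg
        jl.condyle_b = jl.center + 0.02 * seg
        with pytest.raises(ValueError, match="parallel"):
            cf.build_chain(fly, "R2")

    def test_obliquity_zero_matches_orthogonalized_axes(self, fly_orthogonal):
        chain = build(fly_orthogonal, "R3")
        ortho = cf.orthogonalize(chain)
        for name in chain.dof_names:
            assert np.allclose(chain.dof(name).axis, ortho.dof(name).axis, atol=1e-12)


class TestStraighten:
    def test_already_straight_is_identity(self, chain_r2):
        st = straighten_initial_posture(chain_r2)
        for name, adj in st.yaw_adjustments_deg.items():
            assert abs(adj) < 1e-9, name
        for j in cf.JOINTS:
            assert np.allclose(
                st.landmarks.joints[j].center, chain_r2.landmarks.joints[j].center, atol=1e-9
            )

    def test_single_bend_recovered(self, fly_oblique):
        bent = cf.make_synthetic_fly(seed=11, obliquity_deg=12.0, bend_deg={"FeTi": 30.0})
        chain = build(bent, "R2")
        st = straighten_initial_posture(chain)
        assert abs(st.yaw_adjustments_deg["FeTi-yaw"] + 30.0) < 1e-9
        assert st.straightened

    def test_zero_angles_give_collinear_segments(self):
        bent = cf.make_synthetic_fly(
            seed=3, obliquity_deg=10.0, bend_deg={"CxTr": -20.0, "FeTi": 35.0, "TiTar": 15.0}
        )
        chain = build(bent, "R2")
        st = straighten_initial_posture(chain)
        pos = cf.forward_kinematics(st)
        pts = keypoint_array(pos)
        for i in range(4):
            u = pts[i + 1] - pts[i]
            v = pts[i + 2] - pts[i + 1]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            assert cosang > 1 - 1e-9

    def test_segment_lengths_preserved(self, fly_oblique):
        bent = cf.make_synthetic_fly(seed=11, obliquity_deg=12.0, bend_deg={"TrFe": 25.0})
        chain = build(bent, "R1")
        st = straighten_initial_posture(chain)
        for seg in cf.SEGMENTS:
            assert abs(st.segment_lengths[seg] - chain.segment_lengths[seg]) < 1e-9


class TestBuildDH:
    def test_parallel_axes_case(self):
        # two parallel z-axes a distance L apart, x along the common normal
        L = 0.7
        f1 = pose_matrix([1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0])
        f2 = pose_matrix([1, 0, 0], [0, 1, 0], [0, 0, 1], [L, 0, 0])
        theta0, alpha, d, r = _dh_from_frames(f1, f2, None, 1.0)
        assert abs(d) < 1e-12
        assert abs(r - L) < 1e-12
        assert abs(theta0) < 1e-12 and abs(alpha) < 1e-12

    def test_intersecting_orthogonal_axes_case(self):
        f1 = pose_matrix([1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0])
        # z' along y, intersecting at the shared origin; x' normal to both
        f2 = pose_matrix([1, 0, 0], [0, 0, -1], [0, 1, 0], [0, 0, 0])
        theta0, alpha, d, r = _dh_from_frames(f1, f2, None, 1.0)
        assert abs(d) < 1e-12 and abs(r) < 1e-12
        assert abs(abs(alpha) - np.pi / 2) < 1e-12

    def test_transform_composition_reproduces_frames(self, fly_oblique):
        # composing the per-link transforms at zero angles must reproduce
        # every reference LCS pose
        for leg in ("R1", "L2", "R3"):
            chain = build(fly_oblique, leg)
            m = chain.frames_ref[0]
            for i, link in enumerate(chain.link_ref):
                params = chain.dh_params[i]
                t = dh_matrix(*params) if params is not None else link
                m = m @ t
                assert np.max(np.abs(m - chain.frames_ref[i + 1])) < 1e-9

    def test_lcs_orthonormal(self, chain_r2):
        for f in chain_r2.frames_ref:
            r = f[:3, :3]
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(r) - 1) < 1e-9

    def test_end_effector_duplicates_last_frame(self, chain_r2):
        assert np.allclose(
            chain_r2.frames_ref[-1][:3, :3], chain_r2.frames_ref[-2][:3, :3], atol=1e-12
        )
        assert np.allclose(chain_r2.frames_ref[-1][:3, 3], chain_r2.tarsus_tip_ref, atol=1e-12)


class TestForwardKinematics:
    def test_zero_angles_reproduce_reference(self, chain_r2):
        pos = cf.forward_kinematics(chain_r2)
        for j in cf.JOINTS:
            assert np.linalg.norm(pos[j] - chain_r2.landmarks.joints[j].center) < 1e-9
        assert np.linalg.norm(pos["Tar"] - chain_r2.tarsus_tip_ref) < 1e-9

    def test_single_feti_yaw_matches_rodrigues(self, chain_r2):
        phi = 37.0
        pos = cf.forward_kinematics(chain_r2, {"FeTi-yaw": phi})
        dof = chain_r2.dof("FeTi-yaw")
        rot = rodrigues(dof.axis, np.radians(phi))
        ref = cf.forward_kinematics(chain_r2)
        for kp in ("TiTar", "Tar"):
            expected = rot @ (ref[kp] - dof.center) + dof.center
            assert np.linalg.norm(pos[kp] - expected) < 1e-9
        for kp in ("ThCx", "CxTr", "TrFe", "FeTi"):
            assert np.linalg.norm(pos[kp] - ref[kp]) < 1e-12

    def test_rigidity_random_angles(self, fly_oblique, rng):
        chain = build(fly_oblique, "R1", mobility=ALL_MOBILE)
        ref_lengths = chain.segment_lengths
        for _ in range(25):
            angles = {n: rng.uniform(-30, 30) for n in cf.DOF_NAMES}
            pos = cf.forward_kinematics(chain, angles)
            pts = keypoint_array(pos)
            for i, seg in enumerate(cf.SEGMENTS):
                assert abs(np.linalg.norm(pts[i + 1] - pts[i]) - ref_lengths[seg]) < 1e-9

    def test_matches_sequential_oracle(self, fly_oblique, rng):
        chain = build(fly_oblique, "L3", mobility=ALL_MOBILE)
        for _ in range(25):
            angles = {n: rng.uniform(-35, 35) for n in cf.DOF_NAMES}
            a = cf.forward_kinematics(chain, angles)
            b = fk_sequential_oracle(chain, angles)
            assert max(np.linalg.norm(a[k] - b[k]) for k in a) < 1e-8

    def test_angle_sanity_bound(self, chain_r2):
        with pytest.raises(ValueError, match="360"):
            cf.forward_kinematics(chain_r2, {"FeTi-yaw": 400.0})

    def test_unknown_dof_raises(self, chain_r2):
        with pytest.raises(KeyError):
            cf.forward_kinematics(chain_r2, {"FeTi-spin": 10.0})


class TestMirrorSymmetry:
    def test_left_right_reflection(self, fly_oblique, rng):
        cr = build(fly_oblique, "R2", mobility=ALL_MOBILE)
        cl = build(fly_oblique, "L2", mobility=ALL_MOBILE)
        for _ in range(10):
            angles = {n: rng.uniform(-30, 30) for n in cf.DOF_NAMES}
            mirrored = {
                n: (-v if n.split("-")[1] in ("yaw", "roll") else v) for n, v in angles.items()
            }
            pr = cf.forward_kinematics(cr, angles)
            pl = cf.forward_kinematics(cl, mirrored)
            for k in pr:
                assert np.linalg.norm(pr[k] * np.array([1, -1, 1]) - pl[k]) < 1e-9

    def test_mirror_leg_landmarks_round_trip(self, fly_oblique):
        mirrored = cf.mirror_leg_landmarks(fly_oblique, "R2")
        stored = fly_oblique.legs["L2"]
        for j in cf.JOINTS:
            assert np.allclose(mirrored.joints[j].center, stored.joints[j].center, atol=1e-9)
        assert mirrored.side == "left"


class TestScaleToFly:
    def test_identity(self, chain_r2):
        scaled = cf.scale_to_fly(
            chain_r2,
            chain_r2.joint_centers["ThCx"],
            chain_r2.model_rWH,
            chain_r2.model_lWH,
            {k: v for k, v in chain_r2.segment_lengths.items() if k != "tarsus"},
        )
        for j in cf.JOINTS:
            assert np.allclose(
                scaled.landmarks.joints[j].center, chain_r2.landmarks.joints[j].center, atol=1e-9
            )

    def test_uniform_scaling(self, chain_r2):
        s = 1.2
        medians = {k: v * s for k, v in chain_r2.segment_lengths.items() if k != "tarsus"}
        scaled = cf.scale_to_fly(
            chain_r2,
            chain_r2.joint_centers["ThCx"] * s,
            chain_r2.model_rWH * s,
            chain_r2.model_lWH * s,
            medians,
        )
        for seg in cf.SEGMENTS:
            assert abs(scaled.segment_lengths[seg] - s * chain_r2.segment_lengths[seg]) < 1e-9
        for name in chain_r2.dof_names:
            assert np.allclose(scaled.dof(name).axis, chain_r2.dof(name).axis, atol=1e-9)

    def test_axes_stay_unit_and_orthogonal(self, chain_r2, rng):
        medians = {"coxa": 0.3, "trochanter": 0.2, "femur": 0.6, "tibia": 0.45}
        scaled = cf.scale_to_fly(
            chain_r2,
            chain_r2.joint_centers["ThCx"] + rng.normal(0, 0.05, 3),
            chain_r2.model_rWH * 1.1,
            chain_r2.model_lWH * 0.95,
            medians,
        )
        for seg, v in medians.items():
            assert abs(scaled.segment_lengths[seg] - v) < 1e-9
        for joint in cf.JOINTS:
            yaw = scaled.dof(f"{joint}-yaw").axis
            pitch = scaled.dof(f"{joint}-pitch").axis
            assert abs(np.linalg.norm(yaw) - 1) < 1e-9
            assert abs(np.dot(pitch, yaw)) < 1e-9

    def test_degenerate_triangle_raises(self, chain_r2):
        with pytest.raises(ValueError, match="degenerate"):
            cf.scale_to_fly(
                chain_r2,
                np.zeros(3),
                np.array([1.0, 0, 0]),
                np.array([2.0, 0, 0]),
                {"coxa": 0.3},
            )

    def test_nonpositive_median_raises(self, chain_r2):
        with pytest.raises(ValueError, match="> 0"):
            cf.scale_to_fly(
                chain_r2,
                chain_r2.joint_centers["ThCx"],
                chain_r2.model_rWH,
                chain_r2.model_lWH,
                {"coxa": -0.1},
            )


class TestTarsusLength:
    def test_noop(self, chain_r2):
        tip0 = cf.forward_kinematics(chain_r2)["Tar"]
        cf.set_tarsus_length(chain_r2, chain_r2.tarsus_length)
        assert np.allclose(cf.forward_kinematics(chain_r2)["Tar"], tip0, atol=1e-12)

    def test_doubling(self, chain_r2):
        L = chain_r2.tarsus_length
        pos0 = cf.forward_kinematics(chain_r2)
        cf.set_tarsus_length(chain_r2, 2 * L)
        pos1 = cf.forward_kinematics(chain_r2)
        d0 = np.linalg.norm(pos0["Tar"] - pos0["TiTar"])
        d1 = np.linalg.norm(pos1["Tar"] - pos1["TiTar"])
        assert abs(d1 - 2 * d0) < 1e-9
        assert np.allclose(pos1["TiTar"], pos0["TiTar"], atol=1e-12)

    def test_fk_tracks_per_frame_lengths(self, chain_r2, rng):
        angles = {"FeTi-yaw": 20.0, "ThCx-pitch": 5.0}
        for _ in range(10):
            L = rng.uniform(0.3, 0.8)
            cf.set_tarsus_length(chain_r2, L)
            pos = cf.forward_kinematics(chain_r2, angles)
            assert abs(np.linalg.norm(pos["Tar"] - pos["TiTar"]) - L) < 1e-9

    def test_nonpositive_raises(self, chain_r2):
        with pytest.raises(ValueError, match="positive"):
            cf.set_tarsus_length(chain_r2, 0.0)


class TestOrthogonalize:
    def test_body_axis_input_unchanged(self, fly_orthogonal):
        chain = build(fly_orthogonal, "R2")
        ortho = cf.orthogonalize(chain)
        for name in chain.dof_names:
            assert np.allclose(ortho.dof(name).axis, chain.dof(name).axis, atol=1e-12)

    def test_snaps_to_nearest_body_axis(self, fly_oblique):
        chain = build(fly_oblique, "R1")
        ortho = cf.orthogonalize(chain)
        ey = np.array([0.0, 1.0, 0.0])
        for joint in cf.JOINTS:
            axis = ortho.dof(f"{joint}-yaw").axis
            original = chain.dof(f"{joint}-yaw").axis
            assert np.allclose(np.abs(axis), ey, atol=1e-12)
            assert np.dot(axis, original) > 0  # sign preserved

    def test_segments_linearized_down(self, fly_oblique):
        bent = cf.make_synthetic_fly(seed=11, obliquity_deg=12.0, bend_deg={"FeTi": 25.0})
        chain = straighten_initial_posture(build(bent, "R2"))
        ortho = cf.orthogonalize(chain)
        pts = keypoint_array(cf.forward_kinematics(ortho))
        for i in range(5):
            seg = pts[i + 1] - pts[i]
            assert np.allclose(seg / np.linalg.norm(seg), [0, 0, -1], atol=1e-12)

    def test_segment_lengths_conserved(self, fly_oblique):
        chain = build(fly_oblique, "L1")
        ortho = cf.orthogonalize(chain)
        for seg in cf.SEGMENTS:
            assert abs(ortho.segment_lengths[seg] - chain.segment_lengths[seg]) < 1e-9


class TestMobility:
    def test_with_mobility_override(self, chain_r2):
        c2 = chain_r2.with_mobility({"TrFe-roll": True, "ThCx-roll": False})
        assert "TrFe-roll" in c2.mobile_dofs
        assert "ThCx-roll" not in c2.mobile_dofs
        # original untouched
        assert "TrFe-roll" not in chain_r2.mobile_dofs

    def test_left_leg_bounds_mirrored(self, fly_oblique):
        right = cf.make_dof_config("R2")
        left = cf.make_dof_config("L2")
        lo_r, hi_r = right["CxTr-yaw"]["bounds"]
        lo_l, hi_l = left["CxTr-yaw"]["bounds"]
        assert (lo_l, hi_l) == (-hi_r, -lo_r)
        assert left["ThCx-pitch"]["bounds"] == right["ThCx-pitch"]["bounds"]
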