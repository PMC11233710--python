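import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import simpson

import condylefit as cf
from condylefit._geometry import rotation_about_axis
from condylefit.body import compute_body_frame

from conftest import build
from oracles import simpson_oracle


class TestModelError:
    def test_identical_positions_zero(self, rng):
        p = rng.normal(size=(4, 5, 3))
        assert np.allclose(cf.model_error(p, p), 0.0)

    def test_single_displacement(self):
        a = np.zeros((1, 5, 3))
        b = a.copy()
        b[0, 2, 0] = 0.010  # 10 um along x
        assert np.allclose(cf.model_error(b, a), [10.0], atol=1e-9)

    def test_five_unit_displacements(self):
        a = np.zeros((1, 5, 3))
        b = a.copy()
        b[0, :, 1] = 0.001  # each keypoint off by 1 um
        assert np.allclose(cf.model_error(b, a), [5.0], atol=1e-9)

    def test_invariant_under_body_to_global(self, rng):
        frame = compute_body_frame(
            np.array([-0.5, 0.0, 0.1]), np.array([0, 0.25, 0.0]), np.array([0, -0.25, 0.0])
        )
        a = rng.normal(size=(3, 5, 3))
        b = a + rng.normal(0, 0.01, size=a.shape)
        assert np.allclose(cf.model_error(a, b), cf.model_error(a, b, frame), atol=1e-9)

    def test_missing_keypoint_gives_nan(self):
        a = np.zeros((2, 5, 3))
        b = a.copy()
        b[1, 0, 0] = np.nan
        err = cf.model_error(a, b)
        assert np.isfinite(err[0]) and np.isnan(err[1])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="matching"):
            cf.model_error(np.zeros((2, 5, 3)), np.zeros((3, 5, 3)))


class TestAucSimpson:
    grid = np.linspace(0.0, 1.0, 100)

    def test_constant(self):
        assert abs(cf.auc_simpson(np.full(100, 3.7)) - 3.7) < 1e-12

    def test_linear_exact(self):
        assert abs(cf.auc_simpson(self.grid) - 0.5) < 1e-12

    def test_quadratic(self):
        assert abs(cf.auc_simpson(self.grid**2) - 1.0 / 3.0) < 1e-6

    def test_cubic_exact(self):
        assert abs(cf.auc_simpson(self.grid**3) - 0.25) < 1e-12

    def test_linearity(self, rng):
        f = rng.normal(size=100)
        g = rng.normal(size=100)
        a, b = 2.3, -1.7
        lhs = cf.auc_simpson(a * f + b * g)
        rhs = a * cf.auc_simpson(f) + b * cf.auc_simpson(g)
        assert abs(lhs - rhs) < 1e-12

    def test_matches_independent_oracle(self, rng):
        for n in (99, 100, 101, 7):
            y = rng.normal(size=n)
            assert abs(cf.auc_simpson(y) - simpson_oracle(y)) < 1e-12

    def test_close_to_scipy_for_smooth_series(self):
        y = np.sin(2 * np.pi * self.grid) + 2.0
        assert abs(cf.auc_simpson(y) - simpson(y, x=self.grid)) < 1e-6

    def test_nan_raises(self):
        y = np.ones(100)
        y[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cf.auc_simpson(y)


class TestPostprocess:
    def test_feti_yaw_shifted_to_extension_convention(self):
        table = pd.DataFrame({"FeTi-yaw": [0.0, -20.0], "CxTr-yaw": [0.0, 10.0]})
        out = cf.postprocess_angles(table, "R1")
        # solver zero (fully extended) becomes 180 degrees
        assert out["FeTi-yaw"].tolist() == [180.0, 160.0]
        assert out["CxTr-yaw"].tolist() == [180.0, 190.0]

    def test_left_yaw_sign_inverted(self):
        table = pd.DataFrame({"ThCx-yaw": [10.0], "ThCx-pitch": [10.0], "ThCx-roll": [-5.0]})
        out = cf.postprocess_angles(table, "L2")
        assert out["ThCx-yaw"].iloc[0] == -10.0
        assert out["ThCx-pitch"].iloc[0] == 10.0
        assert out["ThCx-roll"].iloc[0] == 5.0

    def test_right_leg_signs_untouched(self):
        table = pd.DataFrame({"ThCx-yaw": [10.0]})
        assert cf.postprocess_angles(table, "R2")["ThCx-yaw"].iloc[0] == 10.0

    def test_left_sign_inversion_applies_before_shift(self):
        table = pd.DataFrame({"FeTi-yaw": [-20.0]})
        assert cf.postprocess_angles(table, "L1")["FeTi-yaw"].iloc[0] == 200.0

    def test_mirror_involution(self, rng):
        table = pd.DataFrame(
            {n: rng.normal(size=5) for n in ("ThCx-yaw", "ThCx-pitch", "TrFe-roll")}
        )
        twice = cf.mirror_angle_signs(cf.mirror_angle_signs(table))
        pd.testing.assert_frame_equal(twice, table)

    def test_unknown_dof_raises(self):
        with pytest.raises(ValueError, match="unknown DOF"):
            cf.postprocess_angles(pd.DataFrame({"FeTi-twist": [1.0]}), "R1")


class TestRom:
    def test_constant_angle_zero_range(self):
        summary = cf.rom({"fly1": pd.DataFrame({"FeTi-yaw": [12.0, 12.0, 12.0]})})
        assert summary.per_fly["range_deg"].iloc[0] == 0.0

    def test_sine_range_is_twice_amplitude(self):
        t = np.linspace(0, 4 * np.pi, 5000)
        summary = cf.rom({"fly1": pd.DataFrame({"ThCx-pitch": 13.0 * np.sin(t)})})
        assert abs(summary.per_fly["range_deg"].iloc[0] - 26.0) < 1e-3

    def test_single_frame_zero(self):
        summary = cf.rom({"fly1": pd.DataFrame({"FeTi-yaw": [40.0]})})
        assert summary.per_fly["range_deg"].iloc[0] == 0.0

    def test_pooled_mean_sd(self):
        summary = cf.rom(
            {
                "a": pd.DataFrame({"FeTi-yaw": [0.0, 10.0]}),
                "b": pd.DataFrame({"FeTi-yaw": [0.0, 20.0]}),
            }
        )
        row = summary.pooled.iloc[0]
        assert row["mean_range_deg"] == 15.0
        assert abs(row["sd_range_deg"] - np.std([10, 20], ddof=1)) < 1e-12
        assert row["n_flies"] == 2

    def test_empty_grouping_raises(self):
        with pytest.raises(ValueError, match="empty grouping"):
            cf.rom({})


def rigid_rotation_positions(angle_deg, n_frames=20):
    """TrFe/FeTi/TiTar stack rigidly rotated by angle_deg about a fixed axis.

    The axis lies in the femur-tibia plane (perpendicular to its normal), so
    the plane normal itself turns by exactly the rotation angle.
    """
    base = np.array([[0.0, 0.0, 0.0], [0.6, 0.0, -0.2], [0.9, 0.4, -0.5]])
    femur = base[1] - base[0]
    tibia = base[2] - base[1]
    axis = 0.7 * femur + 0.3 * tibia  # in-plane, not parallel to either segment
    axis = axis / np.linalg.norm(axis)
    out = []
    for a in np.linspace(0.0, np.radians(angle_deg), n_frames):
        out.append(base @ rotation_about_axis(axis, a).T)
    return np.stack(out)


class TestPlaneRotation:
    def test_no_motion_zero(self):
        pos = rigid_rotation_positions(0.0, n_frames=5)
        assert cf.femur_tibia_plane_rotation(pos) == 0.0

    def test_constructed_rigid_rotation(self):
        pos = rigid_rotation_positions(42.6)
        assert abs(cf.femur_tibia_plane_rotation(pos) - 42.6) < 1e-6

    def test_scale_invariance(self):
        pos = rigid_rotation_positions(30.0)
        assert abs(
            cf.femur_tibia_plane_rotation(pos) - cf.femur_tibia_plane_rotation(2.5 * pos)
        ) < 1e-9

    def test_collinear_raises(self):
        pos = np.tile(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float), (3, 1, 1))
        with pytest.raises(ValueError, match="collinear"):
            cf.femur_tibia_plane_rotation(pos)

    def test_interval_selection(self):
        pos = rigid_rotation_positions(40.0, n_frames=21)
        assert abs(cf.femur_tibia_plane_rotation(pos, (0, 11)) - 20.0) < 1e-6


class TestDofAblation:
    @pytest.fixture
    def setup(self, fly_oblique):
        chain = build(fly_oblique, "R2")
        scen = cf.simulate_walking(chain, n_steps=1, seed=13)
        return build(fly_oblique, "R2"), scen.angles_deg.iloc[:60]

    def test_full_set_difference_zero(self, setup):
        chain, angles = setup
        rng_, diff = cf.dof_ablation(chain, angles, chain.mobile_dofs)
        assert diff == 0.0

    def test_empty_subset_zero_range(self, setup):
        chain, angles = setup
        rng_, _ = cf.dof_ablation(chain, angles, [])
        assert abs(rng_) < 1e-5  # arccos noise at dot products of ~1.0

    def test_driving_subset_recovers_full_range(self, fly_oblique):
        chain = build(fly_oblique, "R2")
        n = 40
        t = np.linspace(0, 1, n)
        angles = pd.DataFrame(
            {
                name: (
                    12.0 * np.sin(2 * np.pi * t)
                    if name == "ThCx-yaw"
                    else (-25.0 + 8.0 * np.cos(2 * np.pi * t) if name == "CxTr-yaw" else np.full(n, 5.0))
                )
                for name in chain.mobile_dofs
            }
        )
        full_range = cf.femur_tibia_plane_rotation(
            np.stack(
                [
                    np.vstack(
                        [
                            cf.forward_kinematics(chain, row.to_dict())[k]
                            for k in ("TrFe", "FeTi", "TiTar")
                        ]
                    )
                    for _, row in angles.iterrows()
                ]
            )
        )
        ablated_range, diff = cf.dof_ablation(chain, angles, ["ThCx-yaw", "CxTr-yaw"])
        assert abs(ablated_range - full_range) < 1e-6
        assert abs(diff) < 1e-6

    def test_immobile_dof_raises(self, setup):
        chain, angles = setup
        with pytest.raises(ValueError, match="immobile"):
            cf.dof_ablation(chain, angles, ["TrFe-roll"])


@settings(max_examples=30, deadline=None)
@given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 1000))
def test_auc_linearity_property(a, b, seed):
    rng_ = np.random.default_rng(seed)
    f = rng_.normal(size=100)
    g = rng_.normal(size=100)
    lhs = cf.auc_simpson(a * f + b * g)
    rhs = a * cf.auc_simpson(f) + b * cf.auc_simpson(g)
    assert abs(lhs - rhs) < 1e-10
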