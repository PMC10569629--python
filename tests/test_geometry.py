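"""Geometry surrogates: kinematics, scaling, and compartment decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tfsupport as tf
from tfsupport.errors import InputError
from tfsupport.geometry import (
    DOFS,
    JOINT_RANGES,
    CompartmentGeometry,
    JointPose,
    MuscleGeometry,
    compartment_moments,
    default_pose_grid,
    knee_load_components,
    linear_scale_model,
    mtu_kinematics,
    optimize_fiber_tendon_lengths,
)


def random_poses(n, seed=0, margin=0.1):
    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(n):
        kw = {}
        for d in DOFS:
            lo, hi = JOINT_RANGES[d]
            span = hi - lo
            kw[f"q_{d}"] = rng.uniform(lo + margin * span, hi - margin * span)
        poses.append(JointPose(**kw))
    return poses


class TestKinematics:
    def test_neutral_pose_gives_reference_length(self, generic_model):
        pose = JointPose()
        for name, g in generic_model.geometry.items():
            L, _ = mtu_kinematics(pose, g)
            assert L == pytest.approx(g.ref_length, rel=1e-12)

    def test_constant_moment_arm_length_change(self):
        # r = 0.03 m constant over dq_KFE = 0.5 rad (flexor) shortens by 0.015 m
        g = MuscleGeometry(ref_length=0.4, moment_arms={"KFE": (0.03,)})
        L0, _ = mtu_kinematics(JointPose(q_KFE=0.0), g)
        L1, _ = mtu_kinematics(JointPose(q_KFE=0.5), g)
        assert L1 - L0 == pytest.approx(-0.015, abs=1e-12)

    def test_moment_arm_equals_negative_length_gradient(self, generic_model):
        # central finite differences at 100 random poses, every MTU
        h = 1e-4
        for pose in random_poses(100, seed=3):
            q = {d: np.array([pose.angle(d)]) for d in DOFS}
            for name, g in generic_model.geometry.items():
                _, r = mtu_kinematics(q, g, clamp=False)
                for d, arm in r.items():
                    qp = {k: v.copy() for k, v in q.items()}
                    qm = {k: v.copy() for k, v in q.items()}
                    qp[d] = qp[d] + h
                    qm[d] = qm[d] - h
                    Lp, _ = mtu_kinematics(qp, g, clamp=False)
                    Lm, _ = mtu_kinematics(qm, g, clamp=False)
                    fd = (Lp - Lm) / (2 * h)
                    assert abs(arm[0] + fd[0]) < 1e-4

    def test_out_of_range_pose_clamped_with_warning(self, generic_model, caplog):
        g = generic_model.geometry["vl"]
        import logging

        with caplog.at_level(logging.WARNING, logger="tfsupport.geometry"):
            L, _ = mtu_kinematics(JointPose(q_KFE=3.5), g)
        Lc, _ = mtu_kinematics(JointPose(q_KFE=JOINT_RANGES["KFE"][1]), g)
        assert L == pytest.approx(Lc)
        assert any("clamping" in rec.message for rec in caplog.records)


class TestScaling:
    def test_identity_scaling(self, generic_model):
        out = linear_scale_model(generic_model, {"pelvis": 1, "thigh": 1, "shank": 1, "foot": 1})
        for n in generic_model.mtus:
            assert out.mtus[n].lmo == generic_model.mtus[n].lmo
            assert out.geometry[n].ref_length == generic_model.geometry[n].ref_length

    def test_single_segment_proportionality(self, generic_model):
        # vl spans the thigh only: factor 1.1 scales its reference length by 1.1
        out = linear_scale_model(generic_model, {"thigh": 1.1})
        g0 = generic_model.geometry["vl"]
        assert out.geometry["vl"].ref_length == pytest.approx(1.1 * g0.ref_length)

    def test_composite_factor_for_bisegment_mtu(self, generic_model):
        # sm spans thigh (0.7) and shank (0.3)
        out = linear_scale_model(generic_model, {"thigh": 1.1, "shank": 1.0})
        k = 0.7 * 1.1 + 0.3 * 1.0
        g0 = generic_model.geometry["sm"]
        assert out.geometry["sm"].ref_length == pytest.approx(k * g0.ref_length)
        assert out.mtus["sm"].lmo == pytest.approx(k * generic_model.mtus["sm"].lmo)

    def test_nonpositive_factor_rejected(self, generic_model):
        with pytest.raises(InputError):
            linear_scale_model(generic_model, {"thigh": -1.0})

    def test_compartment_distances_scale_with_shank(self, generic_model):
        out = linear_scale_model(generic_model, {"shank": 1.2})
        assert out.compartment.d_med == pytest.approx(1.2 * generic_model.compartment.d_med)


class TestFiberTendonOptimization:
    def test_identity_when_scaled_equals_generic(self, generic_model):
        out = optimize_fiber_tendon_lengths(generic_model.copy(), generic_model,
                                            default_pose_grid(24))
        for n in generic_model.mtus:
            assert abs(out.mtus[n].lmo - generic_model.mtus[n].lmo) < 1e-6
            assert abs(out.mtus[n].lts - generic_model.mtus[n].lts) < 1e-6

    def test_uniform_scaling_recovers_proportional_lengths(self, generic_model):
        scaled = linear_scale_model(
            generic_model, {"pelvis": 1.05, "thigh": 1.05, "shank": 1.05, "foot": 1.05}
        )
        out = optimize_fiber_tendon_lengths(scaled, generic_model, default_pose_grid(24))
        for n in ("vl", "sm", "sol"):
            assert out.mtus[n].lmo == pytest.approx(1.05 * generic_model.mtus[n].lmo, rel=1e-4)
            assert out.mtus[n].lts == pytest.approx(1.05 * generic_model.mtus[n].lts, rel=1e-4)

    def test_rest_length_preserved_within_one_percent(self, generic_model):
        scaled = linear_scale_model(generic_model, {"thigh": 1.06, "shank": 0.97})
        out = optimize_fiber_tendon_lengths(scaled, generic_model, default_pose_grid(24))
        for n in generic_model.mtus:
            p_s, p_o = scaled.mtus[n], out.mtus[n]
            rest_s = p_s.lmo * np.cos(p_s.phi_o) + p_s.lts
            rest_o = p_o.lmo * np.cos(p_o.phi_o) + p_o.lts
            assert abs(rest_o - rest_s) / rest_s < 0.01

    def test_degenerate_grid_rejected(self, generic_model):
        with pytest.raises(InputError):
            optimize_fiber_tendon_lengths(generic_model.copy(), generic_model,
                                          [JointPose()])


class TestCompartmentDecomposition:
    def test_zero_force_zero_loads(self, generic_model):
        g = generic_model.geometry["sm"]
        M_k, F_ax = knee_load_components(0.0, 0.3, g)
        assert M_k == 0.0 and F_ax == 0.0

    def test_medial_force_line_gives_varus_moment(self):
        g = MuscleGeometry(ref_length=0.4, moment_arms={"KFE": (0.03,)},
                           z_offset=(-0.02,), axial_fraction=(1.0,))
        M_k, F_ax = knee_load_components(1000.0, 0.0, g)
        assert F_ax == pytest.approx(1000.0)
        assert M_k == pytest.approx(20.0)  # varus positive

    def test_force_line_through_knee_centre(self):
        g = MuscleGeometry(ref_length=0.4, moment_arms={"KFE": (0.03,)},
                           z_offset=(0.0,), axial_fraction=(0.9,))
        M_k, _ = knee_load_components(500.0, 0.2, g)
        assert M_k == 0.0

    def test_pure_couple_loads_compartments_equally(self):
        cg = CompartmentGeometry()
        med, lat = compartment_moments(5.0, 0.0, cg)
        assert med == lat == 5.0

    def test_compression_loads_both_condyles(self):
        cg = CompartmentGeometry(d_med=0.0225, d_lat=0.0225)
        med, lat = compartment_moments(0.0, 1000.0, cg)
        assert med == pytest.approx(-22.5)  # valgus about the medial point
        assert lat == pytest.approx(22.5)   # varus about the lateral point

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(M_k=st.floats(-100, 100), F_ax=st.floats(0, 5000),
           d_med=st.floats(0.01, 0.04), d_lat=st.floats(0.01, 0.04))
    def test_decomposition_identity(self, M_k, F_ax, d_med, d_lat):
        cg = CompartmentGeometry(d_med=d_med, d_lat=d_lat)
        med, lat = compartment_moments(M_k, F_ax, cg)
        assert lat - med == pytest.approx(F_ax * (d_med + d_lat), rel=1e-12, abs=1e-12)

    def test_summation_linearity(self):
        rng = np.random.default_rng(5)
        cg = CompartmentGeometry()
        Ms, Fs = rng.normal(size=(6, 10)), rng.uniform(0, 2000, size=(6, 10))
        med_sum, lat_sum = compartment_moments(Ms.sum(0), Fs.sum(0), cg)
        parts = [compartment_moments(m, f, cg) for m, f in zip(Ms, Fs)]
        assert np.allclose(sum(p[0] for p in parts), med_sum)
        assert np.allclose(sum(p[1] for p in parts), lat_sum)
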