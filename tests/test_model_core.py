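"""Hill muscle-tendon mechanics: activation dynamics, curves, equilibrium."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tfsupport as tf
from tfsupport.errors import GeometryError, InputError, ParameterError
from tfsupport.model_core import (
    DEFAULT_CURVES,
    HillCurves,
    MTUParameters,
    _residual_frame,
    emg_to_activation,
    evaluate_muscle_curves,
    evaluate_tendon_curve,
    pennation,
    solve_equilibrium,
    solve_fiber_lengths_multi,
)


def params(**kw):
    base = dict(name="m", FmMAX=1000.0, lmo=0.1, lts=0.3, phi_o=0.15)
    base.update(kw)
    return MTUParameters(**base)


class TestActivation:
    def test_zero_envelope_gives_zero_activation(self):
        a = emg_to_activation(np.zeros(200), params(), dt=0.01)
        assert np.all(a == 0.0)

    def test_unit_dc_gain_steady_state(self):
        # constant full excitation converges to activation 1 (unit DC gain),
        # and in the A -> 0- limit the nonlinearity is the identity
        p = params(A_shape=-1e-3)
        a = emg_to_activation(np.ones(600), p, dt=0.01)
        assert a[-1] == pytest.approx(1.0, abs=1e-9)

    def test_nonlinearity_endpoints_exact(self):
        for A in (-3.0, -1.5, -0.01):
            p = params(A_shape=A)
            a = emg_to_activation(np.concatenate([np.zeros(5), np.ones(800)]), p, 0.01)
            assert a[0] == 0.0
            assert a[-1] == pytest.approx(1.0, abs=1e-12)

    def test_unstable_filter_constants_rejected(self):
        with pytest.raises(ParameterError):
            params(C1=1.2)

    def test_envelope_out_of_range_rejected(self):
        with pytest.raises(InputError):
            emg_to_activation(np.array([0.1, 1.4]), params(), 0.01)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        e1=st.floats(0.0, 1.0),
        e2=st.floats(0.0, 1.0),
        c1=st.floats(-0.9, -0.05),
        c2=st.floats(-0.9, -0.05),
        A=st.floats(-3.0, -0.01),
    )
    def test_steady_state_monotone_in_envelope(self, e1, e2, c1, c2, A):
        lo, hi = sorted((e1, e2))
        p = params(C1=c1, C2=c2, A_shape=A)
        a_lo = emg_to_activation(np.full(500, lo), p, 0.01)[-1]
        a_hi = emg_to_activation(np.full(500, hi), p, 0.01)[-1]
        assert a_hi >= a_lo - 1e-12

    def test_electromechanical_delay_shifts_onset(self):
        p = params(emd=0.05)
        e = np.concatenate([np.zeros(10), np.ones(90)])
        a = emg_to_activation(e, p, dt=0.01)
        assert np.all(a[:14] == 0.0)
        assert a[20] > 0.0


class TestCurves:
    def test_optimal_isometric_point(self):
        c = evaluate_muscle_curves(1.0, 0.0)
        assert c["f_active"] == pytest.approx(1.0)
        assert c["f_passive"] == pytest.approx(0.0)
        assert c["f_velocity"] == pytest.approx(1.0)

    def test_active_curve_value_at_1p6(self):
        c = evaluate_muscle_curves(1.6, 0.0)
        assert c["f_active"] == pytest.approx(math.exp(-0.36 / 0.45), rel=1e-12)

    def test_maximal_shortening_gives_zero_force(self):
        assert evaluate_muscle_curves(1.0, -1.0)["f_velocity"] == pytest.approx(0.0)

    def test_passive_zero_at_optimal_and_increasing(self):
        l = np.linspace(1.0, 1.8, 50)
        fp = evaluate_muscle_curves(l, 0.0)["f_passive"]
        assert fp[0] == 0.0
        assert np.all(np.diff(fp) > 0)

    def test_eccentric_plateau(self):
        fv = evaluate_muscle_curves(1.0, np.array([0.0, 0.5, 5.0, 50.0]))["f_velocity"]
        assert fv[0] == pytest.approx(1.0)
        assert np.all(np.diff(fv) > 0)
        assert fv[-1] < DEFAULT_CURVES.ecc_plateau

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InputError):
            evaluate_muscle_curves(0.0, 0.0)

    def test_tendon_slack_and_buckled(self):
        assert evaluate_tendon_curve(0.0) == 0.0
        assert evaluate_tendon_curve(-0.02) == 0.0

    def test_tendon_linear_branch_value(self):
        assert evaluate_tendon_curve(0.033) == pytest.approx(37.526 * 0.033 - 0.2375, rel=1e-12)

    def test_tendon_monotone_and_continuous(self):
        e = np.linspace(-0.01, 0.06, 400)
        f = evaluate_tendon_curve(e)
        assert np.all(np.diff(f) >= 0)
        assert np.max(np.abs(np.diff(f))) < 0.02  # no jumps


class TestPennation:
    def test_zero_pennation(self):
        assert pennation(1.3, 0.0) == 0.0

    def test_definition_at_optimal_length(self):
        assert pennation(1.0, 0.2) == pytest.approx(0.2)

    def test_stretched_fibre(self):
        assert pennation(2.0, 0.1) == pytest.approx(math.asin(math.sin(0.1) / 2.0))

    def test_geometrically_impossible_rejected(self):
        with pytest.raises(GeometryError):
            pennation(0.09, 0.1)


class TestEquilibrium:
    def test_zero_strength_zero_force(self):
        p = params(strength_coeff=0.0)
        L = np.full(30, p.lmo * math.cos(p.phi_o) + p.lts * 1.01)
        st_ = solve_equilibrium(L, np.full(30, 0.9), p, 0.01)
        assert np.all(st_.F_MTU == 0.0)

    def test_rigid_tendon_limit(self):
        p = params(phi_o=0.0)
        curves = HillCurves(tendon_stiffness_scale=1e6)
        L = np.full(40, p.lmo + p.lts * 1.001)
        st_ = solve_equilibrium(L, np.full(40, 0.5), p, 0.01, curves)
        lm = st_.norm_fiber_length * p.lmo
        assert np.max(np.abs(lm - (L - p.lts))) < 1e-6

    def test_inextensible_tendon_closed_form(self):
        p = params(lts=0.0, phi_o=0.0)
        L = np.linspace(0.08, 0.12, 10)
        st_ = solve_equilibrium(L, np.full(10, 0.5), p, 0.01)
        assert np.allclose(st_.norm_fiber_length * p.lmo, L)

    def test_isometric_ceiling(self):
        # a=1 at l~m = 1: tendon transmits strength * FmMAX * cos(phi)
        p = params()
        eps1 = (DEFAULT_CURVES.c_lin + math.cos(p.phi_o)) / DEFAULT_CURVES.k_lin
        L = np.full(150, p.lmo * math.cos(p.phi_o) + p.lts * (1 + eps1))
        st_ = solve_equilibrium(L, np.ones(150), p, 0.01)
        expect = p.strength_coeff * p.FmMAX * math.cos(p.phi_o)
        assert st_.F_MTU[-1] == pytest.approx(expect, rel=5e-3)
        assert st_.norm_fiber_length[-1] == pytest.approx(1.0, abs=1e-3)

    def test_force_nonnegative_random_inputs(self):
        rng = np.random.default_rng(0)
        p = params()
        n = 60
        L = (p.lmo * math.cos(p.phi_o) + p.lts) * (1 + 0.02 * np.sin(np.linspace(0, 3, n)))
        a = np.clip(rng.random(n), 0, 1)
        st_ = solve_equilibrium(L, a, p, 0.01)
        assert np.all(st_.F_MTU >= 0.0)
        assert np.all(st_.activation <= 1.0)

    def test_matches_independent_bisection_oracle(self):
        # first-frame (isometric) solve against a brute-force bisection scan
        rng = np.random.default_rng(7)
        p = params()
        lo = math.sin(p.phi_o) + 1e-6
        for _ in range(100):
            a = rng.uniform(0.05, 1.0)
            L = p.lmo * math.cos(p.phi_o) * rng.uniform(0.7, 1.3) + p.lts * rng.uniform(0.99, 1.03)

            def resid(x):
                return float(_residual_frame(
                    np.array([x]), np.array([L]), np.array([a]),
                    np.array([p.lmo]), np.array([p.lts]),
                    np.array([math.sin(p.phi_o)]), None, 0.01, DEFAULT_CURVES)[0])

            b_lo, b_hi = lo, 2.0
            if resid(b_lo) > 0 or resid(b_hi) < 0:
                continue
            for _ in range(60):
                mid = 0.5 * (b_lo + b_hi)
                if resid(mid) < 0:
                    b_lo = mid
                else:
                    b_hi = mid
            oracle = 0.5 * (b_lo + b_hi)
            ln = solve_fiber_lengths_multi(
                np.array([[L]]), np.array([[a]]), np.array([p.lmo]),
                np.array([p.lts]), np.array([p.phi_o]), 0.01)[0, 0]
            assert abs(ln - oracle) < 1e-8

    def test_input_validation(self):
        p = params()
        with pytest.raises(InputError):
            solve_equilibrium(np.array([-0.1, 0.2]), np.array([0.5, 0.5]), p, 0.01)
        with pytest.raises(InputError):
            solve_equilibrium(np.array([0.4, 0.4]), np.array([0.5, 1.5]), p, 0.01)
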