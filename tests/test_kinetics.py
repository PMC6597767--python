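"""Closed-form FT4 kinetics: solution, asymptote, derivative, validity, Taylor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import thyrodose as td
from thyrodose.kinetics import ft4_direct_form

from conftest import draw_valid_params


class TestInhibitionFactor:
    def test_half_maximal_at_ic50(self):
        assert td.inhibition_factor(58.151, 58.151) == pytest.approx(0.5)

    def test_no_drug_no_inhibition(self):
        assert td.inhibition_factor(0.0, 40.0) == 1.0

    def test_large_dose_limit(self):
        assert td.inhibition_factor(1e6 * 40.0, 40.0) < 1e-5

    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4), st.floats(1.0, 150.0))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_dose(self, d1, delta, ic50):
        assert td.inhibition_factor(d1 + delta, ic50) < td.inhibition_factor(d1, ic50)

    def test_domain_errors(self):
        with pytest.raises(td.DomainError):
            td.inhibition_factor(-1.0, 40.0)
        with pytest.raises(td.DomainError):
            td.inhibition_factor(1.0, 0.0)


class TestFt4Solution:
    def test_published_grid_cell(self, patient2_params):
        assert td.ft4_solution(patient2_params, 35, 3) == pytest.approx(19.4, abs=0.05)

    def test_initial_value_identity(self, patient2_params):
        p = patient2_params
        assert td.ft4_solution(p, 0.0, 0.0) == pytest.approx(
            p.a / (p.c + p.a * p.c1), rel=1e-14
        )

    def test_matches_ode_integration(self, patient2_params):
        # oracle: adaptive integration of dy/dt = a*B*y - c*y^2 at d=30
        p, d = patient2_params, 30.0
        b = td.inhibition_factor(d, p.ic50)
        y0 = p.a * b / (p.c + p.a * b * p.c1)
        sol = solve_ivp(
            lambda t, y: p.a * b * y - p.c * y**2,
            (0, 7), [y0], rtol=1e-10, atol=1e-12,
        )
        y7 = sol.y[0, -1]
        assert td.ft4_solution(p, 7, d) == pytest.approx(y7, rel=1e-6)
        assert y7 == pytest.approx(21.1, abs=0.05)

    def test_overflow_safe_at_large_exponent(self, patient23_params):
        # exponent a*ic50*t/(ic50+d) ~ 708 at t=203, d=7.5: direct form blows up
        y = td.ft4_solution(patient23_params, 203, 7.5)
        assert np.isfinite(y) and y == pytest.approx(14.2, abs=0.05)

    def test_reciprocal_equals_direct_form_at_safe_exponents(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p, _ = draw_valid_params(rng)
            d = rng.uniform(0, 60)
            ab = p.a_ic50 / (p.ic50 + d)
            t = rng.uniform(0, min(600.0 / ab, 400.0))
            assert td.ft4_solution(p, t, d) == pytest.approx(
                ft4_direct_form(p, t, d), rel=1e-10
            )

    def test_validity_error_identifies_offending_point(self, patient2_params):
        p = patient2_params
        bad = td.ModelParams(a=p.a, c=1e-7, ic50=p.ic50, c1=-10.0)
        with pytest.raises(td.ValidityError) as err:
            td.ft4_solution(bad, np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert err.value.points is not None

    def test_negative_time_or_dose_rejected(self, patient2_params):
        with pytest.raises(td.DomainError):
            td.ft4_solution(patient2_params, -1.0, 0.0)
        with pytest.raises(td.DomainError):
            td.ft4_solution(patient2_params, 1.0, -1.0)


class TestAsymptote:
    def test_untreated_steady_state(self, patient2_params):
        assert td.ft4_asymptote(patient2_params, 0.0) == pytest.approx(17.3, abs=0.05)

    def test_formula_and_large_t_cross_check(self, patient16_params):
        p = patient16_params
        assert td.ft4_asymptote(p, 15.0) == pytest.approx(11.61, abs=0.01)
        assert td.ft4_asymptote(p, 15.0) == pytest.approx(
            td.ft4_solution(p, 1e6, 15.0), rel=1e-9
        )

    def test_solution_approaches_asymptote_monotonically(self, patient2_params):
        p, d = patient2_params, 10.0
        gaps = [td.ft4_solution(p, t, d) - td.ft4_asymptote(p, d)
                for t in (0, 20, 50, 100, 300, 800)]
        assert all(g > 0 for g in gaps)
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))


class TestDerivative:
    def test_negative_everywhere_for_negative_c1(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p, _ = draw_valid_params(rng)
            d = rng.uniform(0, 60)
            ab = p.a_ic50 / (p.ic50 + d)
            t = rng.uniform(0, 15.0) / ab  # before the tail flattens to 0 in doubles
            assert td.ft4_derivative(p, t, d) < 0

    def test_equals_ode_rhs_and_finite_difference(self, patient2_params):
        p, t, d = patient2_params, 35.0, 3.0
        y = td.ft4_solution(p, t, d)
        b = td.inhibition_factor(d, p.ic50)
        rhs = p.a * b * y - p.c * y**2
        assert td.ft4_derivative(p, t, d) == pytest.approx(rhs, rel=1e-12)
        h = 1e-6
        fd = (td.ft4_solution(p, t + h, d) - td.ft4_solution(p, t - h, d)) / (2 * h)
        assert td.ft4_derivative(p, t, d) == pytest.approx(fd, rel=1e-5)

    def test_flat_tail_for_tiny_c1(self):
        p = td.ModelParams(a=0.05, c=0.003, ic50=50.0, c1=-1e-12)
        assert abs(td.ft4_derivative(p, 500.0, 0.0)) < 1e-6


class TestCheckValidity:
    def test_valid_params_pass_on_grid(self):
        rng = np.random.default_rng(9)
        grid = [(t, d) for t in (0, 50, 400) for d in (0, 30, 60)]
        for _ in range(100):
            p, _ = draw_valid_params(rng)
            assert td.check_validity(p, grid).ok

    def test_positive_c1_fails_with_reason(self):
        rep = td.check_validity((0.05, 0.003, 50.0, +0.01), [(0.0, 0.0)])
        assert not rep.ok and not rep.c1_negative
        assert any("c1 must be negative" in r for r in rep.reasons)

    def test_rounded_published_constants_break_initial_condition(self):
        # individually rounded (a, c, c1) of patient 2 no longer satisfy
        # a - y1*(c + a*c1) = 0 at y1 = 75: residual ~ +0.026
        a, c, c1, y1 = 0.052, 0.003, -0.051, 75.0
        residual = a - y1 * (c + a * c1)
        assert residual == pytest.approx(0.026, abs=0.002)
        assert abs(residual) > 1e-3  # clearly violated, a rounding artifact


class TestTaylorShortcut:
    def test_exact_at_t_zero(self, patient2_params):
        for d in (0.0, 13.0, 60.0):
            res = td.taylor_ft4(patient2_params, 0.0, d)
            assert not res.diverged
            assert res.value == pytest.approx(
                td.ft4_solution(patient2_params, 0.0, d), rel=1e-12
            )

    def test_accurate_in_small_exponent_regime(self, patient2_params):
        res = td.taylor_ft4(patient2_params, 1.0, 0.0)  # a*B*t ~ 0.052
        assert res.value == pytest.approx(
            td.ft4_solution(patient2_params, 1.0, 0.0), rel=1e-3
        )

    def test_divergence_flagged_outside_radius(self, patient2_params):
        res = td.taylor_ft4(patient2_params, 56.0, 13.4)  # a*B*t ~ 2.4
        assert res.diverged and res.value is None and res.z <= 0

    def test_third_order_error_bound(self):
        # remainder of the quadratic truncation scales as (a*B*t)^3:
        # calibrate K on one grid of draws, assert on an independent one
        def rel_errors(seed):
            rng = np.random.default_rng(seed)
            out = []
            for _ in range(200):
                p, _ = draw_valid_params(rng)
                d = rng.uniform(0, 60)
                ab = p.a_ic50 / (p.ic50 + d)
                t = rng.uniform(0.01, 0.3) / ab  # a*B*t in (0.01, 0.3]
                res = td.taylor_ft4(p, t, d)
                exact = td.ft4_solution(p, t, d)
                out.append(abs(res.value - exact) / exact / (ab * t) ** 3)
            return np.array(out)

        K = 1.5 * rel_errors(101).max()
        assert (rel_errors(202) <= K).all()
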