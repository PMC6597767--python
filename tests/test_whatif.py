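"""Three-way solver on F(t, d, y) = 0: predictions, dose and time solves, tables."""

import numpy as np
import pytest

import thyrodose as td
from thyrodose.whatif import solve_time_bisect

from conftest import draw_valid_params


class TestPredictFt4:
    @pytest.mark.parametrize("t,d,expected", [(56, 5, 16.9), (63, 13, 14.9)])
    def test_published_predictions(self, patient2_params, t, d, expected):
        ans = td.predict_ft4(patient2_params, t, d)
        assert ans.ok and ans.value == pytest.approx(expected, abs=0.05)

    def test_t0_d0_is_initial_ft4(self, patient2_params):
        ans = td.predict_ft4(patient2_params, 0.0, 0.0)
        assert ans.value == pytest.approx(td.ft4_initial(patient2_params), rel=1e-14)


class TestSolveDose:
    @pytest.mark.parametrize("t,y,expected", [(35, 12, 44.1), (35, 17, 12.7)])
    def test_published_optimal_doses(self, patient2_params, t, y, expected):
        ans = td.solve_dose(patient2_params, t, y)
        assert ans.ok and ans.value == pytest.approx(expected, abs=0.05)

    def test_round_trip_zero_dose(self, patient2_params):
        y0 = td.ft4_solution(patient2_params, 35, 0.0)
        ans = td.solve_dose(patient2_params, 35, y0)
        assert ans.ok and ans.value == pytest.approx(0.0, abs=1e-3)

    def test_target_below_cap_asymptote_is_infeasible(self, patient2_params):
        # steady state at the 60 mg cap is ~8.5 pmol/l; 5 is unreachable
        assert td.ft4_asymptote(patient2_params, 60.0) > 5.0
        ans = td.solve_dose(patient2_params, 35, 5.0)
        assert ans.status == "infeasible" and ans.achievable is not None
        lo, hi = ans.achievable
        assert lo > 5.0

    def test_cap_honesty(self, patient2_params):
        rng = np.random.default_rng(23)
        for _ in range(50):
            p, _ = draw_valid_params(rng)
            t = rng.uniform(10, 200)
            y = rng.uniform(5, 60)
            ans = td.solve_dose(p, t, y)
            if ans.value is not None:
                assert ans.value <= 60.0 + 1e-9
            if ans.status == "at_bound":
                assert ans.bound_hit == "dose_cap"

    def test_forward_inverse_round_trip(self, patient2_params):
        rng = np.random.default_rng(31)
        for _ in range(100):
            p, _ = draw_valid_params(rng)
            t = rng.uniform(5, 300)
            d_true = rng.uniform(0.5, 59.5)
            y = td.ft4_solution(p, t, d_true)
            ans = td.solve_dose(p, t, y)
            assert ans.ok
            assert td.ft4_solution(p, t, ans.value) == pytest.approx(y, abs=1e-4)

    def test_domain_contracts(self, patient2_params):
        with pytest.raises(td.DomainError):
            td.solve_dose(patient2_params, 0.0, 15.0)
        with pytest.raises(td.DomainError):
            td.solve_dose(patient2_params, 35.0, -1.0)


class TestSolveTime:
    def test_six_weeks_to_target_at_cap(self, patient2_params):
        ans = td.solve_time(patient2_params, 60.0, 10.0)
        assert ans.ok and ans.value == pytest.approx(42.4, abs=0.1)
        assert round(ans.value) == 42

    def test_zero_time_at_starting_level(self, patient2_params):
        y0 = td.ft4_solution(patient2_params, 0.0, 20.0)
        ans = td.solve_time(patient2_params, 20.0, y0)
        assert ans.ok and ans.value == pytest.approx(0.0, abs=1e-9)

    def test_asymptote_never_attained(self, patient2_params):
        y_inf = td.ft4_asymptote(patient2_params, 20.0)
        assert td.solve_time(patient2_params, 20.0, y_inf).status == "infeasible"

    def test_target_above_start_is_infeasible(self, patient2_params):
        y0 = td.ft4_solution(patient2_params, 0.0, 0.0)
        ans = td.solve_time(patient2_params, 0.0, y0 + 5.0)
        assert ans.status == "infeasible"

    def test_closed_form_agrees_with_bisection(self):
        rng = np.random.default_rng(47)
        for _ in range(100):
            p, _ = draw_valid_params(rng)
            d = rng.uniform(0, 60)
            y0 = td.ft4_solution(p, 0.0, d)
            y_inf = td.ft4_asymptote(p, d)
            y = y_inf + rng.uniform(0.05, 0.95) * (y0 - y_inf)
            closed = td.solve_time(p, d, y, time_cap=1e9)
            bis = solve_time_bisect(p, d, y, time_cap=1e9)
            assert closed.ok and bis.ok
            assert closed.value == pytest.approx(bis.value, abs=1e-4)

    def test_time_round_trip(self, patient2_params):
        rng = np.random.default_rng(53)
        p = patient2_params
        for _ in range(50):
            d = rng.uniform(0, 60)
            y0, y_inf = td.ft4_solution(p, 0.0, d), td.ft4_asymptote(p, d)
            y = y_inf + rng.uniform(0.05, 0.95) * (y0 - y_inf)
            t = td.solve_time(p, d, y).value
            assert td.ft4_solution(p, t, d) == pytest.approx(y, rel=1e-6)

    def test_time_cap_reported(self, patient2_params):
        y_near = td.ft4_asymptote(patient2_params, 0.0) + 1e-9
        ans = td.solve_time(patient2_params, 0.0, y_near, time_cap=100.0)
        assert ans.status == "at_bound" and ans.bound_hit == "time_cap"
        assert ans.value > 100.0


class TestQueryDispatch:
    def test_exactly_one_unknown_enforced(self, patient2_params):
        with pytest.raises(td.DomainError):
            td.WhatIfQuery(patient2_params, t=35.0, d=5.0, y=12.0)
        with pytest.raises(td.DomainError):
            td.WhatIfQuery(patient2_params, t=35.0)

    def test_dispatch_matches_direct_solvers(self, patient2_params):
        p = patient2_params
        q = td.WhatIfQuery(p, t=35.0, d=5.0)
        assert td.solve_whatif(q).value == td.predict_ft4(p, 35.0, 5.0).value
        q = td.WhatIfQuery(p, t=35.0, y=12.0)
        assert td.solve_whatif(q).value == td.solve_dose(p, 35.0, 12.0).value
        q = td.WhatIfQuery(p, d=60.0, y=10.0)
        assert td.solve_whatif(q).value == td.solve_time(p, 60.0, 10.0).value


class TestGridsAndCurves:
    def test_ft4_grid_monotone_in_dose_and_time(self, patient2_params):
        df = td.dose_grid(patient2_params, [35, 56, 63], [3, 5, 8, 10, 13])
        wide = df.pivot(index="dose_mg", columns="time_days",
                        values="ft4_pmol_per_l")
        assert (wide.diff(axis=0).dropna() <= 0).all().all()  # higher dose, lower FT4
        assert (wide.diff(axis=1).T.dropna() <= 0).all().all()  # longer time, lower FT4

    def test_single_cell_grid_equals_prediction(self, patient2_params):
        df = td.dose_grid(patient2_params, [35], [3])
        assert df.loc[0, "ft4_pmol_per_l"] == pytest.approx(
            round(td.predict_ft4(patient2_params, 35, 3).value, 1)
        )

    def test_target_grid_marks_infeasible_cells(self, patient2_params):
        df = td.target_grid(patient2_params, [5.0, 12.0], [35.0])
        by_target = df.set_index("target_ft4_pmol_per_l")
        assert by_target.loc[5.0, "status"] == "infeasible"
        assert np.isnan(by_target.loc[5.0, "dose_mg"])
        assert by_target.loc[12.0, "status"] == "solved"

    def test_trajectory_decreasing_to_asymptote(self, patient2_params):
        df = td.trajectory(patient2_params, 60.0, 50.0, 1.0)
        y = df["ft4_pmol_per_l"].to_numpy()
        assert (np.diff(y) < 0).all()
        # gap to the ~8.5 pmol/l steady state after 50 d at the cap:
        # y*y_inf*|c1|*exp(-a*ic50*t/(ic50+d)) ~ 1.17 pmol/l
        assert abs(y[-1] - td.ft4_asymptote(patient2_params, 60.0)) < 1.3

    def test_untreated_trajectory_flattens_at_published_level(self, patient2_params):
        df = td.trajectory(patient2_params, 0.0, 400.0, 50.0)
        assert df["ft4_pmol_per_l"].iloc[-1] == pytest.approx(17.3, abs=0.05)

    def test_step_equal_to_horizon_gives_two_points(self, patient2_params):
        df = td.trajectory(patient2_params, 10.0, 30.0, 30.0)
        assert df["day"].tolist() == [0.0, 30.0]
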