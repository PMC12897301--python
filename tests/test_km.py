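"""Product-limit estimation, the period approach, log-rank and risk
reduction."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter

import regsurv as rs
from regsurv.km import (PeriodWindow, cohort_observations, period_observations,
                        product_limit)

from conftest import make_frame


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # death at 1y, censored at 2y, death at 3y, alive past 5y
        curve = rs.kaplan_meier([1, 2, 3, 6], [True, False, True, False], horizon=5)
        assert rs.os_at(curve, 5).estimate == pytest.approx(0.375)
        assert rs.os_at(curve, 2).estimate == pytest.approx(0.75)
        assert rs.os_at(curve, 0).estimate == 1.0

    def test_value_at_event_time_is_after_the_drop(self):
        curve = rs.kaplan_meier([1, 2, 3, 6], [True, False, True, False], horizon=5)
        assert rs.os_at(curve, 1).estimate == pytest.approx(0.75)

    def test_all_censored_survival_one_variance_zero(self):
        curve = rs.kaplan_meier([5, 5, 5], [False] * 3, horizon=5)
        pt = rs.os_at(curve, 5)
        assert pt.estimate == 1.0
        assert curve.variance.size == 0  # no event steps at all

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2, 200)
        curve = rs.kaplan_meier(t, np.ones(200, bool))
        for q in (0.5, 1.0, 2.0):
            assert rs.os_at(curve, q).estimate == pytest.approx((t > q).mean())

    def test_greenwood_zero_without_events(self):
        curve = rs.kaplan_meier([1, 2, 3], [False, True, False])
        assert np.all(curve.variance[curve.events == 0] >= 0)
        none = rs.kaplan_meier([1, 2, 3], [False] * 3)
        assert none.variance.size == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            rs.kaplan_meier([], [])

    def test_estimate_beyond_followup_flagged_immature(self):
        curve = rs.kaplan_meier([1, 2], [True, False], horizon=5)
        assert rs.os_at(curve, 5).immature

    def test_matches_lifelines_on_random_datasets(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 80))
            t = np.round(rng.exponential(3, n), 2) + 0.01
            e = rng.uniform(size=n) < rng.uniform(0.2, 1.0)
            mine = rs.kaplan_meier(t, e)
            if mine.times.size == 0:
                continue
            ref = KaplanMeierFitter().fit(t, e).survival_function_
            theirs = ref.loc[mine.times, "KM_estimate"].to_numpy()
            assert np.max(np.abs(theirs - mine.survival)) <= 1e-10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.05, 10), st.booleans()),
                    min_size=1, max_size=40))
    def test_invariants_on_arbitrary_data(self, obs):
        t = np.array([o[0] for o in obs])
        e = np.array([o[1] for o in obs])
        curve = rs.kaplan_meier(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))
        assert np.all(curve.ci_low <= curve.survival + 1e-12)
        assert np.all(curve.ci_high >= curve.survival - 1e-12)
        assert np.all(np.diff(curve.at_risk) <= 0)


class TestPeriodApproach:
    def test_window_covering_everything_equals_cohort_km(self, default_registry):
        obs = cohort_observations(default_registry, horizon=5)
        cohort = rs.kaplan_meier(obs["time"], obs["event"], horizon=5)
        period = rs.period_survival(default_registry, PeriodWindow(1999, 2050))
        np.testing.assert_array_equal(cohort.times, period.times)
        np.testing.assert_array_equal(cohort.at_risk, period.at_risk)
        np.testing.assert_allclose(cohort.survival, period.survival, rtol=0, atol=0)

    def test_eligible_diagnosis_years(self):
        w = PeriodWindow(2019, 2022)
        assert w.eligible_diagnosis_years == (2015, 2021)

    def test_hand_conditional_probability_with_delayed_entry(self):
        # Subjects (entry, exit, event): conditional product by hand.
        ent = np.array([0.0, 1.5, 0.0])
        t = np.array([2.0, 3.0, 4.0])
        e = np.array([True, True, False])
        curve = product_limit(t, e, entry=ent)
        # at t=2: at risk {1st, 2nd, 3rd} -> 3, death -> 2/3
        # at t=3: at risk {2nd, 3rd} -> 2, death -> 1/2
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3])

    def test_deaths_outside_window_become_censorings(self):
        df = make_frame(
            {"diagnosis_date": date(2016, 1, 1), "diagnosis_year": 2016,
             "vital_status": "dead", "followup_end_date": date(2021, 6, 1)},
        )
        obs = period_observations(df, PeriodWindow(2017, 2020))
        assert len(obs) == 1
        assert not obs["event"].iloc[0]  # death after window end

    def test_no_persontime_raises(self):
        df = make_frame({"diagnosis_date": date(2005, 6, 1),
                         "diagnosis_year": 2005,
                         "followup_end_date": date(2006, 6, 1)})
        with pytest.raises(ValueError, match="person-time"):
            rs.period_survival(df, PeriodWindow(2019, 2022))

    def test_matches_lifelines_delayed_entry(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(20, 80))
            ent = np.where(rng.uniform(size=n) < 0.5, 0.0,
                           np.round(rng.uniform(0, 1.5, n), 2))
            t = ent + np.round(rng.exponential(3, n), 2) + 0.01
            e = rng.uniform(size=n) < 0.7
            mine = product_limit(t, e, entry=ent)
            ref = KaplanMeierFitter().fit(t, e, entry=ent).survival_function_
            theirs = ref.loc[mine.times, "KM_estimate"].to_numpy()
            assert np.max(np.abs(theirs - mine.survival)) <= 1e-10

    def test_period_tracks_recent_survival_under_improvement(self):
        """With improving survival the period estimate for a recent window
        should sit above the last complete cohort's estimate on average."""
        from regsurv.simulate import TrendScenario
        wins = 0
        reps = 20
        for rep in range(reps):
            sc = TrendScenario(annual_cases={"0-14": 300.0},
                               baseline_hazards={"0-14": (0.16, 0.055, 0.024)},
                               segment_slopes=(-0.05,), seed=100 + rep)
            df = rs.generate_registry(sc)
            cohort_cases = df[(df.diagnosis_year >= 2013) & (df.diagnosis_year <= 2017)]
            obs = cohort_observations(cohort_cases, horizon=5)
            s_cohort = rs.os_at(
                rs.kaplan_meier(obs["time"], obs["event"], horizon=5), 5).estimate
            s_period = rs.os_at(
                rs.period_survival(df, PeriodWindow(2019, 2022)), 5).estimate
            if s_period > s_cohort:
                wins += 1
        assert wins >= 0.7 * reps


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = (np.array([1.0, 2.0, 3.0]), np.array([True, True, False]))
        res = rs.logrank([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_hand_hypergeometric_two_group_toy(self):
        # groups A: deaths at 1, 2, 3; B: deaths at 4, 5, 6 (no censoring)
        a = (np.array([1.0, 2.0, 3.0]), np.ones(3, bool))
        b = (np.array([4.0, 5.0, 6.0]), np.ones(3, bool))
        # brute-force O-E accumulation over pooled event times
        times = [1, 2, 3, 4, 5, 6]
        o_minus_e = 0.0
        var = 0.0
        at_a, at_b = 3, 3
        for t in times:
            n = at_a + at_b
            d = 1
            e_a = d * at_a / n
            o_a = 1 if t <= 3 else 0
            o_minus_e += o_a - e_a
            if n > 1:
                var += d * (at_a / n) * (at_b / n) * (n - d) / (n - 1)
            if t <= 3:
                at_a -= 1
            else:
                at_b -= 1
        expect = o_minus_e ** 2 / var
        res = rs.logrank([a, b])
        assert res.statistic == pytest.approx(expect, rel=1e-10)

    def test_three_groups_df_two(self):
        rng = np.random.default_rng(0)
        gs = [(rng.exponential(2, 30), rng.uniform(size=30) < 0.8) for _ in range(3)]
        assert rs.logrank(gs).df == 2

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            t1, t2 = rng.exponential(2, (2, 100))
            e1 = rng.uniform(size=100) < 0.8
            e2 = rng.uniform(size=100) < 0.8
            if rs.logrank([(t1, e1), (t2, e2)]).pvalue < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rs.logrank([(np.array([1.0]), np.array([True])),
                        (np.array([]), np.array([], dtype=bool))])


class TestRiskReduction:
    @pytest.mark.parametrize("early, late, expected", [
        (75.8, 86.6, 44.6),   # leukaemias: rounds to 45
        (86.7, 97.4, 80.5),   # Burkitt: ~80
        (86.4, 94.4, 58.8),   # lymphomas: rounds to 59
    ])
    def test_reported_reductions(self, early, late, expected):
        assert rs.risk_reduction(early, late) == pytest.approx(expected, abs=0.05)

    def test_no_change_is_zero(self):
        for x in (10.0, 55.5, 99.9):
            assert rs.risk_reduction(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_early_survival_undefined(self):
        with pytest.raises(ValueError):
            rs.risk_reduction(100.0, 99.0)
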