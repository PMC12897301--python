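"""Cox-joinpoint trend models: basis, partial likelihood, BIC selection,
standardised series and the AACS bootstrap."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import regsurv as rs
from regsurv.coxjp import (YearBasis, bic_value, candidate_joinpoints,
                           fit_cox, prepare_strata, select_joinpoints,
                           trend_observations)
from regsurv.simulate import TrendScenario


def simulate_obs(n, beta, rng, years=(1999, 2021), lam=0.1, strata=1,
                 joinpoints=(), censor=8.0):
    """Piecewise-exponential observations with a hinge year effect, truncated
    at 5 years, as a trend-model input frame."""
    year = rng.integers(years[0], years[1] + 1, n)
    basis = YearBasis(years[0], joinpoints)
    eta = basis.evaluate(year) @ np.atleast_1d(beta)
    lab = rng.integers(0, strata, n)
    rate = lam * (1 + 0.3 * lab) * np.exp(eta)
    t = rng.exponential(1 / rate)
    c = rng.uniform(0, censor, n)
    time = np.minimum(np.minimum(t, c), 5.0)
    event = (t <= c) & (t <= 5.0)
    return pd.DataFrame({"time": time, "event": event, "year": year,
                         "stratum": lab})


class TestYearBasis:
    def test_offset_only(self):
        assert YearBasis(1999).evaluate(2004).tolist() == [[5.0]]

    def test_hinge_arithmetic(self):
        assert YearBasis(1999, (2007,)).evaluate(2010).tolist() == [[11.0, 3.0]]

    def test_continuity_at_joinpoint(self):
        basis = YearBasis(1999, (2007,))
        beta = np.array([0.02, -0.05])
        eps = 1e-6
        left = basis.evaluate(2007 - eps) @ beta
        right = basis.evaluate(2007 + eps) @ beta
        at = basis.evaluate(2007) @ beta
        assert left == pytest.approx(at, abs=1e-6)
        assert right == pytest.approx(at, abs=1e-6)

    def test_segment_slopes_are_cumsums(self):
        basis = YearBasis(1999, (2005, 2012))
        np.testing.assert_allclose(
            basis.segment_slopes([0.01, -0.03, 0.05]), [0.01, -0.02, 0.03])

    def test_invalid_joinpoints(self):
        with pytest.raises(ValueError):
            YearBasis(1999, (1999,))
        with pytest.raises(ValueError):
            YearBasis(1999, (2010, 2005))


class TestPartialLikelihood:
    def test_matches_bruteforce_enumeration_tiny_fixture(self):
        # 5 subjects, distinct times -> the partial likelihood is a plain
        # product over risk sets, enumerable by hand at any beta
        time = np.array([1.0, 2.0, 3.0, 4.0, 4.5])
        event = np.array([True, False, True, True, False])
        year = np.array([2000, 2001, 2003, 2005, 2010], dtype=float)
        basis = YearBasis(1999)
        prepared = prepare_strata(time, event, year, np.zeros(5, int))
        for beta in ([0.0], [0.1], [-0.3]):
            x = year - 1999
            eta = x * beta[0]

            def brute(eta):
                ll = 0.0
                for i in np.flatnonzero(event):
                    risk = time >= time[i]
                    ll += eta[i] - np.log(np.exp(eta[risk]).sum())
                return ll

            from regsurv.coxjp import _stratum_quantities
            Xs = basis.evaluate(year)
            XX = Xs[:, :, None] * Xs[:, None, :]
            ll, *_ = _stratum_quantities(prepared[0], Xs, XX, np.array(beta))
            assert ll == pytest.approx(brute(eta), rel=1e-12)

    def test_matches_lifelines_stratified_efron(self):
        rng = np.random.default_rng(10)
        obs = simulate_obs(1500, [-0.04], rng, strata=2)
        obs["time"] = np.round(obs["time"], 1) + 0.05  # force ties
        model = fit_cox(obs, YearBasis(1999))
        df = obs.rename(columns={"time": "T", "event": "E"})
        ref = CoxPHFitter().fit(df, "T", "E", strata="stratum", formula="year")
        assert model.coef_[0] == pytest.approx(ref.params_.iloc[0], abs=1e-6)
        assert model.log_likelihood_ == pytest.approx(ref.log_likelihood_, abs=1e-6)
        assert np.sqrt(model.cov_[0, 0]) == pytest.approx(
            ref.standard_errors_.iloc[0], abs=1e-6)

    def test_consistency_hazard_ratio_two(self):
        # two year-groups one year apart with hazard ratio 2 -> beta -> ln 2
        rng = np.random.default_rng(4)
        n = 40000
        year = np.repeat([1999.0, 2000.0], n // 2)
        rate = np.where(year == 2000, 0.2, 0.1)
        t = rng.exponential(1 / rate)
        time = np.minimum(t, 5.0)
        event = t <= 5.0
        obs = pd.DataFrame({"time": time, "event": event, "year": year,
                            "stratum": 0})
        model = fit_cox(obs, YearBasis(1999))
        assert model.coef_[0] == pytest.approx(np.log(2), abs=0.05)

    def test_null_estimates_unbiased(self):
        rng = np.random.default_rng(8)
        hits = 0
        reps = 40
        for _ in range(reps):
            obs = simulate_obs(800, [0.0], rng)
            m = fit_cox(obs, YearBasis(1999))
            se = np.sqrt(m.cov_[0, 0])
            if abs(m.coef_[0]) < 1.96 * se:
                hits += 1
        assert hits >= 0.85 * reps  # ~95% nominal coverage

    def test_recentring_year_covariate_invariance(self):
        rng = np.random.default_rng(2)
        obs = simulate_obs(1000, [-0.05], rng)
        m1 = fit_cox(obs, YearBasis(1999))
        shifted = obs.assign(year=obs["year"] + 7)
        m2 = fit_cox(shifted, YearBasis(2006))
        assert m1.coef_[0] == pytest.approx(m2.coef_[0], abs=1e-8)
        assert m1.log_likelihood_ == pytest.approx(m2.log_likelihood_, abs=1e-8)

    def test_no_events_rejected(self):
        obs = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False],
                            "year": [2000, 2001], "stratum": [0, 0]})
        with pytest.raises(ValueError):
            fit_cox(obs, YearBasis(1999))


class TestBic:
    def test_hand_arithmetic(self):
        assert bic_value(-10.0, 1, 20) == pytest.approx(20 + np.log(20))

    def test_penalty_monotone_in_params(self):
        assert bic_value(-10.0, 2, 20) > bic_value(-10.0, 1, 20)

    def test_zero_events_undefined(self):
        with pytest.raises(ValueError):
            bic_value(-10.0, 1, 0)

    def test_nesting_never_decreases_loglik(self):
        rng = np.random.default_rng(5)
        obs = simulate_obs(2000, [-0.03], rng)
        m0 = fit_cox(obs, YearBasis(1999))
        m1 = fit_cox(obs, YearBasis(1999, (2010,)))
        assert m1.log_likelihood_ >= m0.log_likelihood_ - 1e-8


class TestSelection:
    def test_candidate_grid_respects_min_segments(self):
        cands = candidate_joinpoints(1999, 2021, 2, 3)
        singles = [c[0] for c in cands if len(c) == 1]
        assert min(singles) == 2002 and max(singles) == 2018
        for t1, t2 in (c for c in cands if len(c) == 2):
            assert t2 - t1 >= 3 and t2 <= 2018

    def test_returned_bic_is_grid_minimum(self):
        rng = np.random.default_rng(3)
        obs = simulate_obs(1200, [-0.04], rng, years=(1999, 2012))
        best = select_joinpoints(obs, max_joinpoints=1)
        table = best.bic_table_
        assert best.bic_ == pytest.approx(np.nanmin(table["bic"]), abs=1e-9)

    def test_tie_break_prefers_fewer_joinpoints(self):
        rng = np.random.default_rng(3)
        obs = simulate_obs(800, [0.0], rng, years=(1999, 2010))
        best = select_joinpoints(obs, max_joinpoints=2)
        # under the null the penalty should dominate: no joinpoints selected
        assert best.basis_.joinpoints == ()

    def test_strong_break_recovered(self):
        sc = TrendScenario(
            annual_cases={"0-14": 870.0},
            baseline_hazards={"0-14": (0.14, 0.049, 0.021)},
            joinpoints=(2010,), segment_slopes=(0.0, 0.08), seed=21)
        df = rs.generate_registry(sc)
        obs = trend_observations(df)
        best = select_joinpoints(obs, max_joinpoints=2)
        assert len(best.basis_.joinpoints) >= 1
        assert min(abs(t - 2010) for t in best.basis_.joinpoints) <= 1


class TestSeriesAndAacs:
    def test_no_trend_series_constant(self):
        rng = np.random.default_rng(9)
        obs = simulate_obs(3000, [0.0], rng, strata=2)
        m = fit_cox(obs, YearBasis(1999))
        m.coef_[0] = 0.0  # exactly flat year effect
        series = m.standardised_series({0: 0.5, 1: 0.5}, range(1999, 2023))
        expect = 0.5 * np.exp(-m.baselines_[0].cum_hazard) + \
            0.5 * np.exp(-m.baselines_[1].cum_hazard)
        np.testing.assert_allclose(series.s5, expect)

    def test_aacs_arithmetic(self):
        years = np.arange(1999, 2023)
        s = np.linspace(0.80, 0.915, years.size)
        assert rs.aacs(list(s)) == pytest.approx(0.5)

    def test_flat_series_zero(self):
        assert rs.aacs([0.7] * 24) == 0.0

    def test_bl_like_endpoint_arithmetic(self):
        # start ~84%, AACS 0.65 over 24 years -> 0.84 + 23 * 0.0065 ~ 0.99
        assert 0.84 + 23 * 0.0065 == pytest.approx(0.99, abs=0.005)

    def test_extrapolated_year_flagged(self):
        rng = np.random.default_rng(1)
        obs = simulate_obs(1500, [-0.03], rng)
        m = fit_cox(obs, YearBasis(1999))
        series = m.standardised_series({0: 1.0}, range(1999, 2023))
        assert bool(series.extrapolated[-1]) and not series.extrapolated[:-2].any()

    def test_band_covers_truth_in_wellspecified_fit(self):
        sc = TrendScenario(annual_cases={"0-14": 870.0},
                           baseline_hazards={"0-14": (0.14, 0.049, 0.021)},
                           segment_slopes=(-0.03,), seed=13)
        df = rs.generate_registry(sc)
        obs = trend_observations(df)
        m = fit_cox(obs, YearBasis(1999))
        years = range(1999, 2022)
        series = m.standardised_series({"0-14": 1.0}, years)
        truth = np.array([rs.true_s5(sc, y, "0-14") for y in years])
        covered = (series.band_low <= truth) & (truth <= series.band_high)
        assert covered.mean() >= 0.85

    def test_segment_aacs_splits_series(self):
        years = np.arange(1999, 2023)
        s = np.where(years <= 2010, 0.8, 0.8 + 0.01 * (years - 2010))
        series = rs.TrendSeries(years=years, s5=s, band_low=s, band_high=s,
                                extrapolated=years > 2021)
        seg = series.segment_aacs([2010])
        assert seg[(1999, 2010)] == pytest.approx(0.0)
        assert seg[(2010, 2022)] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(17)
    return simulate_obs(2500, [-0.04], rng)


class TestBootstrap:

    def test_same_seed_identical(self, fitted):
        basis = YearBasis(1999)
        years = range(1999, 2023)
        a = rs.bootstrap_aacs(fitted, basis, years, B=30, seed=5)
        b = rs.bootstrap_aacs(fitted, basis, years, B=30, seed=5)
        assert (a.median, a.ci_low, a.ci_high) == (b.median, b.ci_low, b.ci_high)

    def test_median_inside_interval(self, fitted):
        res = rs.bootstrap_aacs(fitted, YearBasis(1999), range(1999, 2023),
                                B=40, seed=2)
        assert res.ci_low <= res.median <= res.ci_high

    def test_stratified_resampling_runs(self, fitted):
        res = rs.bootstrap_aacs(fitted, YearBasis(1999), range(1999, 2023),
                                B=20, seed=3, stratified=True)
        assert res.n_failed == 0
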