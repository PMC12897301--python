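# regsurv

Survival estimation and trend modelling for childhood-cancer registries.

National paediatric cancer registries track every child diagnosed before age
15 and ask two recurring questions: *what is 5-year overall survival right
now*, and *how fast has it been improving*? Answering them well requires a
specific statistical stack, which this package implements as a tested,
reusable library:

- **Cohort Kaplan–Meier** overall survival at 1/3/5 years with Greenwood
  variance and complementary log-log confidence intervals, plus k-group
  log-rank tests.
- **Period-approach survival** for recent calendar windows (delayed-entry
  product-limit over the follow-up slice inside the window), giving
  up-to-date estimates before the newest diagnosis cohort completes 5 years.
- **Age standardisation with case-pool weights**: each age group's share of
  the tumour's full case pool, with adjacent-group pooling when any cohort
  cell falls below 15 cases and suppression of estimates based on fewer than
  15 cases.
- **Cox–joinpoint trend models**: age-stratified Cox proportional hazards
  with the diagnosis year entering through a continuous hinge basis
  `f(y) = (y − y0, max(0, y − τ1), …)`, so the log hazard is piecewise linear
  in calendar time. The number and location of joinpoints (0–2) are selected
  by exhaustive grid search minimising `BIC = −2 log PL + p·ln(d)` with `d`
  the number of deaths. Breslow baselines per age stratum yield model-based
  survival `S_a(5 | y) = exp(−Λ_a(5)·e^{f(y)'β})`, combined into an
  age-standardised fitted series with a delta-method band.
- **AACS** (average absolute change in survival): the average yearly change
  of fitted age-standardised 5-year survival over the series, in percentage
  points, with a 500-replicate case-resampling bootstrap for its 95% CI.
- A **synthetic registry generator** (piecewise-exponential hazards per age
  group, hinge calendar trend, ~3% loss to follow-up, administrative
  censoring) with closed-form ground truth, so the whole pipeline is
  testable end to end without access to confidential registry records.

The estimators follow scikit-learn conventions (`KaplanMeierEstimator`,
`PeriodSurvivalEstimator`, `JoinpointCoxPH`: `fit`, fitted attributes with a
trailing underscore, `get_params`/`set_params`); module-level functions wrap
them for scripting, and a `regsurv` CLI (`simulate`, `km`, `period`,
`tables`, `trend`, `report`) covers shell workflows.

## Worked example

```python
import numpy as np
import regsurv as rs
from regsurv.coxjp import select_joinpoints, trend_observations, bootstrap_aacs

# a registry-like dataset: ~20,000 cases, 1999-2021, improving survival
scenario = rs.TrendScenario(seed=1)
cases = rs.apply_cohort_filters(rs.generate_registry(scenario))

# observed survival: first 5-year cohort vs the 2019-2022 period window
first = cases[cases.diagnosis_year <= 2003]
obs = rs.cohort_observations(first, horizon=5)
s_first = rs.os_at(rs.kaplan_meier(obs["time"], obs["event"], horizon=5), 5)
s_recent = rs.os_at(rs.period_survival(cases, rs.PeriodWindow(2019, 2022)), 5)
print(f"5-year OS 1999-2003: {100*s_first.estimate:.1f}")   # 76.7
print(f"5-year OS 2019-2022: {100*s_recent.estimate:.1f}")  # 83.7

# trend: joinpoint selection, case-pool weights, standardised series, AACS
grouping = rs.AgeGrouping(("0-4", "5-9", "10-14"))
trend = trend_observations(cases, grouping=grouping)
model = select_joinpoints(trend, max_joinpoints=2)
weights = rs.derive_weights(cases.assign(
    age_group=grouping.assign(cases["age_group"])), grouping)
series = model.standardised_series(weights.as_dict(), np.arange(1999, 2023))
boot = bootstrap_aacs(trend, model.basis_, np.arange(1999, 2023), B=500, seed=2)
print(f"joinpoints: {model.basis_.joinpoints}")             # ()
print(f"AACS: {rs.aacs(series):.2f} [{boot.ci_low:.2f}, {boot.ci_high:.2f}]")
# AACS: 0.42 [0.34, 0.51]
```

The period estimate (83.7%) sits 7 points above the first cohort — an honest
registry would report exactly this gain — and the fitted trend recovers the
generative truth: the scenario's true standardised AACS is 0.42 points/year,
inside the bootstrap interval, and no spurious joinpoint is selected for its
linear log-hazard trend.

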