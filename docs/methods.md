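# Methods

This note documents the statistical models implemented in `regsurv`, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real registry data.

## Survival estimation

**Cohort estimates.** Overall survival is the product-limit (Kaplan–Meier)
estimator over all-cause death; for childhood cancer, absolute survival is
close to cause-specific survival, so no relative-survival machinery is used.
Time is measured in years as days/365.25 from the diagnosis date to death,
last contact, or administrative closure; same-day deaths receive half a day
so no interval is degenerate. At tied times deaths precede censorings.
Variance is Greenwood's estimator; 95% confidence intervals use the
complementary log-log transform (`S^exp(±z·se(log(−log S)))`), the standard
registry choice because it keeps bounds inside [0, 1] and behaves well near
1. Reading the curve past the last observed exit returns the last estimate
flagged as potentially immature.

**Period approach.** For a recent calendar window [w0, w1] the estimator
conditions on the survival experience observed *inside* the window: each
eligible case (diagnosed from `w0 − horizon + 1` through `w1 − 1`; the final
window year contributes follow-up only) enters the risk set at
`max(0, w0 − diagnosis date)` years and exits at
`min(followup end, w1, horizon)`, with deaths after `w1` treated as
censorings. The estimate is a delayed-entry product-limit over these clipped
observations; person-time is clipped at day resolution, not whole years. The
Greenwood form is reused with the time-varying risk sets. When the window
covers all observed follow-up this reduces *exactly* to the cohort estimator
(asserted in the tests), and in a context of steadily improving survival the
period estimate slightly understates current-year survival while sitting
above the last complete cohort — the behaviour the simulation tests check.

**Log-rank tests** (k groups, df = k−1) delegate to lifelines'
`multivariate_logrank_test`; a hand hypergeometric accumulation serves as the
oracle in the test suite.

## Age standardisation

Weights are the analysed tumour's own case-pool age composition over the full
incidence period (`w_a = n_a / n`), so standardised values stay on the scale
of observed all-ages survival rather than an external standard population.
The default grouping is 0–4 / 5–9 / 10–14; the infant split (<1 vs 1–4) is
used only in by-age tables and only when both cells reach 15 cases in every
cohort. When any cohort cell falls below 15 cases, adjacent groups merge —
to 0–9/10–14 for tumours typically diagnosed at older ages, to 0–4/5–14 for
young-heavy tumours, or (without a hint) toward the neighbour giving the
larger combined count — and if still deficient everything collapses to a
single 0–14 group, i.e. no standardisation. The standardised estimate is
`Σ w_a S_a` with `se = sqrt(Σ w_a² se_a²)`; the independence assumption
across age strata is reasonable because strata partition the cases. Any
estimate based on fewer than 15 cases is suppressed in reports (strict
inequality: 15 cases are reported, 14 are not), and the suppressed value
never reaches an output artifact.

## Cox–joinpoint trend models

The hazard of death within 5 years of diagnosis is modelled as

    λ(t | y, a) = λ0a(t) · exp(β' f(y)),   f(y) = (y − y0, (y − τ1)+, …)

with one baseline hazard per age stratum `a` and a continuous piecewise-linear
("hinge") effect of the diagnosis year `y`. The slope on segment k is the
cumulative sum `β1 + … + βk+1`, so the fitted log-hazard trend is continuous
at each joinpoint τ. Follow-up is right-truncated at 5 years.

Fitting maximises the stratified partial likelihood with the Efron tie
correction by Newton–Raphson with step-halving. The gradient stopping rule is
scaled per event (`max|score| ≤ 1e-8 · d`): the score is a sum over deaths,
so an absolute cutoff would sit below floating-point noise at registry scale;
a step-size floor catches the same noise plateau. Divergent coefficients
(monotone likelihood / separation in the year covariate) and singular
information matrices raise flagged errors rather than returning garbage. The
implementation is vectorised over tie groups and reuses the per-stratum sort
and tie structure across the whole joinpoint grid, which keeps an exhaustive
search at 20,000 cases around two seconds.

**Joinpoint selection** is an exhaustive scan over integer calendar years:
0, 1 or 2 joinpoints, every segment (including both series ends) at least 3
years long, minimising `BIC = −2 log PL + p·ln(d)` where `p` counts the
basis coefficients and `d` the deaths — the standard effective sample size
for Cox-model BIC. Joinpoint *locations* are not counted in the penalty by
default (a toggle exists); ties break toward fewer joinpoints, then earlier
locations. Selection is BIC-only; no permutation-test machinery.

**Model-based standardised series.** Per stratum,
`S_a(5 | y) = exp(−Λ_a(5)·e^{β'f(y)})` with `Λ_a` the Breslow baseline
cumulative hazard at the reference year; case-pool weights combine the
strata. The series is extended one year past the last fitted diagnosis year
by continuing the final segment's slope, flagged as extrapolated. The 95%
band is a delta-method interval treating (Λ_a, β) as jointly asymptotically
normal with the standard large-sample covariance of the Breslow estimator:
`Cov(Λ_a, Λ_b) = δ_ab·Σd/S0² + q_a' W q_b`, `Cov(Λ_a, β) = −W q_a`, where
`q_a = Σ d·S1/S0²` and `W` is the coefficient covariance. A bootstrap band is
available as a cross-check.

**AACS.** The average absolute change in survival over the series is
`(S[last] − S[first]) · 100 / (#years − 1)` in percentage points per year;
per-segment values between joinpoints are also exposed, with the full-series
value as the headline. Its 95% CI comes from resampling cases with
replacement (optionally within age strata), refitting coefficients, baselines
and case-pool weights per replicate *with the joinpoints held fixed at the
selected locations*, and taking the 2.5th/50th/97.5th percentiles over 500
replicates. Replicates that fail to fit are dropped and counted; more than
10% failures is an error.

## Synthetic registry generator

The generator emulates the structure of a national childhood-cancer registry
over incidence years 1999–2021 (~870 expected cases/year ≈ 20,000 total;
infants ~10.9% of cases): Poisson annual counts per age group, diagnosis
dates uniform within the year, piecewise-constant baseline hazards over
follow-up intervals [0,1), [1,3), [3,∞) years front-loaded so about half the
5-year cumulative hazard falls in the first year, with default
start-of-series 5-year survival 0.70 / 0.78 / 0.76 / 0.72 for <1 / 1–4 / 5–9
/ 10–14 (survival peaking at 1–4 years). The calendar trend multiplies the
hazard by `exp(β'f(y))` through the *same* hinge basis the fitting module
uses — the fitted model is well-specified by default — with default slope
−0.024/year, which lifts all-ages 5-year survival from about 0.75 to about
0.85 across the series. A `misspecified` toggle instead applies the trend
additively to 5-year survival for robustness experiments. Loss to follow-up
is an independent exponential process calibrated so ~3% of cases are lost
within 5 years; administrative censoring falls on 31 December 2022. Sex
(54% male), second primaries (0.6%), microscopic verification (89.5%) and a
25-entry tumour-code mix (including non-malignant fractions for CNS codes)
are sampled independently of survival. Closed-form `true_s5`/`true_aacs`
expose the generative truth for recovery tests.

What the generator does **not** emulate: registration-completeness drift
(e.g. rising capture of non-malignant CNS and epithelial tumours), outcome
differences by tumour code given age (hazards depend only on age group),
informative loss to follow-up, and abrupt additive survival shifts. Passing
tests therefore demonstrate that the estimators recover the truth under a
correctly specified, cleanly registered data-generating process; they cannot
certify behaviour under real registries' registration artefacts.

## Test problem sizes

Operating-characteristic suites run at the sizes the methods are meant for:
joinpoint recovery uses 100 replicates of ~20,000 cases with a single break
(flat, then +0.08/year on the log hazard at 2010); selection specificity uses
200 no-trend replicates of ~5,000 cases; AACS bootstrap coverage uses 200
well-specified registries of ~4,600 cases (200/year) at 200 bootstrap
replicates per dataset — enough cases for the asymptotics to hold while the
full suite stays comfortably runnable on a single CPU.

## Known limitations

- DCO% is structurally 0 because the modelled registry does not register
  cases from death certificates; the field is retained for IARC-format
  parity and rendered "-" in reports.
- The delta-method band relies on large-sample normality of (Λ_a, β); for
  rare tumours (tens of deaths) the bootstrap band is preferable.
- Joinpoints are restricted to integer calendar years, matching the annual
  resolution of the covariate; sub-year breaks are not identifiable here.
- The period estimator reuses the Greenwood variance with time-varying risk
  sets; it matches the behaviour of standard period-analysis software to
  sampling accuracy but is not bound to it to machine precision.
- Event-free survival, relative survival and cure-fraction models are out of
  scope.
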