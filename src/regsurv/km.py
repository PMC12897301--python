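"""Cohort and period overall-survival estimation.

The core is a product-limit (Kaplan-Meier) estimator that also handles delayed
entry, which is what the period approach needs: for a recent calendar window,
each case contributes only the slice of its follow-up that falls inside the
window (entering at the window start, censored at the window end), giving an
up-to-date estimate before the newest diagnosis cohort completes 5 years of
follow-up.

Conventions: at tied times deaths precede censorings; the Greenwood variance
is reported on the survival scale; 95% confidence intervals use the
complementary log-log transform, which keeps the bounds inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .simulate import DAYS_PER_YEAR


@dataclass
class SurvivalCurve:
    """Step-function survival estimate with per-step risk sets and CI."""

    times: np.ndarray          # event times (years since diagnosis)
    at_risk: np.ndarray        # risk-set size entering each step
    events: np.ndarray         # deaths at each step
    survival: np.ndarray       # S just after each step
    variance: np.ndarray       # Greenwood variance of S
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_total: int
    horizon: float | None = None
    max_time: float = np.nan   # latest observed exit (for immaturity flags)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "at_risk": self.at_risk, "events": self.events,
            "S": self.survival, "var": self.variance,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


@dataclass
class PointEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    immature: bool = False


def _cloglog_ci(s: np.ndarray, var: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    z = norm.ppf(1.0 - alpha / 2.0)
    lo = np.empty_like(s)
    hi = np.empty_like(s)
    interior = (s > 0.0) & (s < 1.0) & (var > 0.0)
    se_theta = np.sqrt(var[interior]) / (s[interior] * np.abs(np.log(s[interior])))
    lo[interior] = s[interior] ** np.exp(z * se_theta)
    hi[interior] = s[interior] ** np.exp(-z * se_theta)
    lo[~interior] = s[~interior]
    hi[~interior] = s[~interior]
    return np.clip(lo, 0.0, 1.0), np.clip(hi, 0.0, 1.0)


def product_limit(time, event, entry=None, horizon: float | None = None,
                  alpha: float = 0.05) -> SurvivalCurve:
    """Product-limit estimate, optionally with delayed entry.

    ``time`` are exit times (years), ``event`` marks deaths, ``entry`` marks
    delayed-entry times (0 for cohort analyses). Observations with
    ``entry >= time`` are invalid. A subject is at risk at event time t when
    ``entry < t <= time`` (deaths-first at ties).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    entry = np.zeros_like(time) if entry is None else np.asarray(entry, dtype=float)
    if time.size == 0:
        raise ValueError("cannot estimate survival from no observations")
    if np.any(entry >= time):
        raise ValueError("zero-length or negative observation intervals")
    if np.any(entry < 0):
        raise ValueError("negative entry times")

    if horizon is not None:
        event = event & (time <= horizon)
        time = np.minimum(time, horizon)
        keep = entry < time
        time, event, entry = time[keep], event[keep], entry[keep]
        if time.size == 0:
            raise ValueError("no person-time before the horizon")

    t_sorted = np.sort(time)
    e_sorted = np.sort(entry)
    uniq = np.unique(time[event])
    # at risk at t: exits >= t minus entries >= t
    n_at_risk = (t_sorted.size - np.searchsorted(t_sorted, uniq, side="left")) - (
        e_sorted.size - np.searchsorted(e_sorted, uniq, side="left"))
    # deaths at each unique event time
    d = np.bincount(np.searchsorted(uniq, time[event]),
                    minlength=uniq.size).astype(int)

    frac = 1.0 - d / n_at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = d / (n_at_risk * (n_at_risk - d).astype(float))
    gw_terms[~np.isfinite(gw_terms)] = 0.0  # steps where S hits 0
    var = surv ** 2 * np.cumsum(gw_terms)
    lo, hi = _cloglog_ci(surv, var, alpha)
    return SurvivalCurve(
        times=uniq, at_risk=n_at_risk.astype(int), events=d, survival=surv,
        variance=var, ci_low=lo, ci_high=hi, n_total=int(time.size),
        horizon=horizon, max_time=float(t_sorted[-1]),
    )


def os_at(curve: SurvivalCurve, t: float, alpha_unused: float = 0.05) -> PointEstimate:
    """Survival-curve read-off at time ``t`` (right-continuous step function).

    Past the last observed exit the last available estimate is returned,
    flagged as potentially immature.
    """
    if curve.horizon is not None and t > curve.horizon + 1e-12:
        raise ValueError(f"t={t} beyond the estimation horizon {curve.horizon}")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return PointEstimate(1.0, 1.0, 1.0)
    immature = bool(t > curve.max_time + 1e-12)
    return PointEstimate(float(curve.survival[idx]), float(curve.ci_low[idx]),
                         float(curve.ci_high[idx]), immature)


class KaplanMeierEstimator(BaseEstimator):
    """Cohort Kaplan-Meier estimator (sklearn-style).

    Parameters
    ----------
    horizon : follow-up truncation in years (None = no truncation).
    alpha : two-sided CI level (0.05 -> 95% intervals).
    """

    def __init__(self, horizon: float | None = None, alpha: float = 0.05):
        self.horizon = horizon
        self.alpha = alpha

    def fit(self, time, event) -> "KaplanMeierEstimator":
        curve = product_limit(time, event, horizon=self.horizon, alpha=self.alpha)
        self.curve_ = curve
        self.times_ = curve.times
        self.survival_ = curve.survival
        self.n_ = curve.n_total
        return self

    def survival_at(self, t: float) -> PointEstimate:
        return os_at(self.curve_, t)


def kaplan_meier(time, event, horizon: float | None = None,
                 alpha: float = 0.05) -> SurvivalCurve:
    """Functional form of :class:`KaplanMeierEstimator`."""
    return product_limit(time, event, horizon=horizon, alpha=alpha)


# ---------------------------------------------------------------------------
# Period approach
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodWindow:
    """Calendar window for period survival estimation.

    Diagnoses from ``calendar_start - horizon + 1`` through ``calendar_end - 1``
    can contribute person-time inside the window at lags up to the horizon; the
    window's final year is kept purely as a year of follow-up.
    """

    calendar_start: int
    calendar_end: int
    horizon: float = 5.0

    def __post_init__(self) -> None:
        if self.calendar_end < self.calendar_start:
            raise ValueError("empty calendar window")

    @property
    def eligible_diagnosis_years(self) -> tuple[int, int]:
        return (int(self.calendar_start - self.horizon + 1), self.calendar_end - 1)

    @property
    def start_date(self) -> date:
        return date(self.calendar_start, 1, 1)

    @property
    def end_date(self) -> date:
        return date(self.calendar_end, 12, 31)


def period_observations(cases: pd.DataFrame, window: PeriodWindow) -> pd.DataFrame:
    """Clip each case's follow-up to the calendar window (day resolution).

    Returns columns ``entry``, ``time``, ``event`` in years since diagnosis;
    cases contributing no positive person-time inside the window are dropped.
    Deaths after the window end count as censorings at the window end.
    """
    lo, hi = window.eligible_diagnosis_years
    df = cases.loc[(cases["diagnosis_year"] >= lo) & (cases["diagnosis_year"] <= hi)]
    if df.empty:
        return pd.DataFrame(columns=["entry", "time", "event"])
    diag = pd.to_datetime(df["diagnosis_date"]).to_numpy(dtype="datetime64[D]")
    fu = pd.to_datetime(df["followup_end_date"]).to_numpy(dtype="datetime64[D]")
    w_start = np.datetime64(window.start_date, "D")
    w_end = np.datetime64(window.end_date, "D")

    entry = np.maximum((w_start - diag).astype(int), 0) / DAYS_PER_YEAR
    exit_date = np.minimum(fu, w_end)
    time = (exit_date - diag).astype(int) / DAYS_PER_YEAR
    # same-day deaths get the same half-day bump as the cohort path
    time = np.maximum(time, 0.5 / DAYS_PER_YEAR)
    event = (df["vital_status"] == "dead").to_numpy() & (fu <= w_end)
    # truncate at the horizon
    over = time > window.horizon
    time = np.minimum(time, window.horizon)
    event = event & ~over
    keep = time > entry
    return pd.DataFrame({"entry": entry[keep], "time": time[keep],
                         "event": event[keep]}).reset_index(drop=True)


class PeriodSurvivalEstimator(BaseEstimator):
    """Period-approach survival estimator (delayed-entry product-limit)."""

    def __init__(self, window: PeriodWindow | None = None, alpha: float = 0.05):
        self.window = window
        self.alpha = alpha

    def fit(self, cases: pd.DataFrame) -> "PeriodSurvivalEstimator":
        if self.window is None:
            raise ValueError("a PeriodWindow is required")
        obs = period_observations(cases, self.window)
        if obs.empty:
            raise ValueError("no person-time inside the calendar window")
        self.curve_ = product_limit(obs["time"], obs["event"], entry=obs["entry"],
                                    horizon=self.window.horizon, alpha=self.alpha)
        self.n_ = self.curve_.n_total
        return self

    def survival_at(self, t: float) -> PointEstimate:
        return os_at(self.curve_, t)


def period_survival(cases: pd.DataFrame, window: PeriodWindow,
                    alpha: float = 0.05) -> SurvivalCurve:
    """Functional form of :class:`PeriodSurvivalEstimator`."""
    return PeriodSurvivalEstimator(window, alpha).fit(cases).curve_


# ---------------------------------------------------------------------------
# Group comparison and derived statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    pvalue: float


def logrank(groups: Sequence[pd.DataFrame | tuple]) -> LogrankResult:
    """k-group log-rank test; each group supplies (time, event) observations.

    Groups may be DataFrames with ``time``/``event`` columns or (time, event)
    array pairs.
    """
    from lifelines.statistics import multivariate_logrank_test

    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for k, g in enumerate(groups):
        if isinstance(g, pd.DataFrame):
            t, e = g["time"].to_numpy(), g["event"].to_numpy()
        else:
            t, e = np.asarray(g[0], dtype=float), np.asarray(g[1], dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {k} has no observations")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, k))
    res = multivariate_logrank_test(np.concatenate(times), np.concatenate(labels),
                                    np.concatenate(events))
    return LogrankResult(float(res.test_statistic), len(groups) - 1, float(res.p_value))


def risk_reduction(s_early: float, s_late: float) -> float:
    """Percent reduction in the 5-year risk of death between two survival
    percentages: ``100 * (1 - (100 - s_late) / (100 - s_early))``."""
    if not (0.0 < s_early <= 100.0 and 0.0 < s_late <= 100.0):
        raise ValueError("survival percentages must lie in (0, 100]")
    if s_early == 100.0:
        raise ValueError("risk reduction undefined when early risk is zero")
    return 100.0 * (1.0 - (100.0 - s_late) / (100.0 - s_early))


def cohort_observations(cases: pd.DataFrame, horizon: float | None = None) -> pd.DataFrame:
    """Follow-up observations (time in years, death indicator) for cohort
    analyses, optionally right-truncated at ``horizon`` years."""
    diag = pd.to_datetime(cases["diagnosis_date"]).to_numpy(dtype="datetime64[D]")
    fu = pd.to_datetime(cases["followup_end_date"]).to_numpy(dtype="datetime64[D]")
    time = (fu - diag).astype(int) / DAYS_PER_YEAR
    event = (cases["vital_status"] == "dead").to_numpy()
    # same-day deaths get a half-day of survival so intervals are non-degenerate
    time = np.maximum(time, 0.5 / DAYS_PER_YEAR)
    if horizon is not None:
        event = event & (time <= horizon)
        time = np.minimum(time, horizon)
    return pd.DataFrame({"time": time, "event": event})
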