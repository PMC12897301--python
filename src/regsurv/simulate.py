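"""Synthetic cancer-registry generator with known survival ground truth.

Cases are drawn from a piecewise-exponential model: each age group has a
piecewise-constant baseline hazard over follow-up, multiplied by
``exp(beta . f(year))`` where ``f`` is the same continuous piecewise-linear
(hinge) calendar-year basis the trend-fitting module uses. Diagnosis-year
counts are Poisson, loss to follow-up is an independent exponential censoring
process, and everyone is administratively censored at the registry closure
date. Because the generative trend and the fitted trend share the hinge basis,
the Cox-joinpoint model is well-specified by default; a ``misspecified``
toggle instead applies the trend additively to 5-year survival for robustness
checks.

Closed-form ground truth (:func:`true_s5`, :func:`true_aacs`) is exposed for
parameter-recovery assertions downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

#: Default per-entry tumour mix: (ICCC code, share, P(non-malignant behaviour)).
#: Shares approximate a national childhood-cancer registry; they are
#: normalised at sampling time. Group III plus subgroup Xa carry a
#: non-malignant fraction so the CNS quality indicator is exercised.
DEFAULT_CODE_MIX: tuple[tuple[str, float, float], ...] = (
    ("Ia", 0.235, 0.0), ("Ib", 0.045, 0.0),
    ("IIa", 0.040, 0.0), ("IIb", 0.025, 0.0), ("IIc", 0.025, 0.0),
    ("IIe", 0.002, 0.0),
    ("IIIa", 0.020, 0.07), ("IIIb", 0.100, 0.55), ("IIIc", 0.050, 0.0),
    ("IIId", 0.040, 0.25), ("IIIf", 0.004, 0.5),
    ("IVa", 0.090, 0.0), ("V", 0.030, 0.0), ("VIa", 0.050, 0.0),
    ("VIIa", 0.012, 0.0), ("VIIIa", 0.025, 0.0), ("VIIIc", 0.020, 0.0),
    ("IXa", 0.035, 0.0), ("IXb", 0.020, 0.0),
    ("Xa", 0.005, 0.10), ("Xb", 0.010, 0.0), ("Xc", 0.015, 0.0),
    ("XIb", 0.020, 0.0), ("XIf", 0.002, 0.0), ("XII", 0.030, 0.0),
)

#: Baseline 5-year survival by age group at the series start implied by the
#: default hazards below: <1: 0.70, 1-4: 0.78, 5-9: 0.76, 10-14: 0.72 —
#: survival peaking at 1-4 years, mirroring the age pattern of childhood
#: cancer overall. Hazards are front-loaded (about half of the 5-year
#: cumulative hazard falls in the first year after diagnosis).
DEFAULT_BASELINE_HAZARDS: dict[str, tuple[float, ...]] = {
    "<1":    (0.178, 0.0625, 0.027),
    "1-4":   (0.124, 0.0435, 0.019),
    "5-9":   (0.137, 0.0480, 0.021),
    "10-14": (0.164, 0.0575, 0.025),
}

#: Expected annual case counts by age group (~870/yr, ~20,000 over 23 years;
#: infants ~10.9% of cases).
DEFAULT_ANNUAL_CASES: dict[str, float] = {
    "<1": 95.0, "1-4": 315.0, "5-9": 245.0, "10-14": 215.0,
}


def hinge_coefficients(segment_slopes: Sequence[float],
                       joinpoints: Sequence[int]) -> np.ndarray:
    """Per-segment slopes -> hinge-basis coefficients (b0, b1, ...).

    ``b0`` is the first-segment slope; ``bk`` is the slope change at the k-th
    joinpoint, so the slope on segment k is ``sum(b[:k+1])``.
    """
    slopes = np.asarray(segment_slopes, dtype=float)
    if len(slopes) != len(joinpoints) + 1:
        raise ValueError("need one slope per segment (len(joinpoints)+1)")
    return np.diff(slopes, prepend=0.0)


def hinge_eval(year, y0: int, joinpoints: Sequence[int]) -> np.ndarray:
    """Hinge basis f(y) = (y - y0, max(0, y - tau_1), ...); columns per term."""
    y = np.atleast_1d(np.asarray(year, dtype=float))
    cols = [y - y0] + [np.maximum(0.0, y - tau) for tau in joinpoints]
    return np.column_stack(cols)


@dataclass(frozen=True)
class TrendScenario:
    """Data-generating conditions for a synthetic registry.

    Parameters
    ----------
    years : inclusive incidence-year range.
    annual_cases : expected (Poisson mean) case count per age group per year.
    baseline_hazards : per-age-group piecewise-constant hazards (events per
        person-year) on the intervals given by ``hazard_cutpoints``; the last
        hazard extends beyond the final cutpoint.
    joinpoints / segment_slopes : calendar-year hinge trend on the log hazard;
        ``segment_slopes`` has one entry per segment (log-hazard-ratio change
        per calendar year).
    ltfu_rate : annual exponential loss-to-follow-up hazard. The default makes
        ~3% of cases lost before 5 years (1 - exp(-5 * rate) = 0.03).
    admin_close : administrative censoring date.
    """

    years: tuple[int, int] = (1999, 2021)
    annual_cases: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANNUAL_CASES))
    baseline_hazards: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_HAZARDS))
    hazard_cutpoints: tuple[float, ...] = (0.0, 1.0, 3.0)
    joinpoints: tuple[int, ...] = ()
    segment_slopes: tuple[float, ...] = (-0.024,)
    ltfu_rate: float = -math.log(0.97) / 5.0
    admin_close: date = date(2022, 12, 31)
    male_fraction: float = 0.54
    second_tumour_fraction: float = 0.006
    mv_prob: float = 0.895
    code_mix: tuple[tuple[str, float, float], ...] = DEFAULT_CODE_MIX
    misspecified: bool = False
    seed: int = 0

    def validate(self) -> None:
        y0, y1 = self.years
        if y0 > y1:
            raise ValueError("years range is empty")
        for a, hz in self.baseline_hazards.items():
            if len(hz) != len(self.hazard_cutpoints):
                raise ValueError(f"{a}: one hazard per cutpoint interval required")
            if any(h < 0 for h in hz):
                raise ValueError("hazards must be non-negative")
        if any(c <= 0 for c in self.annual_cases.values()):
            raise ValueError("expected annual case counts must be positive")
        if list(self.joinpoints) != sorted(set(self.joinpoints)):
            raise ValueError("joinpoints must be strictly increasing")
        if any(not (y0 < t < y1) for t in self.joinpoints):
            raise ValueError("joinpoints must be interior to the year range")
        if len(self.segment_slopes) != len(self.joinpoints) + 1:
            raise ValueError("need one slope per segment")
        if self.ltfu_rate < 0:
            raise ValueError("ltfu_rate must be non-negative")

    @property
    def age_groups(self) -> tuple[str, ...]:
        return tuple(self.annual_cases)

    def log_multiplier(self, year) -> np.ndarray:
        """beta . f(year): log hazard-rate multiplier relative to the series start."""
        b = hinge_coefficients(self.segment_slopes, self.joinpoints)
        return hinge_eval(year, self.years[0], self.joinpoints) @ b

    def cumulative_baseline(self, age_group: str, t: float) -> float:
        """Integral of the piecewise-constant baseline hazard over [0, t]."""
        hz = np.asarray(self.baseline_hazards[age_group], dtype=float)
        cuts = np.asarray(self.hazard_cutpoints, dtype=float)
        upper = np.append(cuts[1:], np.inf)
        lengths = np.clip(np.minimum(upper, t) - cuts, 0.0, None)
        return float(np.dot(hz, lengths))


def true_s5(scenario: TrendScenario, year: int, age_group: str,
            horizon: float = 5.0) -> float:
    """Exact model 5-year survival for a diagnosis year and age group."""
    y0, y1 = scenario.years
    if not (y0 <= year <= y1 + 1):  # +1: the prediction year just past the series
        raise ValueError(f"year {year} outside scenario range {scenario.years}")
    lam = scenario.cumulative_baseline(age_group, horizon)
    drift = float(scenario.log_multiplier(year)[0])
    if scenario.misspecified:
        # trend acts additively on 5-year survival, not on the hazard
        return float(np.clip(math.exp(-lam) - drift, 0.0, 1.0))
    return math.exp(-lam * math.exp(drift))


def true_aacs(scenario: TrendScenario, weights: Mapping[str, float] | None = None,
              end_year: int | None = None) -> float:
    """Ground-truth AACS: standardised true S5 change per year, in points.

    ``weights`` maps age groups to standardisation weights (defaults to equal
    weights over the scenario's groups); the statistic is
    ``(S5(end) - S5(start)) * 100 / (end - start)``.
    """
    y0, y1 = scenario.years
    end = end_year if end_year is not None else y1
    groups = scenario.age_groups
    if weights is None:
        weights = {a: 1.0 / len(groups) for a in groups}
    s_start = sum(weights[a] * true_s5(scenario, y0, a) for a in groups)
    s_end = sum(weights[a] * true_s5(scenario, end, a) for a in groups)
    return (s_end - s_start) * 100.0 / (end - y0)


def _sample_piecewise_exponential(rng: np.random.Generator,
                                  hazards: np.ndarray,
                                  cutpoints: np.ndarray,
                                  multiplier: np.ndarray) -> np.ndarray:
    """Draw event times from hazard ``multiplier * hazards`` (piecewise constant).

    Vectorised inversion: accumulate cumulative hazard interval by interval.
    Returns +inf where the target exceeds the total reachable hazard (only
    possible when every hazard is 0).
    """
    n = multiplier.shape[0]
    target = rng.exponential(size=n)  # -log U
    times = np.full(n, np.inf)
    acc = np.zeros(n)
    upper = np.append(cutpoints[1:], np.inf)
    for lo, hi, h in zip(cutpoints, upper, hazards):
        rate = multiplier * h
        if np.isfinite(hi):
            seg = (hi - lo) * rate
            hit = np.isinf(times) & (rate > 0) & (acc + seg >= target)
            times[hit] = lo + (target[hit] - acc[hit]) / rate[hit]
            acc = acc + seg
        else:
            hit = np.isinf(times) & (rate > 0)
            times[hit] = lo + (target[hit] - acc[hit]) / rate[hit]
    return times


def generate_registry(scenario: TrendScenario, seed: int | None = None) -> pd.DataFrame:
    """Sample a registry case table from the scenario's generative model.

    Follow-up is censored at min(death, loss to follow-up, administrative
    closure); the 5-year truncation used by the trend models is an analysis
    step and is *not* applied here. Byte-identical output under a fixed seed.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    y0, y1 = scenario.years
    years = np.arange(y0, y1 + 1)

    codes = np.array([c for c, _, _ in scenario.code_mix])
    shares = np.array([s for _, s, _ in scenario.code_mix], dtype=float)
    shares = shares / shares.sum()
    p_nonmal = np.array([p for _, _, p in scenario.code_mix], dtype=float)
    cuts = np.asarray(scenario.hazard_cutpoints, dtype=float)

    frames = []
    for age in scenario.age_groups:
        counts = rng.poisson(scenario.annual_cases[age], size=len(years))
        year = np.repeat(years, counts)
        n = year.size
        if n == 0:
            continue
        frac = rng.uniform(size=n)  # diagnosis date uniform within year
        year_start = np.array([date(y, 1, 1).toordinal() for y in years])
        year_len = np.array([(date(y + 1, 1, 1) - date(y, 1, 1)).days for y in years])
        diag_ord = np.repeat(year_start, counts) + np.floor(
            frac * np.repeat(year_len, counts)).astype(int)

        hz = np.asarray(scenario.baseline_hazards[age], dtype=float)
        if scenario.misspecified:
            # solve for the per-year hazard scale that yields the additive
            # survival drift; trend on S5 rather than on the hazard
            lam5 = scenario.cumulative_baseline(age, 5.0)
            s_target = np.clip(np.exp(-lam5) - scenario.log_multiplier(year),
                               1e-6, 1.0 - 1e-12)
            mult = np.log(s_target) / (-lam5)
        else:
            mult = np.exp(scenario.log_multiplier(year))
        death = _sample_piecewise_exponential(rng, hz, cuts, mult)
        lost = (rng.exponential(1.0 / scenario.ltfu_rate, size=n)
                if scenario.ltfu_rate > 0 else np.full(n, np.inf))
        admin = (scenario.admin_close.toordinal() - diag_ord) / DAYS_PER_YEAR

        end = np.minimum.reduce([death, lost, admin])
        status = np.where(death <= end, "dead",
                          np.where(lost <= admin, "lost", "alive"))
        end_ord = diag_ord + np.maximum(np.rint(end * DAYS_PER_YEAR), 0).astype(int)
        # administrative censoring must not overshoot the closure date by rounding
        end_ord = np.minimum(end_ord, scenario.admin_close.toordinal())

        code_idx = rng.choice(len(codes), size=n, p=shares)
        behaviour = np.where(rng.uniform(size=n) < p_nonmal[code_idx],
                             "non-malignant", "malignant")
        frames.append(pd.DataFrame({
            "diagnosis_date": [date.fromordinal(o) for o in diag_ord],
            "diagnosis_year": year,
            "age_group": age,
            "sex": np.where(rng.uniform(size=n) < scenario.male_fraction,
                            "male", "female"),
            "iccc_code": codes[code_idx],
            "behaviour": behaviour,
            "morphology": rng.integers(8000, 9990, size=n),
            "microscopically_verified": rng.uniform(size=n) < scenario.mv_prob,
            "sequence_number": np.where(
                rng.uniform(size=n) < scenario.second_tumour_fraction, 2, 1),
            "vital_status": status,
            "followup_end_date": [date.fromordinal(o) for o in end_ord],
        }))

    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["diagnosis_year", "diagnosis_date", "age_group"],
                          kind="mergesort").reset_index(drop=True)
    out.insert(0, "case_id", [f"S{i:06d}" for i in range(len(out))])
    return out[["case_id", "diagnosis_date", "diagnosis_year", "age_group", "sex",
                "iccc_code", "behaviour", "morphology", "microscopically_verified",
                "sequence_number", "vital_status", "followup_end_date"]]


def scenario_with(scenario: TrendScenario, **changes) -> TrendScenario:
    """Convenience: a copy of ``scenario`` with fields replaced."""
    return replace(scenario, **changes)
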