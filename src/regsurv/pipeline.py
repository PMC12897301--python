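"""End-to-end runs: simulate -> estimate -> standardise -> trend, with
table/series outputs, suppression and a run manifest.

Cohort tables mirror a registry report: observed 5-year (and 1/3-year) overall
survival per diagnostic group for four 5-year diagnosis cohorts plus a period
estimate for the most recent calendar window; by-age and by-sex tables add
log-rank comparisons; the trend runs fit the Cox-joinpoint models and emit the
fitted age-standardised series with AACS and its bootstrap interval.
Suppressed cells (fewer than 15 cases) are rendered as "-" and the underlying
estimate never reaches any output artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coxjp, km, standardise as std
from .records import AGE_GROUPS, parse_iccc

logger = logging.getLogger("regsurv")

#: Default diagnostic-group selections: name -> ICCC code prefixes.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "All tumours": ("I", "II", "III", "IV", "V", "VI", "VII", "VIII",
                    "IX", "X", "XI", "XII"),
    "Leukaemias": ("I",),
    "Lymphomas": ("II",),
    "CNS": ("III",),
}


@dataclass
class RunConfig:
    """Configuration of an end-to-end reporting run."""

    cohorts: tuple[tuple[int, int], ...] = (
        (1999, 2003), (2004, 2008), (2009, 2013), (2014, 2018))
    period_window: km.PeriodWindow = field(
        default_factory=lambda: km.PeriodWindow(2019, 2022))
    groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    horizon: float = 5.0
    min_cases: int = 15
    max_joinpoints: int = 2
    min_segment: int = 3
    bootstrap_reps: int = 500
    seed: int = 0
    age_table_cohort: tuple[int, int] = (2009, 2018)

    def __post_init__(self) -> None:
        spans = sorted(self.cohorts)
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if a1 >= b0:
                raise ValueError("cohorts must be disjoint and ordered")


def select_group(cases: pd.DataFrame, prefixes: Sequence[str]) -> pd.DataFrame:
    """Cases whose ICCC code matches any prefix. A bare group numeral (e.g.
    ``"III"``) matches the whole group; ``"IIIb"`` matches that subgroup."""
    parsed = [parse_iccc(p) for p in prefixes]

    def match(code: str) -> bool:
        g, sub = parse_iccc(code)
        return any(g == pg and (psub == "" or sub == psub) for pg, psub in parsed)

    return cases.loc[cases["iccc_code"].map(match)].reset_index(drop=True)


def _km_cell(cases: pd.DataFrame, horizon: float, t: float, min_cases: int) -> dict:
    n = len(cases)
    if n < min_cases:
        return {"n": n, "estimate": None, "ci_low": None, "ci_high": None,
                "suppressed": True}
    obs = km.cohort_observations(cases, horizon=horizon)
    curve = km.kaplan_meier(obs["time"], obs["event"], horizon=horizon)
    pt = km.os_at(curve, t)
    return {"n": n, "estimate": round(100 * pt.estimate, 1),
            "ci_low": round(100 * pt.ci_low, 1),
            "ci_high": round(100 * pt.ci_high, 1), "suppressed": False}


def run_cohort_tables(cases: pd.DataFrame, config: RunConfig | None = None,
                      times: Sequence[float] = (1.0, 3.0, 5.0)) -> pd.DataFrame:
    """Observed OS by diagnostic group and 5-year cohort; period estimate for
    the final window; suppression applied."""
    config = config or RunConfig()
    rows = []
    for name, prefixes in config.groups.items():
        sub = select_group(cases, prefixes)
        for (c0, c1) in config.cohorts:
            coh = sub.loc[(sub["diagnosis_year"] >= c0) & (sub["diagnosis_year"] <= c1)]
            for t in times:
                cell = _km_cell(coh, config.horizon, t, config.min_cases)
                rows.append({"group": name, "cohort": f"{c0}-{c1}", "t": t, **cell})
        # period estimate for the recent window
        w = config.period_window
        lo, hi = w.eligible_diagnosis_years
        eligible = sub.loc[(sub["diagnosis_year"] >= lo) & (sub["diagnosis_year"] <= hi)]
        for t in times:
            n = len(eligible)
            if n < config.min_cases:
                cell = {"n": n, "estimate": None, "ci_low": None,
                        "ci_high": None, "suppressed": True}
            else:
                curve = km.period_survival(eligible, w)
                pt = km.os_at(curve, t)
                cell = {"n": n, "estimate": round(100 * pt.estimate, 1),
                        "ci_low": round(100 * pt.ci_low, 1),
                        "ci_high": round(100 * pt.ci_high, 1), "suppressed": False}
            rows.append({"group": name,
                         "cohort": f"{w.calendar_start}-{w.calendar_end}",
                         "t": t, **cell})
    return pd.DataFrame(rows)


def run_age_sex_tables(cases: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Observed 5-year OS by (pooled) age group and by sex for the recent
    cohort, with log-rank p-values."""
    config = config or RunConfig()
    c0, c1 = config.age_table_cohort
    rows = []
    for name, prefixes in config.groups.items():
        sub = select_group(cases, prefixes)
        coh = sub.loc[(sub["diagnosis_year"] >= c0) & (sub["diagnosis_year"] <= c1)]
        if coh.empty:
            continue
        counts = pd.DataFrame(
            {g: [int((coh["age_group"] == g).sum())] for g in AGE_GROUPS})
        grouping = std.pool_age_groups(counts, min_cases=config.min_cases,
                                       infant_split=True)
        coh = coh.assign(age_label=grouping.assign(coh["age_group"]))
        groups_obs = []
        for lab in grouping.labels:
            part = coh.loc[coh["age_label"] == lab]
            cell = _km_cell(part, config.horizon, 5.0, config.min_cases)
            rows.append({"group": name, "axis": "age", "level": lab, **cell})
            if len(part):
                groups_obs.append(km.cohort_observations(part, horizon=config.horizon))
        p_age = (km.logrank(groups_obs).pvalue if len(groups_obs) >= 2 else np.nan)
        sex_obs = []
        for sex in ("female", "male"):
            part = coh.loc[coh["sex"] == sex]
            cell = _km_cell(part, config.horizon, 5.0, config.min_cases)
            rows.append({"group": name, "axis": "sex", "level": sex, **cell})
            if len(part):
                sex_obs.append(km.cohort_observations(part, horizon=config.horizon))
        p_sex = (km.logrank(sex_obs).pvalue if len(sex_obs) >= 2 else np.nan)
        rows.append({"group": name, "axis": "age", "level": "p_logrank",
                     "n": len(coh), "estimate": p_age, "ci_low": None,
                     "ci_high": None, "suppressed": False})
        rows.append({"group": name, "axis": "sex", "level": "p_logrank",
                     "n": len(coh), "estimate": p_sex, "ci_low": None,
                     "ci_high": None, "suppressed": False})
    return pd.DataFrame(rows)


@dataclass
class TrendRunResult:
    group: str
    model: coxjp.JoinpointCoxPH
    series: coxjp.TrendSeries
    weights: std.AgeWeights
    cohort_dots: pd.DataFrame
    period_dots: pd.DataFrame
    stratified: bool


def run_trends(cases: pd.DataFrame, config: RunConfig | None = None,
               groups: Mapping[str, tuple[str, ...]] | None = None,
               direction_hints: Mapping[str, str] | None = None,
               standardise_flags: Mapping[str, bool] | None = None,
               end_year: int = 2022) -> dict[str, TrendRunResult]:
    """Fit the Cox-joinpoint trend per diagnostic group.

    Per group: select joinpoints by BIC, derive case-pool age weights (after
    pooling), compute the standardised fitted series extended to ``end_year``
    (prediction, flagged), bootstrap the AACS, and attach the annual observed
    cohort and period estimates that the fitted curves are plotted against.
    Groups whose strata cannot support a stratified fit fall back to an
    unstratified fit with a logged note.
    """
    config = config or RunConfig()
    groups = groups if groups is not None else config.groups
    hints = direction_hints or {}
    flags = standardise_flags or {}
    y0 = int(cases["diagnosis_year"].min())
    y_last = int(cases["diagnosis_year"].max())
    years = np.arange(y0, end_year + 1)

    out: dict[str, TrendRunResult] = {}
    for name, prefixes in groups.items():
        sub = select_group(cases, prefixes)
        if sub.empty:
            logger.info("trend: %s has no cases; skipped", name)
            continue
        do_std = flags.get(name, True)
        counts = sub.pivot_table(index="diagnosis_year", columns="age_group",
                                 values="case_id", aggfunc="count").reindex(
            columns=list(AGE_GROUPS)).fillna(0).astype(int)
        grouping = (std.pool_age_groups(counts, min_cases=config.min_cases,
                                        direction_hint=hints.get(name, "none"))
                    if do_std else std.AgeGrouping(std.SINGLE))
        stratified = do_std and len(grouping.labels) > 1
        obs = coxjp.trend_observations(sub, grouping=grouping, horizon=config.horizon)

        try:
            model = coxjp.select_joinpoints(
                obs, max_joinpoints=config.max_joinpoints,
                min_segment=config.min_segment, horizon=config.horizon)
        except coxjp.ConvergenceError:
            if not stratified:
                raise
            logger.info("trend: %s stratified fit failed; falling back to "
                        "unstratified", name)
            grouping = std.AgeGrouping(std.SINGLE)
            stratified = False
            obs = coxjp.trend_observations(sub, grouping=grouping,
                                           horizon=config.horizon)
            model = coxjp.select_joinpoints(
                obs, max_joinpoints=config.max_joinpoints,
                min_segment=config.min_segment, horizon=config.horizon)

        weights = std.derive_weights(sub.assign(
            age_group=grouping.assign(sub["age_group"])), grouping)
        series = model.standardised_series(weights.as_dict(), years)
        boot = coxjp.bootstrap_aacs(
            obs, model.basis_, years, weights=None,
            B=config.bootstrap_reps, seed=config.seed)
        series.aacs = coxjp.aacs(series)
        series.aacs_ci = (boot.ci_low, boot.ci_high)

        dots = []
        for y in range(y0, y_last + 1):
            part = sub.loc[sub["diagnosis_year"] == y]
            cell = _km_cell(part, config.horizon, config.horizon, config.min_cases)
            dots.append({"year": y, **cell})
        pdots = []
        for y in range(max(y0 + 1, y_last - 3), end_year + 1):
            w = km.PeriodWindow(y, y, horizon=config.horizon)
            lo, hi = w.eligible_diagnosis_years
            eligible = sub.loc[(sub["diagnosis_year"] >= lo)
                               & (sub["diagnosis_year"] <= hi)]
            try:
                curve = km.period_survival(eligible, w)
                pt = km.os_at(curve, config.horizon)
                pdots.append({"year": y, "estimate": round(100 * pt.estimate, 1),
                              "n": curve.n_total})
            except ValueError:
                pdots.append({"year": y, "estimate": None, "n": len(eligible)})
        out[name] = TrendRunResult(
            group=name, model=model, series=series, weights=weights,
            cohort_dots=pd.DataFrame(dots), period_dots=pd.DataFrame(pdots),
            stratified=stratified)
        logger.info("trend: %s joinpoints=%s AACS=%.3f [%.3f, %.3f]", name,
                    model.basis_.joinpoints, series.aacs, *series.aacs_ci)
    return out


def render_table(table: pd.DataFrame) -> pd.DataFrame:
    """Reporting view: suppressed cells become '-', estimates formatted."""
    view = table.copy()

    def fmt(row):
        if row.get("suppressed"):
            return "-"
        if row["estimate"] is None or (isinstance(row["estimate"], float)
                                       and np.isnan(row["estimate"])):
            return "-"
        if row.get("ci_low") is None:
            return f"{row['estimate']:.3g}"
        return f"{row['estimate']} [{row['ci_low']}, {row['ci_high']}]"

    view["cell"] = view.apply(fmt, axis=1)
    return view.drop(columns=[c for c in ("estimate", "ci_low", "ci_high")
                              if c in view.columns])


def write_outputs(outdir: str | Path, *, config: RunConfig,
                  tables: Mapping[str, pd.DataFrame] | None = None,
                  trends: Mapping[str, TrendRunResult] | None = None,
                  input_hash: str = "") -> None:
    """Serialise run outputs (CSV + JSON) and a machine-readable manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "input_sha256": input_hash,
                "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
                "outputs": []}
    for name, tab in (tables or {}).items():
        path = outdir / f"{name}.csv"
        render_table(tab).to_csv(path, index=False)
        manifest["outputs"].append(path.name)
    for name, res in (trends or {}).items():
        slug = name.lower().replace(" ", "_").replace("/", "-")
        frame = res.series.to_frame()
        frame.to_csv(outdir / f"trend_{slug}.csv", index=False)
        meta = {
            "group": name,
            "joinpoints": list(res.model.basis_.joinpoints),
            "segment_slopes": list(res.model.basis_.segment_slopes(res.model.coef_)),
            "bic": res.model.bic_,
            "aacs": res.series.aacs,
            "aacs_ci": list(res.series.aacs_ci) if res.series.aacs_ci else None,
            "weights": res.weights.as_dict(),
            "stratified": res.stratified,
        }
        (outdir / f"trend_{slug}.json").write_text(json.dumps(meta, indent=2))
        res.cohort_dots.to_csv(outdir / f"dots_cohort_{slug}.csv", index=False)
        res.period_dots.to_csv(outdir / f"dots_period_{slug}.csv", index=False)
        manifest["outputs"] += [f"trend_{slug}.csv", f"trend_{slug}.json"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def hash_cases(cases: pd.DataFrame) -> str:
    payload = cases.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
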