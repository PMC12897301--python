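"""Registry case records: domain types, delimited-text I/O, cohort filters and
IARC-style quality indicators.

The registry table is a headered delimited-text file (CSV/TSV), one row per
registered tumour. Column names are mapped onto the canonical fields through a
:class:`RegistryDialect`, so files from different registries can be read without
renaming columns by hand. Analyses operate on a :class:`pandas.DataFrame` with
the canonical columns; :class:`CaseRecord` is the validated row-level view.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

AGE_GROUPS: tuple[str, ...] = ("<1", "1-4", "5-9", "10-14")
#: Pooled labels a registry table may also carry (adjacent-group merges).
POOLED_AGE_GROUPS: tuple[str, ...] = ("0-4", "0-9", "5-14", "0-14")
VALID_AGE_LABELS: tuple[str, ...] = AGE_GROUPS + POOLED_AGE_GROUPS
SEXES: tuple[str, ...] = ("female", "male")
BEHAVIOURS: tuple[str, ...] = ("malignant", "non-malignant")
VITAL_STATUSES: tuple[str, ...] = ("alive", "dead", "lost")

#: Canonical column order of the registry table.
COLUMNS: tuple[str, ...] = (
    "case_id",
    "diagnosis_date",
    "diagnosis_year",
    "age_group",
    "sex",
    "iccc_code",
    "behaviour",
    "morphology",
    "microscopically_verified",
    "sequence_number",
    "vital_status",
    "followup_end_date",
)

#: Unspecified-diagnosis (NOS) ICCC codes used by the quality indicator, plus
#: leukaemias whose morphology is one of the unspecific histology codes.
NOS_CODES: frozenset[str] = frozenset(
    {"IIe", "IIIf", "VIc", "VIIc", "VIIIe", "IXe", "Xe", "XIf", "XIIb"}
)
NOS_LEUKAEMIA_MORPHOLOGIES: frozenset[int] = frozenset({8000, 8800, 9800})

_ROMAN = {
    "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6,
    "VII": 7, "VIII": 8, "IX": 9, "X": 10, "XI": 11, "XII": 12,
}
_ICCC_RE = re.compile(r"^(XII|XI|X|IX|VIII|VII|VI|V|IV|III|II|I)([a-f]?)$")


def parse_iccc(code: str) -> tuple[int, str]:
    """Split an ICCC label like ``"IIIb"`` into (group number, subgroup suffix).

    The suffix is empty for bare group labels (``"X"`` -> (10, "")).
    """
    m = _ICCC_RE.match(str(code).strip())
    if m is None:
        raise ValueError(f"unparseable ICCC code: {code!r}")
    return _ROMAN[m.group(1)], m.group(2)


def iccc_group(codes: Iterable[str]) -> np.ndarray:
    return np.array([parse_iccc(c)[0] for c in codes], dtype=int)


@dataclass(frozen=True)
class CaseRecord:
    """One registered tumour with diagnosis timing, strata and follow-up outcome."""

    case_id: str
    diagnosis_date: date
    diagnosis_year: int
    age_group: str
    sex: str
    iccc_code: str
    behaviour: str
    morphology: int
    microscopically_verified: bool
    sequence_number: int
    vital_status: str
    followup_end_date: date

    def validate(self) -> None:
        if self.followup_end_date < self.diagnosis_date:
            raise ValueError("followup_end_date before diagnosis_date")
        if self.diagnosis_date.year != self.diagnosis_year:
            raise ValueError("diagnosis_year inconsistent with diagnosis_date")
        if self.age_group not in VALID_AGE_LABELS:
            raise ValueError(f"unknown age_group {self.age_group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if self.vital_status not in VITAL_STATUSES:
            raise ValueError(f"unknown vital_status {self.vital_status!r}")
        if self.sequence_number < 1:
            raise ValueError("sequence_number must be >= 1")
        parse_iccc(self.iccc_code)


@dataclass(frozen=True)
class RegistryDialect:
    """Mapping from file columns to canonical fields plus the delimiter.

    ``columns`` maps canonical field name -> column name in the file; fields
    absent from the mapping are assumed to use the canonical name.
    """

    delimiter: str = ","
    columns: Mapping[str, str] = field(default_factory=dict)

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_file(cls, path: str | Path) -> "RegistryDialect":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(delimiter=raw.get("delimiter", ","), columns=raw.get("columns", {}))


@dataclass(frozen=True)
class RowRejection:
    row: int          # 0-based data-row index in the file
    reason: str


@dataclass
class ReadResult:
    records: pd.DataFrame
    rejections: list[RowRejection]

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _coerce_bool(values: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    return values.astype(str).str.strip().str.lower().map(mapping)


def read_registry(path: str | Path, dialect: RegistryDialect | None = None) -> ReadResult:
    """Read a delimited registry table, validating every row.

    Invalid rows are reported (row number + reason) rather than raising; a
    missing mandatory column is a configuration error and does raise.
    """
    dialect = dialect or RegistryDialect()
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    missing = [c for c in COLUMNS if dialect.file_column(c) not in raw.columns]
    if missing:
        raise KeyError(f"registry file lacks mapped columns for: {missing}")
    df = pd.DataFrame({c: raw[dialect.file_column(c)] for c in COLUMNS})

    rejections: list[RowRejection] = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        for i in df.index[mask & ~bad]:
            rejections.append(RowRejection(int(i), reason))
        bad |= mask

    ddate = pd.to_datetime(df["diagnosis_date"], format="%Y-%m-%d", errors="coerce")
    fdate = pd.to_datetime(df["followup_end_date"], format="%Y-%m-%d", errors="coerce")
    flag(ddate.isna() | fdate.isna(), "unparseable ISO-8601 date")
    flag(fdate < ddate, "followup_end_date before diagnosis_date")

    year = pd.to_numeric(df["diagnosis_year"], errors="coerce")
    flag(year.isna() | (year != ddate.dt.year), "diagnosis_year inconsistent with diagnosis_date")
    flag(~df["age_group"].isin(VALID_AGE_LABELS), "unknown age_group")
    flag(~df["sex"].isin(SEXES), "unknown sex")
    flag(~df["behaviour"].isin(BEHAVIOURS), "unknown behaviour")
    flag(~df["vital_status"].isin(VITAL_STATUSES), "unknown vital_status")

    morph = pd.to_numeric(df["morphology"], errors="coerce")
    flag(morph.isna(), "non-numeric morphology code")
    seq = pd.to_numeric(df["sequence_number"], errors="coerce")
    flag(seq.isna() | (seq < 1), "sequence_number must be a positive integer")
    mv = _coerce_bool(df["microscopically_verified"])
    flag(mv.isna(), "unparseable microscopically_verified flag")

    code_ok = df["iccc_code"].astype(str).apply(lambda c: _ICCC_RE.match(c.strip()) is not None)
    flag(~code_ok, "unparseable ICCC code")

    keep = ~bad
    out = pd.DataFrame({
        "case_id": df.loc[keep, "case_id"].astype(str),
        "diagnosis_date": ddate[keep].dt.date,
        "diagnosis_year": year[keep].astype(int),
        "age_group": df.loc[keep, "age_group"],
        "sex": df.loc[keep, "sex"],
        "iccc_code": df.loc[keep, "iccc_code"].astype(str).str.strip(),
        "behaviour": df.loc[keep, "behaviour"],
        "morphology": morph[keep].astype(int),
        "microscopically_verified": mv[keep].astype(bool),
        "sequence_number": seq[keep].astype(int),
        "vital_status": df.loc[keep, "vital_status"],
        "followup_end_date": fdate[keep].dt.date,
    }).reset_index(drop=True)
    return ReadResult(out, rejections)


def write_registry(cases: pd.DataFrame, path: str | Path,
                   dialect: RegistryDialect | None = None) -> None:
    """Write the canonical registry table; inverse of :func:`read_registry`."""
    dialect = dialect or RegistryDialect()
    out = cases[list(COLUMNS)].copy()
    out["microscopically_verified"] = out["microscopically_verified"].map(
        {True: "true", False: "false"})
    out["diagnosis_date"] = out["diagnosis_date"].map(lambda d: d.isoformat())
    out["followup_end_date"] = out["followup_end_date"].map(lambda d: d.isoformat())
    out.columns = [dialect.file_column(c) for c in COLUMNS]
    out.to_csv(path, sep=dialect.delimiter, index=False)


def records_from_frame(cases: pd.DataFrame) -> list[CaseRecord]:
    """Materialise validated :class:`CaseRecord` objects from the table view."""
    out = []
    for row in cases.itertuples(index=False):
        rec = CaseRecord(**{c: getattr(row, c) for c in COLUMNS})
        rec.validate()
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortFilterConfig:
    """Registry exclusions: diagnostic codes dropped wholesale and the valid
    incidence-year range."""

    excluded_codes: tuple[str, ...] = ("Id", "IId")
    year_range: tuple[int, int] = (1999, 2021)


def apply_cohort_filters(cases: pd.DataFrame,
                         config: CohortFilterConfig | None = None) -> pd.DataFrame:
    """Drop excluded diagnostic codes and out-of-range incidence years.

    Returns a new frame; the input is untouched. Idempotent.
    """
    config = config or CohortFilterConfig()
    lo, hi = config.year_range
    keep = (
        ~cases["iccc_code"].isin(config.excluded_codes)
        & (cases["diagnosis_year"] >= lo)
        & (cases["diagnosis_year"] <= hi)
    )
    return cases.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Quality indicators
# ---------------------------------------------------------------------------

def proportion_pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded for reporting."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class QualityReport:
    """IARC-style registry quality indicators, all percentages in [0, 100].

    ``dco_pct`` is structurally 0: the registry does not use death certificates
    as a registration source, so no case can be death-certificate-only.
    """

    mv_pct: float
    dco_pct: float
    nos_pct: float
    infant_pct: float
    nonmalignant_cns_pct: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def to_table(self) -> str:
        rows = [
            ("Microscopically verified cases (MV%)", f"{self.mv_pct}"),
            ("Cases ascertained from death certificate only (DCO%)", "-"),
            ("Proportion of unspecified cases (NOS%)", f"{self.nos_pct}"),
            ("Cases aged < 1-year (%)", f"{self.infant_pct}"),
            ("Non-malignant CNS cases (%)", f"{self.nonmalignant_cns_pct}"),
        ]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {val}" for name, val in rows)


def _cns_mask(cases: pd.DataFrame) -> pd.Series:
    """CNS scope for the quality indicator: diagnostic group III plus subgroup Xa."""
    parsed = cases["iccc_code"].map(parse_iccc)
    group = parsed.map(lambda t: t[0])
    sub = parsed.map(lambda t: t[1])
    return (group == 3) | ((group == 10) & (sub == "a"))


def quality_indicators(cases: pd.DataFrame) -> QualityReport:
    """Compute registry quality indicators from the case table."""
    n = len(cases)
    if n == 0:
        raise ValueError("quality indicators undefined on an empty case collection")

    parsed = cases["iccc_code"].map(parse_iccc)
    group = parsed.map(lambda t: t[0])
    nos = cases["iccc_code"].isin(NOS_CODES) | (
        (group == 1) & cases["morphology"].isin(NOS_LEUKAEMIA_MORPHOLOGIES)
    )
    cns = _cns_mask(cases)
    n_cns = int(cns.sum())
    nm_cns = proportion_pct(
        int((cns & (cases["behaviour"] == "non-malignant")).sum()), n_cns
    ) if n_cns else 0.0

    return QualityReport(
        mv_pct=proportion_pct(int(cases["microscopically_verified"].sum()), n),
        dco_pct=0.0,
        nos_pct=proportion_pct(int(nos.sum()), n),
        infant_pct=proportion_pct(int((cases["age_group"] == "<1").sum()), n),
        nonmalignant_cns_pct=nm_cns,
    )


@dataclass(frozen=True)
class TrendTestResult:
    slope: float
    se: float
    pvalue: float
    n_years: int


def nonmalignant_cns_trend_test(cases: pd.DataFrame) -> TrendTestResult:
    """OLS of the annual non-malignant proportion among CNS cases on diagnosis year.

    Returns the slope (proportion per calendar year), its standard error and the
    two-sided p-value. Needs at least three diagnosis years with CNS cases.
    """
    import statsmodels.api as sm

    cns = cases.loc[_cns_mask(cases)]
    if cns.empty:
        raise ValueError("no CNS cases")
    annual = cns.groupby("diagnosis_year")["behaviour"].agg(
        prop=lambda b: float((b == "non-malignant").mean()))
    if len(annual) < 3:
        raise ValueError("need >=3 diagnosis years with CNS cases")
    x = sm.add_constant(annual.index.to_numpy(dtype=float))
    fit = sm.OLS(annual["prop"].to_numpy(), x).fit()
    return TrendTestResult(
        slope=float(fit.params[1]), se=float(fit.bse[1]),
        pvalue=float(fit.pvalues[1]), n_years=len(annual),
    )
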