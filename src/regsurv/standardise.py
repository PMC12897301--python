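"""Age standardisation with case-pool weights, adjacent-group pooling and
small-cell suppression.

Weights are derived from the registry's own case pool (each age group's share
of all cases of the tumour over the whole incidence period), so standardised
estimates stay on the scale of the observed all-ages survival. Age groups are
pooled to the coarsest-necessary grouping whenever any group in any diagnosis
cohort holds fewer than ``min_cases`` cases, and estimates based on fewer than
``min_cases`` cases are suppressed in reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import AGE_GROUPS

#: Base age groups and the standard pooled groupings, ordered fine -> coarse.
FOUR_GROUPS = AGE_GROUPS                        # <1 / 1-4 / 5-9 / 10-14
THREE_GROUPS = ("0-4", "5-9", "10-14")
OLD_HEAVY = ("0-9", "10-14")
YOUNG_HEAVY = ("0-4", "5-14")
SINGLE = ("0-14",)

_MEMBERS: dict[str, tuple[str, ...]] = {
    "<1": ("<1",), "1-4": ("1-4",), "5-9": ("5-9",), "10-14": ("10-14",),
    "0-4": ("<1", "1-4"), "0-9": ("<1", "1-4", "5-9"),
    "5-14": ("5-9", "10-14"), "0-14": AGE_GROUPS,
}


@dataclass(frozen=True)
class AgeGrouping:
    """Ordered (possibly pooled) age-group labels with the base-group mapping."""

    labels: tuple[str, ...]

    def map_base(self, base_group: str) -> str:
        for label in self.labels:
            if base_group in _MEMBERS[label]:
                return label
        raise KeyError(f"age group {base_group!r} not covered by {self.labels}")

    def assign(self, base_groups: pd.Series) -> pd.Series:
        table = {b: lab for lab in self.labels for b in _MEMBERS[lab]}
        table.update({lab: lab for lab in self.labels})  # idempotent on labels
        out = base_groups.map(table)
        if out.isna().any():
            missing = sorted(base_groups[out.isna()].unique())
            raise KeyError(f"age groups not covered by grouping: {missing}")
        return out


@dataclass(frozen=True)
class AgeWeights:
    """Standardisation weights over an age grouping; weights sum to 1."""

    grouping: AgeGrouping
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.grouping.labels):
            raise ValueError("one weight per age-group label required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.grouping.labels, self.weights))

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


@dataclass
class StandardisedEstimate:
    """Weighted survival estimate with SE and its per-group components."""

    value: float
    se: float
    components: pd.DataFrame  # columns: group, value, se, n
    suppressed: bool = False

    def reportable(self) -> str:
        return "-" if self.suppressed else f"{100 * self.value:.1f}"


def derive_weights(case_pool: pd.DataFrame | Mapping[str, int],
                   grouping: AgeGrouping | Sequence[str]) -> AgeWeights:
    """Case-pool weights: each grouped age class's share of the full pool."""
    if not isinstance(grouping, AgeGrouping):
        grouping = AgeGrouping(tuple(grouping))
    if isinstance(case_pool, pd.DataFrame):
        if case_pool.empty:
            raise ValueError("empty case pool")
        grouped = grouping.assign(case_pool["age_group"])
        counts = grouped.value_counts()
    else:
        relabelled: dict[str, float] = {}
        for k, v in dict(case_pool).items():
            lab = k if k in grouping.labels else grouping.map_base(k)
            relabelled[lab] = relabelled.get(lab, 0.0) + float(v)
        counts = pd.Series(relabelled, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty case pool")
    w = tuple(float(counts.get(lab, 0)) / total for lab in grouping.labels)
    return AgeWeights(grouping, w)


def pool_age_groups(counts_per_cohort: pd.DataFrame | Mapping[str, Mapping[str, int]],
                    min_cases: int = 15,
                    direction_hint: str = "none",
                    infant_split: bool = False) -> AgeGrouping:
    """Coarsest-necessary age grouping given per-cohort case counts.

    ``counts_per_cohort`` has one row per diagnosis cohort and one column per
    base age group (<1, 1-4, 5-9, 10-14). The starting point is the
    three-group standard 0-4/5-9/10-14; with ``infant_split=True`` (by-age
    tables) the <1 group is kept separate, but only when both <1 and 1-4 reach
    ``min_cases`` in every cohort. Deficient groupings are merged to
    0-9/10-14 for tumours typically diagnosed at older ages
    (``direction_hint='old-heavy'``), to 0-4/5-14 for young-heavy tumours, or
    toward the neighbour giving the larger combined count when no hint is
    given; if still deficient, all ages collapse to a single 0-14 group (no
    standardisation possible).
    """
    counts = pd.DataFrame(counts_per_cohort).T if isinstance(
        counts_per_cohort, Mapping) else pd.DataFrame(counts_per_cohort)
    missing = [g for g in AGE_GROUPS if g not in counts.columns]
    if missing:
        raise KeyError(f"counts lack base age groups: {missing}")
    counts = counts[list(AGE_GROUPS)]
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative case counts")
    if direction_hint not in ("young-heavy", "old-heavy", "none"):
        raise ValueError(f"unknown direction_hint {direction_hint!r}")

    def min_cell(labels: tuple[str, ...]) -> int:
        pooled = pd.DataFrame(
            {lab: counts[list(_MEMBERS[lab])].sum(axis=1) for lab in labels})
        return int(pooled.to_numpy().min())

    if infant_split and min_cell(FOUR_GROUPS) >= min_cases:
        return AgeGrouping(FOUR_GROUPS)
    if min_cell(THREE_GROUPS) >= min_cases:
        return AgeGrouping(THREE_GROUPS)

    if direction_hint == "old-heavy":
        merged = OLD_HEAVY
    elif direction_hint == "young-heavy":
        merged = YOUNG_HEAVY
    else:
        merged = OLD_HEAVY if min_cell(OLD_HEAVY) >= min_cell(YOUNG_HEAVY) else YOUNG_HEAVY
    if min_cell(merged) >= min_cases:
        return AgeGrouping(merged)
    return AgeGrouping(SINGLE)


def standardise(estimates: pd.DataFrame | Mapping[str, tuple[float, float]],
                weights: AgeWeights) -> StandardisedEstimate:
    """Weighted combination of per-group estimates: value = sum(w_a * S_a),
    SE = sqrt(sum(w_a^2 * se_a^2)) assuming independent strata."""
    if isinstance(estimates, Mapping):
        est = pd.DataFrame(
            [(g, v[0], v[1], v[2] if len(v) > 2 else np.nan)
             for g, v in estimates.items()],
            columns=["group", "value", "se", "n"])
    else:
        est = estimates.copy()
        if "n" not in est.columns:
            est["n"] = np.nan
    if set(est["group"]) != set(weights.grouping.labels):
        raise ValueError(
            f"grouping mismatch: estimates {sorted(est['group'])} vs "
            f"weights {sorted(weights.grouping.labels)}")
    est = est.set_index("group").loc[list(weights.grouping.labels)].reset_index()
    w = np.asarray(weights.weights)
    value = float(np.dot(w, est["value"]))
    se = float(np.sqrt(np.dot(w ** 2, est["se"] ** 2)))
    return StandardisedEstimate(value=value, se=se, components=est)


def suppress_small(value, n: int, min_cases: int = 15):
    """Suppress estimates based on fewer than ``min_cases`` cases.

    Returns the value unchanged when ``n >= min_cases``; otherwise a
    :class:`StandardisedEstimate` is returned with ``suppressed=True`` and
    any other value is replaced by ``None``.
    """
    if n < 0:
        raise ValueError("negative case count")
    if n >= min_cases:
        return value
    if isinstance(value, StandardisedEstimate):
        value.suppressed = True
        return value
    return None
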