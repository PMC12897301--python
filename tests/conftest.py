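from datetime import date

import pandas as pd
import pytest

from regsurv.simulate import TrendScenario, generate_registry


def make_case(**overrides) -> dict:
    """One valid registry row, overridable per field."""
    base = dict(
        case_id="C001", diagnosis_date=date(2005, 3, 14), diagnosis_year=2005,
        age_group="1-4", sex="female", iccc_code="Ia", behaviour="malignant",
        morphology=9811, microscopically_verified=True, sequence_number=1,
        vital_status="alive", followup_end_date=date(2010, 3, 14),
    )
    base.update(overrides)
    return base


def make_frame(*rows) -> pd.DataFrame:
    return pd.DataFrame([make_case(case_id=f"C{i:03d}", **r)
                         for i, r in enumerate(rows)])


@pytest.fixture(scope="session")
def default_registry() -> pd.DataFrame:
    """One realistic synthetic registry shared across read-only tests."""
    return generate_registry(TrendScenario(seed=11), seed=11)


@pytest.fixture(scope="session")
def flat_scenario() -> TrendScenario:
    """Single age group, constant hazard 0.1/yr, no calendar trend, and a
    closure date far enough out that administrative censoring never binds
    within 5 years."""
    return TrendScenario(
        annual_cases={"0-14": 870.0},
        baseline_hazards={"0-14": (0.1, 0.1, 0.1)},
        segment_slopes=(0.0,), ltfu_rate=0.0,
        admin_close=date(2060, 12, 31), seed=5,
    )
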