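import numpy as np
import pandas as pd
import pytest

from rollrisk.synthetic import (
    JourneyChain,
    PlantedFactor,
    SyntheticConfig,
    generate_cohort,
)
from rollrisk.timeseries import parse_month

START = parse_month("2015-04")


def month_date(offset: int, day: int = 15) -> str:
    m = START + offset
    return f"{m // 12:04d}-{m % 12 + 1:02d}-{day:02d}"


def make_events(records) -> pd.DataFrame:
    """records: (patient_id, category, code, month_offset[, value])"""
    rows = []
    for rec in records:
        pid, cat, code, off = rec[:4]
        val = rec[4] if len(rec) > 4 else np.nan
        rows.append((pid, cat, code, month_date(off), val))
    return pd.DataFrame(rows, columns=["patient_id", "category", "code", "event_date", "numeric_value"])


def make_demo(records) -> pd.DataFrame:
    """records: (patient_id, attribute, value[, effective_date])"""
    rows = []
    for rec in records:
        pid, attr, value = rec[:3]
        eff = rec[3] if len(rec) > 3 else None
        rows.append((pid, attr, value, eff))
    return pd.DataFrame(rows, columns=["patient_id", "attribute", "value", "effective_date"])


def adult(pid: str):
    return (pid, "birth_date", "1970-06-15")


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size synthetic cohort with planted signal, shared across tests."""
    cfg = SyntheticConfig(
        n_patients=800,
        n_months=36,
        planted_factors=(
            PlantedFactor("RISKA", "diagnosis", 0.25, 8.0, "start"),
            PlantedFactor("PROTA", "medication", 0.20, 1e-6, "start"),
        ),
        journey_chains=(
            JourneyChain((("LAB_X", "lab"), ("DX_X", "diagnosis"), ("MED_X", "medication"))),
        ),
        n_null_codes=60,
        baseline_hazard=0.0012,
        master_seed=7,
    )
    events, demographics, truth = generate_cohort(cfg)
    return cfg, events, demographics, truth
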