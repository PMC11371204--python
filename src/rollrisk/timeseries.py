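"""Patient-month time-series construction from event-level clinical tables.

The longitudinal unit is the *patient-month*: one row per calendar month in
which a patient has at least one hospital encounter.  Months are handled as
absolute integer indices (``year * 12 + month - 1``) so month arithmetic is
exact and timezone-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CATEGORIES = frozenset(
    {
        "encounter",
        "diagnosis",
        "procedure",
        "medication",
        "lab",
        "flowsheet",
        "vital",
        "chief_complaint",
    }
)

EVENT_COLUMNS = ["patient_id", "category", "code", "event_date", "numeric_value"]
DEMO_COLUMNS = ["patient_id", "attribute", "value", "effective_date"]

#: outcome value used for rows whose follow-up window extends past the horizon
UNOBSERVABLE = pd.NA


def month_index(dates) -> pd.Series | int:
    """Absolute calendar-month index (``year*12 + month - 1``) of date(s)."""
    if np.isscalar(dates) or isinstance(dates, (pd.Timestamp, str)):
        ts = pd.Timestamp(dates)
        return ts.year * 12 + ts.month - 1
    dt = pd.to_datetime(pd.Series(dates))
    return (dt.dt.year * 12 + dt.dt.month - 1).astype("int64")


def month_label(idx: int) -> str:
    """Inverse of :func:`month_index` restricted to 'YYYY-MM' labels."""
    return f"{idx // 12:04d}-{idx % 12 + 1:02d}"


def parse_month(label: str) -> int:
    """Parse a 'YYYY-MM' label into an absolute month index."""
    year, month = label.split("-")
    return int(year) * 12 + int(month) - 1


@dataclass(frozen=True)
class CohortSpec:
    """Endpoint definition and cohort eligibility rules.

    ``endpoint_codes`` are matched as code *prefixes* so a family like
    ``{"I63", "I64"}`` captures every sub-code (``I63.4`` etc.).
    """

    endpoint_codes: frozenset = field(
        default_factory=lambda: frozenset({"G45", "I63", "I64", "I20", "I21", "I22", "I23", "I24", "I25"})
    )
    min_age_years: int = 18
    followup_months: int = 12
    death_policy: str = "code_as_no_outcome"

    def __post_init__(self):
        if self.followup_months < 1:
            raise ValueError("followup_months must be >= 1")
        if not self.endpoint_codes:
            raise ValueError("endpoint_codes must be non-empty")
        if self.death_policy != "code_as_no_outcome":
            raise ValueError(f"unknown death_policy: {self.death_policy!r}")
        object.__setattr__(self, "endpoint_codes", frozenset(self.endpoint_codes))


def validate_events(events: pd.DataFrame) -> None:
    """Schema check for an event table; raises ``ValueError`` naming offenders."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns and c != "numeric_value"]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    bad = ~events["category"].isin(VALID_CATEGORIES)
    if bad.any():
        idx = events.index[bad][:5].tolist()
        vals = events.loc[bad, "category"].unique()[:5].tolist()
        raise ValueError(f"unknown event category values {vals} at rows {idx}")
    empty = events["code"].isna() | (events["code"].astype(str).str.len() == 0)
    if empty.any():
        raise ValueError(f"empty event codes at rows {events.index[empty][:5].tolist()}")


def _with_month(events: pd.DataFrame) -> pd.DataFrame:
    if "month_index" in events.columns:
        return events
    out = events.copy()
    out["month_index"] = month_index(events["event_date"]).to_numpy()
    return out


def matches_endpoint(codes: pd.Series, spec: CohortSpec) -> pd.Series:
    """Boolean mask of codes that belong to the endpoint family (prefix match)."""
    prefixes = tuple(sorted(spec.endpoint_codes))
    return codes.astype(str).str.startswith(prefixes)


def endpoint_month_by_patient(events: pd.DataFrame, spec: CohortSpec) -> pd.Series:
    """Month index of each patient's *first* qualifying endpoint code."""
    ev = _with_month(events)
    hits = ev.loc[matches_endpoint(ev["code"], spec) & (ev["category"] == "diagnosis")]
    return hits.groupby("patient_id")["month_index"].min()


def _attribute_month(demographics: pd.DataFrame, attribute: str) -> pd.Series:
    rows = demographics.loc[demographics["attribute"] == attribute]
    if rows.empty:
        return pd.Series(dtype="float64")
    months = month_index(rows["value"])
    return pd.Series(months.to_numpy(), index=rows["patient_id"].to_numpy(), dtype="float64")


def birth_month_by_patient(demographics: pd.DataFrame) -> pd.Series:
    return _attribute_month(demographics, "birth_date")


def death_month_by_patient(demographics: pd.DataFrame) -> pd.Series:
    return _attribute_month(demographics, "death_date")


def apply_cohort_filters(
    events: pd.DataFrame, demographics: pd.DataFrame, spec: CohortSpec
) -> pd.Index:
    """Return the eligible patient set.

    A patient is eligible when they have at least one encounter, are at least
    ``min_age_years`` old at their first encounter, and — if they ever exhibit
    the endpoint — their first encounter falls strictly before the endpoint's
    month (so the initial encounter is not associated with the endpoint and at
    least one patient-month precedes it).
    """
    validate_events(events)
    ev = _with_month(events)
    enc = ev.loc[ev["category"] == "encounter"]
    first_enc = enc.groupby("patient_id")["month_index"].min()

    birth = birth_month_by_patient(demographics)
    aligned_birth = birth.reindex(first_enc.index)
    age_years = (first_enc - aligned_birth) / 12.0
    old_enough = age_years >= spec.min_age_years
    # missing birth date cannot satisfy the age rule
    old_enough = old_enough.fillna(False)

    ep = endpoint_month_by_patient(ev, spec).reindex(first_enc.index)
    pre_endpoint = ep.isna() | (first_enc < ep)

    eligible = first_enc.index[old_enough.to_numpy() & pre_endpoint.to_numpy()]
    return pd.Index(eligible, name="patient_id")


def build_patient_months(events: pd.DataFrame, eligible: pd.Index) -> pd.DataFrame:
    """One row per (eligible patient, calendar month with >=1 encounter)."""
    ev = _with_month(events)
    enc = ev.loc[(ev["category"] == "encounter") & ev["patient_id"].isin(eligible)]
    if enc.empty:
        return pd.DataFrame(
            columns=["patient_id", "month_index", "encounter_count", "gap_months"]
        ).astype({"month_index": "int64", "encounter_count": "int64", "gap_months": "int64"})
    rows = (
        enc.groupby(["patient_id", "month_index"])
        .size()
        .rename("encounter_count")
        .reset_index()
        .sort_values(["patient_id", "month_index"], kind="mergesort")
        .reset_index(drop=True)
    )
    gaps = rows.groupby("patient_id")["month_index"].diff()
    rows["gap_months"] = gaps.fillna(0).astype("int64")
    return rows


def code_outcome(
    rows: pd.DataFrame,
    events: pd.DataFrame,
    spec: CohortSpec,
    horizon_end: int,
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label each patient-month with the endpoint outcome over ``(m, m+L]``.

    ``outcome`` is 1 when the patient's first endpoint month falls within the
    L months strictly after the row month, 0 when the full window is
    observable and endpoint-free (death inside the window counts as 0 under
    the ``code_as_no_outcome`` policy), and missing (``pd.NA``) when
    ``m + L`` extends past ``horizon_end``.  Rows of endpoint patients at or
    after the endpoint month are removed (censoring); those patients' rows
    carry ``censored = True``.
    """
    L = spec.followup_months
    out = rows.copy()
    if not out.empty and horizon_end < out["month_index"].min():
        warnings.warn("horizon_end precedes all patient-months; every outcome is unobservable")

    ep = endpoint_month_by_patient(events, spec)
    ep_aligned = out["patient_id"].map(ep)

    out = out.loc[ep_aligned.isna() | (out["month_index"] < ep_aligned)].copy()
    ep_aligned = out["patient_id"].map(ep)

    m = out["month_index"]
    hit = ep_aligned.notna() & (ep_aligned <= m + L)
    observable = (m + L) <= horizon_end
    outcome = pd.array([pd.NA] * len(out), dtype="Int8")
    outcome[(observable & hit).to_numpy()] = 1
    outcome[(observable & ~hit).to_numpy()] = 0
    out["outcome"] = outcome
    out["censored"] = ep_aligned.notna().to_numpy()
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class SplitPlan:
    """Temporal and patient-level partition anchored at validation month T."""

    validation_month: int
    followup_months: int
    train_fraction: float
    split_seed: int
    train_patients: tuple = ()
    test_patients: tuple = ()

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def analytic_end(self) -> int:
        return self.validation_month - self.followup_months - 1

    @property
    def observation_window(self) -> tuple[int, int]:
        T, L = self.validation_month, self.followup_months
        return (T - L, T - 1)

    @property
    def validation_followup(self) -> tuple[int, int]:
        T, L = self.validation_month, self.followup_months
        return (T + 1, T + L)

    def to_manifest(self) -> dict:
        return {
            "validation_month": month_label(self.validation_month),
            "followup_months": self.followup_months,
            "train_fraction": self.train_fraction,
            "split_seed": self.split_seed,
            "analytic_end": month_label(self.analytic_end),
            "train_patients": list(self.train_patients),
            "test_patients": list(self.test_patients),
        }


def make_split_plan(
    rows: pd.DataFrame,
    T: int,
    spec: CohortSpec,
    seed: int,
    train_fraction: float = 0.90,
) -> tuple[SplitPlan, dict[str, pd.DataFrame]]:
    """Carve labeled rows into training / test / validation / unused subsets.

    Analytic rows are those at months ``<= T - L - 1`` with an observable
    outcome; their patients are split 90:10 by a seeded uniform draw per
    patient.  Validation rows are the month-``T`` rows.
    """
    L = spec.followup_months
    analytic_end = T - L - 1
    analytic = rows.loc[(rows["month_index"] <= analytic_end) & rows["outcome"].notna()]
    if analytic.empty:
        feasible = (
            int(rows["month_index"].min()) + L + 1 if not rows.empty else None
        )
        raise ValueError(
            f"empty analytic set for T={month_label(T)}; "
            f"minimum feasible T is {month_label(feasible) if feasible is not None else 'undefined'}"
        )

    patients = np.asarray(sorted(analytic["patient_id"].unique()))
    rng = np.random.default_rng(seed)
    draws = rng.random(len(patients))
    train_ids = patients[draws < train_fraction]
    test_ids = patients[draws >= train_fraction]

    plan = SplitPlan(
        validation_month=T,
        followup_months=L,
        train_fraction=train_fraction,
        split_seed=seed,
        train_patients=tuple(train_ids.tolist()),
        test_patients=tuple(test_ids.tolist()),
    )

    training = analytic.loc[analytic["patient_id"].isin(train_ids)]
    test = analytic.loc[analytic["patient_id"].isin(test_ids)]
    validation = rows.loc[rows["month_index"] == T]
    used = pd.concat([training, test, validation]).index
    unused = rows.loc[~rows.index.isin(used)]
    subsets = {
        "training": training.reset_index(drop=True),
        "test": test.reset_index(drop=True),
        "validation": validation.reset_index(drop=True),
        "unused": unused.reset_index(drop=True),
        "analytic": analytic.reset_index(drop=True),
    }
    return plan, subsets


def load_table(path) -> pd.DataFrame:
    """Read an event or demographics table from CSV or Parquet by extension."""
    path = str(path)
    if path.endswith((".parquet", ".pq")):
        return pd.read_parquet(path)
    return pd.read_csv(path)
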