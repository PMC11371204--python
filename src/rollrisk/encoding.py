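"""Month-level design-matrix construction for retained predictors.

Three indicator schemas are used: *past-and-present* (``:pp``, diagnoses
only — present from the first occurring patient-month onward), *historical*
(``:hist`` — occurred strictly before the current month) and
*contemporaneous* (``:now`` — occurred during the current month).  Fixed
numeric measurements get a paired presence/value encoding in both the
historical and contemporaneous schemas; demographics are one-hot with an
explicit missing indicator; age is a single standardized contemporaneous
column.  All trim bounds, standardization constants and dummy levels are
fitted on the analytic dataset only and frozen in an :class:`EncodingPlan`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .timeseries import _with_month, birth_month_by_patient

MISSING_LEVEL = "__missing__"
NUMERIC_CATEGORIES = ("lab", "vital", "flowsheet")
DEFAULT_NUMERIC_NAMES = ("BMI", "SBP", "DBP")


@dataclass(frozen=True)
class NumericSpec:
    name: str
    trim_low: float
    trim_high: float
    mean: float
    sd: float

    def standardize(self, values: np.ndarray) -> np.ndarray:
        clipped = np.clip(values, self.trim_low, self.trim_high)
        return (clipped - self.mean) / self.sd


@dataclass(frozen=True)
class DemographicSpec:
    attribute: str
    levels: tuple
    time_varying: bool


@dataclass(frozen=True)
class EncodingPlan:
    """Frozen constants needed to score any set of patient-months."""

    diagnosis_codes: tuple = ()
    other_binary_codes: tuple = ()  # (code, category) pairs
    numeric_specs: tuple = ()  # NumericSpec, paired presence/value
    row_numeric_specs: tuple = ()  # NumericSpec for always-defined row descriptors
    demographic_specs: tuple = ()
    age_mean: float = 0.0
    age_sd: float = 1.0

    @property
    def column_names(self) -> list[str]:
        cols: list[str] = []
        for code in self.diagnosis_codes:
            cols.append(f"{code}:pp")
        for code, _cat in self.other_binary_codes:
            cols.extend([f"{code}:hist", f"{code}:now"])
        for spec in self.numeric_specs:
            cols.extend(
                [
                    f"{spec.name}:present_hist",
                    f"{spec.name}:value_hist",
                    f"{spec.name}:present_now",
                    f"{spec.name}:value_now",
                ]
            )
        for spec in self.demographic_specs:
            for level in spec.levels:
                cols.append(f"demo:{spec.attribute}={level}")
            cols.append(f"demo:{spec.attribute}={MISSING_LEVEL}")
        cols.append("age")
        for spec in self.row_numeric_specs:
            cols.append(spec.name)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate design-matrix columns: {dupes}")
        return cols

    def to_json(self) -> str:
        payload = asdict(self)
        payload["other_binary_codes"] = [list(p) for p in self.other_binary_codes]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EncodingPlan":
        payload = json.loads(text)
        return cls(
            diagnosis_codes=tuple(payload["diagnosis_codes"]),
            other_binary_codes=tuple((c, k) for c, k in payload["other_binary_codes"]),
            numeric_specs=tuple(NumericSpec(**s) for s in payload["numeric_specs"]),
            row_numeric_specs=tuple(NumericSpec(**s) for s in payload["row_numeric_specs"]),
            demographic_specs=tuple(
                DemographicSpec(s["attribute"], tuple(s["levels"]), s["time_varying"])
                for s in payload["demographic_specs"]
            ),
            age_mean=payload["age_mean"],
            age_sd=payload["age_sd"],
        )


# ---------------------------------------------------------------------------
# reference per-series encoders (array semantics used by the assembler)

def encode_past_present(row_months, occurrence_months) -> np.ndarray:
    """1 from the first occurrence month onward, 0 before."""
    row_months = np.asarray(row_months)
    occ = np.asarray(list(occurrence_months))
    if occ.size == 0:
        return np.zeros(row_months.shape, dtype=np.int8)
    return (row_months >= occ.min()).astype(np.int8)


def encode_historical(row_months, occurrence_months) -> np.ndarray:
    """1 when the code occurred in any month strictly before the row month."""
    row_months = np.asarray(row_months)
    occ = np.asarray(list(occurrence_months))
    if occ.size == 0:
        return np.zeros(row_months.shape, dtype=np.int8)
    return (row_months > occ.min()).astype(np.int8)


def encode_contemporaneous(row_months, occurrence_months) -> np.ndarray:
    """1 when the code occurred during the row month itself."""
    row_months = np.asarray(row_months)
    occ = set(occurrence_months)
    return np.fromiter((m in occ for m in row_months), dtype=np.int8, count=len(row_months))


def encode_numeric_pair(row_months, measurements: dict, spec: NumericSpec):
    """Per-series paired encoding for one numeric measurement.

    ``measurements`` maps month -> last raw value that month.  Returns four
    arrays: presence_now, value_now, presence_hist, value_hist where the
    historical value is the running max of the standardized contemporaneous
    values over strictly earlier months (0 when never measured).
    """
    row_months = np.asarray(row_months)
    meas_months = np.array(sorted(measurements), dtype=float)
    std = {m: float(spec.standardize(np.array([measurements[m]]))[0]) for m in measurements}

    presence_now = np.fromiter((m in measurements for m in row_months), dtype=np.int8, count=len(row_months))
    value_now = np.array([std.get(m, 0.0) for m in row_months])
    presence_hist = np.fromiter(
        ((meas_months < m).any() for m in row_months), dtype=np.int8, count=len(row_months)
    )
    value_hist = np.array(
        [
            max((std[int(mm)] for mm in meas_months[meas_months < m]), default=0.0)
            for m in row_months
        ]
    )
    return presence_now, value_now, presence_hist, value_hist


# ---------------------------------------------------------------------------
# plan fitting

def _monthly_last_values(events: pd.DataFrame, name: str) -> pd.DataFrame:
    """Last chronological value per (patient, month) for one measurement."""
    ev = _with_month(events)
    mask = (ev["code"] == name) & ev["category"].isin(NUMERIC_CATEGORIES) & ev["numeric_value"].notna()
    sub = ev.loc[mask, ["patient_id", "month_index", "event_date", "numeric_value"]]
    if sub.empty:
        return pd.DataFrame(columns=["patient_id", "month_index", "numeric_value"])
    sub = sub.sort_values(["patient_id", "month_index", "event_date"], kind="mergesort")
    return (
        sub.groupby(["patient_id", "month_index"], as_index=False)["numeric_value"].last()
    )


def _demo_records(demographics: pd.DataFrame, attribute: str):
    rows = demographics.loc[demographics["attribute"] == attribute].copy()
    time_varying = bool(rows["effective_date"].notna().any()) if not rows.empty else False
    if time_varying:
        eff = rows["effective_date"]
        months = np.where(
            eff.notna(), pd.to_datetime(eff).map(lambda t: t.year * 12 + t.month - 1), -(10**9)
        )
        rows["eff_month"] = months.astype("int64")
    else:
        rows["eff_month"] = -(10**9)
    return rows[["patient_id", "eff_month", "value"]], time_varying


def _current_demo_value(rows: pd.DataFrame, records: pd.DataFrame) -> pd.Series:
    """Value of a demographic attribute in effect at each patient-month."""
    if records.empty:
        return pd.Series([None] * len(rows), index=rows.index, dtype=object)
    left = rows[["patient_id", "month_index"]].reset_index().sort_values("month_index", kind="mergesort")
    right = records.sort_values("eff_month", kind="mergesort")
    merged = pd.merge_asof(
        left,
        right,
        by="patient_id",
        left_on="month_index",
        right_on="eff_month",
        direction="backward",
    )
    return merged.set_index("index")["value"].reindex(rows.index)


def fit_encoding_plan(
    analytic_rows: pd.DataFrame,
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    decisions,
    numeric_names=DEFAULT_NUMERIC_NAMES,
    demographic_attributes=("sex", "smoker"),
    trim_percentiles=(0.1, 99.9),
) -> EncodingPlan:
    """Fit all encoding constants on the analytic dataset only."""
    retained = [d for d in decisions if d.retained]
    numeric_set = set(numeric_names)
    diagnosis_codes = tuple(sorted(d.code for d in retained if d.category == "diagnosis"))
    other_binary = tuple(
        sorted(
            (d.code, d.category)
            for d in retained
            if d.category != "diagnosis" and d.code not in numeric_set
        )
    )

    key = analytic_rows[["patient_id", "month_index"]]
    numeric_specs = []
    for name in numeric_names:
        monthly = _monthly_last_values(events, name)
        observed = key.merge(monthly, on=["patient_id", "month_index"], how="inner")["numeric_value"]
        if observed.empty:
            warnings.warn(f"numeric measurement {name!r} absent from analytic rows; dropped")
            continue
        lo, hi = np.percentile(observed, trim_percentiles)
        clipped = np.clip(observed, lo, hi)
        mean, sd = float(np.mean(clipped)), float(np.std(clipped))
        if sd == 0.0:
            warnings.warn(f"numeric measurement {name!r} has zero analytic variance; dropped")
            continue
        numeric_specs.append(NumericSpec(name, float(lo), float(hi), mean, sd))

    demo_specs = []
    for attribute in demographic_attributes:
        records, time_varying = _demo_records(demographics, attribute)
        current = _current_demo_value(analytic_rows, records)
        levels = tuple(sorted({v for v in current.dropna().unique()}))
        demo_specs.append(DemographicSpec(attribute, levels, time_varying))

    birth = birth_month_by_patient(demographics)
    bm = analytic_rows["patient_id"].map(birth)
    if bm.isna().any():
        missing = analytic_rows.loc[bm.isna(), "patient_id"].unique()[:5].tolist()
        raise ValueError(f"missing birth_date for patients {missing}; cohort filter should exclude them")
    ages = (analytic_rows["month_index"] - bm) / 12.0
    age_mean, age_sd = float(ages.mean()), float(ages.std(ddof=0))
    if age_sd == 0.0:
        raise ValueError("age has zero variance in the analytic dataset")

    row_specs = []
    for name in ("gap_months", "encounter_count"):
        col = analytic_rows[name].astype(float)
        sd = float(col.std(ddof=0))
        if sd == 0.0:
            warnings.warn(f"row descriptor {name!r} has zero analytic variance; dropped")
            continue
        row_specs.append(NumericSpec(name, float(col.min()), float(col.max()), float(col.mean()), sd))

    return EncodingPlan(
        diagnosis_codes=diagnosis_codes,
        other_binary_codes=other_binary,
        numeric_specs=tuple(numeric_specs),
        row_numeric_specs=tuple(row_specs),
        demographic_specs=tuple(demo_specs),
        age_mean=age_mean,
        age_sd=age_sd,
    )


# ---------------------------------------------------------------------------
# transformation

def _binary_columns(rows, events, plan):
    ev = _with_month(events)
    wanted = set(plan.diagnosis_codes) | {c for c, _k in plan.other_binary_codes}
    occ = (
        ev.loc[ev["code"].isin(wanted), ["code", "patient_id", "month_index"]]
        .drop_duplicates()
    )
    by_code_first = occ.groupby(["code", "patient_id"])["month_index"].min()
    row_mi = pd.MultiIndex.from_arrays([rows["patient_id"], rows["month_index"]])
    m = rows["month_index"].to_numpy()

    cols = {}
    for code in plan.diagnosis_codes:
        first = (
            by_code_first.xs(code, level="code") if code in by_code_first.index.get_level_values(0) else pd.Series(dtype=float)
        )
        f = rows["patient_id"].map(first).to_numpy(dtype=float)
        cols[f"{code}:pp"] = (m >= f).astype(np.float64)  # NaN compares False
    occ_by_code = dict(tuple(occ.groupby("code")))
    for code, _cat in plan.other_binary_codes:
        sub = occ_by_code.get(code)
        if sub is None:
            cols[f"{code}:hist"] = np.zeros(len(rows))
            cols[f"{code}:now"] = np.zeros(len(rows))
            continue
        first = sub.groupby("patient_id")["month_index"].min()
        f = rows["patient_id"].map(first).to_numpy(dtype=float)
        cols[f"{code}:hist"] = (m > f).astype(np.float64)
        occ_mi = pd.MultiIndex.from_arrays([sub["patient_id"], sub["month_index"]])
        cols[f"{code}:now"] = row_mi.isin(occ_mi).astype(np.float64)
    return cols


def _numeric_columns(rows, events, plan):
    cols = {}
    base = rows[["patient_id", "month_index"]].reset_index(drop=True)
    for spec in plan.numeric_specs:
        monthly = _monthly_last_values(events, spec.name)
        merged = base.merge(monthly, on=["patient_id", "month_index"], how="left")
        present_now = merged["numeric_value"].notna().to_numpy()
        std_now = np.zeros(len(base))
        if present_now.any():
            std_now[present_now] = spec.standardize(merged.loc[present_now, "numeric_value"].to_numpy())

        # historical pieces must also see measurements in non-row months:
        # interleave measurement records after row records within each month so
        # a running max up to a row position covers strictly earlier months.
        meas = monthly.copy()
        meas["kind"] = 1
        meas["std"] = spec.standardize(meas["numeric_value"].to_numpy()) if not meas.empty else []
        rows_k = base.copy()
        rows_k["kind"] = 0
        rows_k["row_pos"] = np.arange(len(rows_k))
        combined = pd.concat(
            [rows_k[["patient_id", "month_index", "kind", "row_pos"]],
             meas[["patient_id", "month_index", "kind", "std"]]],
            ignore_index=True,
        ).sort_values(["patient_id", "month_index", "kind"], kind="mergesort")
        vals = combined["std"].to_numpy(dtype=float)
        vals[combined["kind"].to_numpy() == 0] = -np.inf
        vals = np.where(np.isnan(vals), -np.inf, vals)
        combined["running"] = pd.Series(vals, index=combined.index).groupby(
            combined["patient_id"].to_numpy()
        ).cummax()
        at_rows = combined.loc[combined["kind"] == 0].sort_values("row_pos")
        running = at_rows["running"].to_numpy()
        present_hist = np.isfinite(running)
        value_hist = np.where(present_hist, running, 0.0)

        cols[f"{spec.name}:present_hist"] = present_hist.astype(np.float64)
        cols[f"{spec.name}:value_hist"] = value_hist
        cols[f"{spec.name}:present_now"] = present_now.astype(np.float64)
        cols[f"{spec.name}:value_now"] = std_now
    return cols


def _demographic_columns(rows, demographics, plan):
    cols = {}
    for spec in plan.demographic_specs:
        records, _tv = _demo_records(demographics, spec.attribute)
        current = _current_demo_value(rows, records)
        known = set(spec.levels)
        unseen = {v for v in current.dropna().unique()} - known
        if unseen:
            warnings.warn(
                f"unseen {spec.attribute!r} level(s) {sorted(unseen)} mapped to missing"
            )
        vals = current.where(current.isin(known)).to_numpy(dtype=object)
        for level in spec.levels:
            cols[f"demo:{spec.attribute}={level}"] = (vals == level).astype(np.float64)
        cols[f"demo:{spec.attribute}={MISSING_LEVEL}"] = pd.isna(vals).astype(np.float64)
    return cols


def assemble_design_matrix(
    rows: pd.DataFrame,
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    plan: EncodingPlan,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Encode patient-months into the dense design matrix.

    Returns ``(X, y)`` where ``X`` is indexed by (patient_id, month_index)
    in the row order given and ``y`` holds outcomes as floats with ``nan``
    for unobservable labels (all-``nan`` when rows are unlabeled).
    """
    rows = rows.reset_index(drop=True)
    cols: dict[str, np.ndarray] = {}
    cols.update(_binary_columns(rows, events, plan))
    cols.update(_numeric_columns(rows, events, plan))
    cols.update(_demographic_columns(rows, demographics, plan))

    birth = birth_month_by_patient(demographics)
    bm = rows["patient_id"].map(birth)
    if bm.isna().any():
        missing = rows.loc[bm.isna(), "patient_id"].unique()[:5].tolist()
        raise ValueError(f"missing birth_date for patients {missing}")
    ages = (rows["month_index"] - bm).to_numpy() / 12.0
    cols["age"] = (ages - plan.age_mean) / plan.age_sd
    for spec in plan.row_numeric_specs:
        cols[spec.name] = (rows[spec.name].to_numpy(dtype=float) - spec.mean) / spec.sd

    order = plan.column_names
    X = pd.DataFrame({name: cols[name] for name in order})
    X.index = pd.MultiIndex.from_arrays(
        [rows["patient_id"], rows["month_index"]], names=["patient_id", "month_index"]
    )
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise AssertionError(f"missing cells in design matrix columns {bad}")

    if "outcome" in rows.columns:
        y = rows["outcome"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    else:
        y = np.full(len(rows), np.nan)
    return X, y
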