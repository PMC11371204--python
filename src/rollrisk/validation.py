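"""Monthly pseudo-prospective validation loop.

Each validation month T gets one full run of the algorithm fitted strictly
on data collected through month T-1: cohort filtering, patient-month
construction, outcome coding, predictor retention, encoding-plan fitting and
network training.  The resulting model scores the patients with encounters
in month T, whose follow-up window [T+1, T+L] is then observed to measure
performance.  Repeating over successive months yields the rolling refresh
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .encoding import EncodingPlan, assemble_design_matrix, fit_encoding_plan, DEFAULT_NUMERIC_NAMES
from .model import ModelConfig, TrainedRiskModel, build_network, predict_risk, train
from .selection import SelectionConfig, decisions_frame, select_predictors
from .timeseries import (
    CohortSpec,
    _with_month,
    apply_cohort_filters,
    build_patient_months,
    code_outcome,
    endpoint_month_by_patient,
    make_split_plan,
    month_label,
)

DEFAULT_BANDS = (_metrics.RankBand(1, 100), _metrics.RankBand(101, 200))
DEFAULT_THRESHOLDS = (0.05, 0.025)


@dataclass
class ValidationMonthResult:
    month: int
    analytic_patients: int
    analytic_outcome_pct: float
    retained_predictors: int
    predictor_encodings: int
    cohort_patients: int
    cohort_outcome_pct: float
    auroc: float
    auprc: float
    band_metrics: list = field(default_factory=list)
    threshold_metrics: list = field(default_factory=list)
    risk_descriptives: pd.DataFrame | None = None
    decisions: list = field(default_factory=list)
    plan: EncodingPlan | None = None
    model: TrainedRiskModel | None = None
    patient_scores: pd.DataFrame | None = None

    def summary(self) -> dict:
        row = {
            "month": month_label(self.month),
            "analytic_patients": self.analytic_patients,
            "analytic_outcome_pct": self.analytic_outcome_pct,
            "retained_predictors": self.retained_predictors,
            "predictor_encodings": self.predictor_encodings,
            "cohort_patients": self.cohort_patients,
            "cohort_outcome_pct": self.cohort_outcome_pct,
            "auroc": self.auroc,
            "auprc": self.auprc,
        }
        for bm in self.band_metrics:
            row[f"ppv_{bm['band']}"] = bm["ppv"]
            row[f"or_{bm['band']}"] = bm["odds_ratio"]
        return row


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


class RollingError(RuntimeError):
    """Failure partway through a rolling run; carries the completed months."""

    def __init__(self, month: int, original: Exception, results: list):
        super().__init__(f"month {month_label(month)} failed: {original}")
        self.results = results
        self.original = original


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def validation_outcomes(
    events: pd.DataFrame, patients, T: int, spec: CohortSpec
) -> pd.Series:
    """Outcome (endpoint within [T+1, T+L]) per validation-cohort patient."""
    ep = endpoint_month_by_patient(events, spec)
    ep = ep.reindex(pd.Index(patients))
    L = spec.followup_months
    return ((ep > T) & (ep <= T + L)).astype(int)


def run_month(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    T: int,
    cohort_spec: CohortSpec | None = None,
    selection_cfg: SelectionConfig | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int = 0,
    bands=DEFAULT_BANDS,
    thresholds=DEFAULT_THRESHOLDS,
    numeric_names=DEFAULT_NUMERIC_NAMES,
    demographic_attributes=("sex", "smoker"),
    keep_model: bool = True,
) -> ValidationMonthResult:
    """One full-algorithm run for validation month ``T``.

    Fitting only sees events at months ``<= T - 1``; month-``T`` events enter
    solely as contemporaneous features of the validation rows; months beyond
    ``T`` are used only to observe validation outcomes.
    """
    cohort_spec = cohort_spec or CohortSpec()
    selection_cfg = selection_cfg or SelectionConfig()
    model_cfg = model_cfg or ModelConfig()
    model_cfg = replace(model_cfg, train_seed=model_cfg.train_seed + seed)
    L = cohort_spec.followup_months

    ev = _with_month(events)
    visible = ev.loc[ev["month_index"] <= T]

    rows, subsets = _build_rows(visible, demographics, cohort_spec, T, seed)
    analytic = subsets["analytic"]
    validation = subsets["validation"]
    if validation.empty:
        raise StageError("split", ValueError(f"empty validation cohort at T={month_label(T)}"))

    decisions = _select(analytic, visible, selection_cfg, cohort_spec, T - L - 1)
    plan = _fit_plan(analytic, visible, demographics, decisions, numeric_names, demographic_attributes)
    model = _train_model(subsets, visible, demographics, plan, model_cfg)
    return _evaluate(
        model, plan, decisions, subsets, visible, events, demographics,
        cohort_spec, T, seed, bands, thresholds, keep_model,
    )


@_stage("timeseries")
def _build_rows(visible, demographics, cohort_spec, T, seed):
    eligible = apply_cohort_filters(visible, demographics, cohort_spec)
    rows = build_patient_months(visible, eligible)
    rows = code_outcome(rows, visible, cohort_spec, horizon_end=T - 1, demographics=demographics)
    plan, subsets = make_split_plan(rows, T, cohort_spec, seed=seed)
    subsets["split_plan"] = plan
    return rows, subsets


@_stage("selection")
def _select(analytic, visible, selection_cfg, cohort_spec, analytic_end):
    return select_predictors(
        analytic, visible, selection_cfg, cohort_spec=cohort_spec, analytic_end=analytic_end
    )


@_stage("encoding")
def _fit_plan(analytic, visible, demographics, decisions, numeric_names, demographic_attributes):
    return fit_encoding_plan(
        analytic, visible, demographics, decisions,
        numeric_names=numeric_names, demographic_attributes=demographic_attributes,
    )


@_stage("training")
def _train_model(subsets, visible, demographics, plan, model_cfg):
    X_tr, y_tr = assemble_design_matrix(subsets["training"], visible, demographics, plan)
    X_te, y_te = assemble_design_matrix(subsets["test"], visible, demographics, plan)
    net = build_network(X_tr.shape[1], model_cfg, columns=tuple(X_tr.columns))
    model = train(net, X_tr, y_tr, X_te, y_te, model_cfg)
    model.encoding_plan_json = plan.to_json()
    return model


@_stage("evaluation")
def _evaluate(model, plan, decisions, subsets, visible, full_events, demographics,
              cohort_spec, T, seed, bands, thresholds, keep_model):
    analytic = subsets["analytic"]
    validation = subsets["validation"]
    X_val, _ = assemble_design_matrix(validation, visible, demographics, plan)
    row_scores = predict_risk(model, X_val)

    scored = pd.DataFrame({"patient_id": validation["patient_id"].to_numpy(), "score": row_scores})
    patient_scores = scored.groupby("patient_id")["score"].max()
    labels = validation_outcomes(full_events, patient_scores.index, T, cohort_spec)

    s = patient_scores.to_numpy()
    y = labels.to_numpy()
    auroc_v = _metrics.auroc(s, y) if 0 < y.sum() < len(y) else float("nan")
    auprc_v = _metrics.auprc(s, y) if 0 < y.sum() < len(y) else float("nan")
    band_results = [
        _metrics.band_metrics(s, y, band, seed=seed) for band in bands if band.end_rank <= len(s)
    ]
    threshold_results = [
        {"threshold": t, **dict(zip(("sensitivity", "specificity"), _metrics.threshold_metrics(s, y, t)))}
        for t in thresholds
    ]

    analytic_patients = analytic["patient_id"].nunique()
    outcome_pat = analytic.loc[analytic["outcome"].astype("Float64") == 1, "patient_id"].nunique()
    return ValidationMonthResult(
        month=T,
        analytic_patients=int(analytic_patients),
        analytic_outcome_pct=100.0 * outcome_pat / analytic_patients,
        retained_predictors=sum(d.retained for d in decisions),
        predictor_encodings=len(plan.column_names),
        cohort_patients=int(len(patient_scores)),
        cohort_outcome_pct=100.0 * float(y.mean()),
        auroc=auroc_v,
        auprc=auprc_v,
        band_metrics=band_results,
        threshold_metrics=threshold_results,
        risk_descriptives=_metrics.risk_distribution_descriptives(s, y),
        decisions=decisions,
        plan=plan,
        model=model if keep_model else None,
        patient_scores=pd.DataFrame({"patient_id": patient_scores.index, "score": s, "outcome": y}),
    )


def run_rolling(events, demographics, T_values, **kwargs) -> tuple[list[ValidationMonthResult], dict]:
    """One run per validation month plus OLS trend slopes per metric."""
    results: list[ValidationMonthResult] = []
    for T in T_values:
        try:
            results.append(run_month(events, demographics, T, **kwargs))
        except Exception as exc:  # noqa: BLE001
            raise RollingError(T, exc, results) from exc
    return results, trend_summary(results)


def trend_summary(results: list[ValidationMonthResult]) -> dict:
    """Least-squares slope per month for each headline metric (None if < 2 months)."""
    slopes = {}
    months = np.array([r.month for r in results], dtype=float)
    for name in ("auroc", "auprc"):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        ok = np.isfinite(vals)
        slopes[name] = float(np.polyfit(months[ok], vals[ok], 1)[0]) if ok.sum() >= 2 else None
    return slopes


def summary_frame(results: list[ValidationMonthResult]) -> pd.DataFrame:
    return pd.DataFrame([r.summary() for r in results])
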