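"""Automated binary predictor retention.

Every candidate binary predictor is screened at the patient level against two
criteria: an exact Fisher test on the predictor-by-outcome contingency table
(criterion 1), and, for risk factors only, a cumulative-binomial check that a
10% test split would be expected to contain at least one outcome-bearing
carrier (criterion 2).  Predictors meeting the applicable criteria are
retained for the final-stage model; decisions are emitted for every candidate
so the selection plane can be inspected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import matches_endpoint

RISK = "risk"
PROTECTIVE = "protective"
NULL = "null"


@dataclass(frozen=True)
class ContingencyTable:
    """Patient-level 2x2 counts: (carrier, non-carrier) x (outcome, no outcome)."""

    a: int  # carriers with the outcome
    b: int  # carriers without the outcome
    c: int  # non-carriers with the outcome
    d: int  # non-carriers without the outcome

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_carriers(self) -> int:
        return self.a + self.b

    @property
    def n_outcome(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    test_fraction: float = 0.10
    prc2_threshold: float = 0.95
    #: optional (risk_tail, protective_tail) pair replacing alpha/2 per tail
    asymmetric_alpha: tuple[float, float] | None = None
    #: 'doubled-tail' reproduces the closed-form minimum-N boundary for
    #: complete protective factors; 'point-probability' is the standard
    #: two-sided exact convention
    fisher_convention: str = "doubled-tail"

    def __post_init__(self):
        for name in ("alpha", "test_fraction", "prc2_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.fisher_convention not in ("doubled-tail", "point-probability"):
            raise ValueError(f"unknown fisher_convention: {self.fisher_convention!r}")

    def tail_alphas(self) -> tuple[float, float]:
        """(risk_tail, protective_tail) significance mass."""
        if self.asymmetric_alpha is not None:
            return self.asymmetric_alpha
        return (self.alpha / 2.0, self.alpha / 2.0)


@dataclass(frozen=True)
class PredictorDecision:
    code: str
    category: str
    table: ContingencyTable
    direction: str
    prc1_p: float
    prc2_prob: float | None
    retained: bool


def patient_level_contingency(
    carriers: set | pd.Index, outcome_patients: set | pd.Index, all_patients: set | pd.Index
) -> ContingencyTable:
    """2x2 counts from patient sets; carriers must be a subset of all patients."""
    carriers = set(carriers)
    outcome_patients = set(outcome_patients)
    all_patients = set(all_patients)
    carriers &= all_patients
    outcome_patients &= all_patients
    a = len(carriers & outcome_patients)
    b = len(carriers) - a
    c = len(outcome_patients) - a
    d = len(all_patients) - a - b - c
    return ContingencyTable(a, b, c, d)


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int, alternative: str) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def fisher_two_tailed_p(table: ContingencyTable, convention: str = "point-probability") -> float:
    """Exact two-sided p-value for a 2x2 table under the hypergeometric null.

    ``point-probability`` sums the probabilities of all tables (margins
    fixed) whose point probability does not exceed that of the observed
    table.  ``doubled-tail`` doubles the smaller one-sided tail (capped at
    1), which matches the per-tail reading of a two-tailed alpha.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if convention == "point-probability":
        return _fisher_cached(a, b, c, d, "two-sided")
    if convention == "doubled-tail":
        less = _fisher_cached(a, b, c, d, "less")
        greater = _fisher_cached(a, b, c, d, "greater")
        return min(1.0, 2.0 * min(less, greater))
    raise ValueError(f"unknown convention: {convention!r}")


def fisher_tail_p(table: ContingencyTable, direction: str) -> float:
    """One-sided exact tail probability in the given direction."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if direction == RISK:
        return _fisher_cached(a, b, c, d, "greater")
    if direction == PROTECTIVE:
        return _fisher_cached(a, b, c, d, "less")
    raise ValueError("tail p-value requires a risk or protective direction")


def classify_direction(table: ContingencyTable) -> str:
    """Risk if carriers show a higher outcome rate than non-carriers, etc."""
    if table.n_carriers == 0:
        return NULL
    carrier_rate = table.a / table.n_carriers
    rest = table.c + table.d
    rest_rate = table.c / rest if rest > 0 else carrier_rate
    if carrier_rate > rest_rate:
        return RISK
    if carrier_rate < rest_rate:
        return PROTECTIVE
    return NULL


def min_complete_protective_n(rate: float, alpha: float = 0.05) -> int:
    """Minimum carrier count at which a zero-outcome carrier group can reach
    two-tailed significance: ``ceil(log(alpha/2) / log(1 - rate))``."""
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must lie in (0, 1); got {rate}")
    return math.ceil(math.log(alpha / 2.0) / math.log(1.0 - rate))


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def prc2(n_carriers: int, o_carriers: int, cfg: SelectionConfig | None = None) -> tuple[float, bool]:
    """Probability that a ``test_fraction`` sample of the carriers contains at
    least one outcome-bearing carrier, and whether it clears the threshold."""
    cfg = cfg or SelectionConfig()
    if not 0 <= o_carriers <= n_carriers:
        raise ValueError("need 0 <= o_carriers <= n_carriers")
    if o_carriers == 0:
        raise ValueError("prc2 applies to risk factors only (o_carriers > 0)")
    n_test = max(1, round_half_up(cfg.test_fraction * n_carriers))
    p_hit = o_carriers / n_carriers
    prob = 1.0 - (1.0 - p_hit) ** n_test
    return prob, prob >= cfg.prc2_threshold


def decide_predictor(
    code: str, category: str, table: ContingencyTable, cfg: SelectionConfig | None = None
) -> PredictorDecision:
    """Apply both retention criteria to a single candidate predictor."""
    cfg = cfg or SelectionConfig()
    direction = classify_direction(table)
    risk_tail, protective_tail = cfg.tail_alphas()

    if cfg.fisher_convention == "doubled-tail" or cfg.asymmetric_alpha is not None:
        # per-tail rule: the observed tail mass must not exceed its alpha share
        if direction == NULL:
            prc1_p = fisher_two_tailed_p(table, cfg.fisher_convention)
            prc1_pass = False
        else:
            tail = fisher_tail_p(table, direction)
            prc1_p = min(1.0, 2.0 * tail)
            budget = risk_tail if direction == RISK else protective_tail
            prc1_pass = tail <= budget
    else:
        prc1_p = fisher_two_tailed_p(table, "point-probability")
        prc1_pass = prc1_p <= cfg.alpha and direction != NULL

    prc2_prob = None
    retained = False
    if prc1_pass:
        if direction == PROTECTIVE:
            retained = True
        elif direction == RISK:
            prc2_prob, prc2_pass = prc2(table.n_carriers, table.a, cfg)
            retained = prc2_pass
    return PredictorDecision(
        code=code,
        category=category,
        table=table,
        direction=direction,
        prc1_p=prc1_p,
        prc2_prob=prc2_prob,
        retained=retained,
    )


def carrier_sets(
    events: pd.DataFrame,
    analytic_patients,
    analytic_end: int,
    cohort_spec=None,
) -> pd.DataFrame:
    """Per-code carrier sets from analytic-window events.

    A patient carries a code when it occurs anywhere in their events at
    months ``<= analytic_end`` and, for endpoint patients, strictly before
    their endpoint month (the censoring boundary).  Returns one row per
    (code, category) with the set of carrier patient ids.
    """
    from .timeseries import _with_month, endpoint_month_by_patient

    ev = _with_month(events)
    ev = ev.loc[ev["patient_id"].isin(analytic_patients) & (ev["month_index"] <= analytic_end)]
    if cohort_spec is not None:
        ep = endpoint_month_by_patient(events, cohort_spec)
        cutoff = ev["patient_id"].map(ep)
        ev = ev.loc[cutoff.isna() | (ev["month_index"] < cutoff)]
        ev = ev.loc[~(matches_endpoint(ev["code"], cohort_spec) & (ev["category"] == "diagnosis"))]
    ev = ev.loc[ev["category"] != "encounter"]
    grouped = (
        ev.groupby(["code", "category"])["patient_id"]
        .agg(lambda s: frozenset(s))
        .rename("carriers")
        .reset_index()
    )
    return grouped


def select_predictors(
    analytic_rows: pd.DataFrame,
    events: pd.DataFrame,
    cfg: SelectionConfig | None = None,
    cohort_spec=None,
    analytic_end: int | None = None,
) -> list[PredictorDecision]:
    """Run both retention criteria over every candidate code in the analytic window."""
    cfg = cfg or SelectionConfig()
    if analytic_rows.empty:
        return []
    if analytic_end is None:
        analytic_end = int(analytic_rows["month_index"].max())
    analytic_patients = pd.Index(analytic_rows["patient_id"].unique())
    outcome_patients = set(
        analytic_rows.loc[analytic_rows["outcome"].astype("Float64") == 1, "patient_id"].unique()
    )
    all_patients = set(analytic_patients)

    decisions = []
    for rec in carrier_sets(events, analytic_patients, analytic_end, cohort_spec).itertuples():
        table = patient_level_contingency(rec.carriers, outcome_patients, all_patients)
        decisions.append(decide_predictor(rec.code, rec.category, table, cfg))
    return decisions


def decisions_frame(decisions: list[PredictorDecision]) -> pd.DataFrame:
    """Flatten decisions into the retained-predictor report table."""
    return pd.DataFrame(
        {
            "code": [d.code for d in decisions],
            "category": [d.category for d in decisions],
            "a": [d.table.a for d in decisions],
            "b": [d.table.b for d in decisions],
            "c": [d.table.c for d in decisions],
            "d": [d.table.d for d in decisions],
            "direction": [d.direction for d in decisions],
            "prc1_p": [d.prc1_p for d in decisions],
            "prc2_prob": [np.nan if d.prc2_prob is None else d.prc2_prob for d in decisions],
            "retained": [d.retained for d in decisions],
        }
    )
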