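"""Evaluation metrics for rank-ordered and threshold-based screening."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties counted 1/2)."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


def auprc(scores, labels) -> float:
    """Average precision (step-wise, non-interpolated precision-recall area)."""
    return float(average_precision_score(np.asarray(labels), np.asarray(scores)))


@dataclass(frozen=True)
class RankBand:
    """1-based inclusive rank range over patients ordered by descending risk."""

    start_rank: int = 1
    end_rank: int = 100

    def __post_init__(self):
        if not 1 <= self.start_rank <= self.end_rank:
            raise ValueError("need 1 <= start_rank <= end_rank")

    @property
    def size(self) -> int:
        return self.end_rank - self.start_rank + 1


def _rank_order(scores: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices sorting scores descending; ties broken by a seeded shuffle."""
    tiebreak = np.random.default_rng(seed).permutation(len(scores))
    return np.lexsort((tiebreak, -np.asarray(scores)))


def ppv_at_band(scores, labels, band: RankBand, seed: int = 0) -> float:
    """Percent of band members with the outcome (precision within the band)."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if len(scores) < band.end_rank:
        raise ValueError(f"cohort of {len(scores)} smaller than band end rank {band.end_rank}")
    order = _rank_order(scores, seed)
    members = order[band.start_rank - 1 : band.end_rank]
    return 100.0 * float(labels[members].sum()) / band.size


def ppv_to_odds_ratio(band_outcomes: int, band_size: int, cohort_outcomes: int, cohort_size: int) -> float:
    """Band odds of the outcome versus the rest-of-cohort odds.

    Returns ``nan`` when the rest-of-cohort rate is degenerate (0 or 1) and
    0 when the band has no outcomes.
    """
    rest_outcomes = cohort_outcomes - band_outcomes
    rest_size = cohort_size - band_size
    if rest_size <= 0 or rest_outcomes <= 0 or rest_outcomes >= rest_size:
        return float("nan")
    if band_outcomes >= band_size:
        return float("inf")
    band_odds = band_outcomes / (band_size - band_outcomes)
    rest_odds = rest_outcomes / (rest_size - rest_outcomes)
    return band_odds / rest_odds


def band_metrics(scores, labels, band: RankBand, seed: int = 0) -> dict:
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    order = _rank_order(scores, seed)
    members = order[band.start_rank - 1 : band.end_rank]
    band_outcomes = int(labels[members].sum())
    return {
        "band": f"{band.start_rank}-{band.end_rank}",
        "ppv": 100.0 * band_outcomes / band.size,
        "odds_ratio": ppv_to_odds_ratio(band_outcomes, band.size, int(labels.sum()), len(labels)),
    }


def threshold_metrics(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of classification at ``score >= threshold``."""
    scores = np.asarray(scores)
    labels = np.asarray(labels).astype(bool)
    predicted = scores >= threshold
    pos, neg = labels.sum(), (~labels).sum()
    sensitivity = float((predicted & labels).sum() / pos) if pos else float("nan")
    specificity = float((~predicted & ~labels).sum() / neg) if neg else float("nan")
    return sensitivity, specificity


def risk_distribution_descriptives(scores, labels) -> pd.DataFrame:
    """Percent-scale risk summary (min/quartiles/mean/max) per outcome group."""
    frame = pd.DataFrame({"risk_pct": 100.0 * np.asarray(scores), "outcome": np.asarray(labels)})
    rows = []
    for group, label in ((0, "No"), (1, "Yes")):
        vals = frame.loc[frame["outcome"] == group, "risk_pct"]
        if vals.empty:
            continue
        rows.append(
            {
                "outcome": label,
                "min": vals.min(),
                "q1": vals.quantile(0.25),
                "median": vals.median(),
                "mean": vals.mean(),
                "q3": vals.quantile(0.75),
                "max": vals.max(),
            }
        )
    return pd.DataFrame(rows)
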