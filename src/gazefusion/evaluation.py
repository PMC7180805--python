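"""Metrics and statistical comparison for per-category binary classifiers.

Precision, recall and F1 follow the usual confusion-count definitions with
the 0/0 -> 0 convention (needed when a rare category never appears in a
small test split).  Result tables hold one F1 per (subject, category) cell
and are averaged both ways; the grand mean is identical under either
grouping on a rectangular table.  Method comparison uses Welch's two-sample
t-test (unequal variances, Welch-Satterthwaite degrees of freedom,
two-sided p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ResultTable",
    "confusion_from_predictions",
    "precision_recall_f1",
    "welch_t",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class ResultTable:
    """F1 per (subject, category) with row/column/grand means."""

    cells: pd.DataFrame  # index: subject, columns: category
    per_subject: pd.Series
    per_category: pd.Series
    grand_mean: float


def confusion_from_predictions(truth, predicted) -> ConfusionCounts:
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    return ConfusionCounts(
        TP=int(np.sum((predicted == 1) & (truth == 1))),
        FP=int(np.sum((predicted == 1) & (truth == 0))),
        FN=int(np.sum((predicted == 0) & (truth == 1))),
        TN=int(np.sum((predicted == 0) & (truth == 0))),
    )


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a, ddof=1) <= 0 or np.var(b, ddof=1) <= 0:
        raise ValueError("each sample must have positive variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def aggregate(results: pd.DataFrame, allow_missing: bool = False) -> ResultTable:
    """Row (per-subject), column (per-category) and grand means of an F1 grid.

    ``results`` is a rectangular DataFrame indexed by subject with one
    column per category.  Missing cells raise unless ``allow_missing``.
    """
    if results.isna().any().any() and not allow_missing:
        raise ValueError("result grid has missing cells")
    per_subject = results.mean(axis=1)
    per_category = results.mean(axis=0)
    grand = float(np.nanmean(results.to_numpy(dtype=float)))
    return ResultTable(cells=results, per_subject=per_subject,
                       per_category=per_category, grand_mean=grand)
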