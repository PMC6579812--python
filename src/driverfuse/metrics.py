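"""Binary classification metrics with driver as the positive class.

Accuracy, precision, recall and F1 are evaluated from the confusion counts
with exact rational arithmetic before conversion to float.  Precision,
recall and F1 are defined as 0 when their denominator is empty, so a
constant all-passenger predictor has a well-defined F1 of 0.  AUC follows
the pairwise-comparison construction: the probability that a random driver
outscores a random passenger, ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    """ROC points sorted from the most permissive threshold to the strictest."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    auc: float | None = None
    roc: RocCurve | None = None

    def as_dict(self, digits: int = 4) -> dict[str, float | None]:
        out = {
            k: round(getattr(self, k), digits)
            for k in ("accuracy", "precision", "recall", "f1", "tpr", "tnr", "fpr", "fnr")
        }
        out["auc"] = None if self.auc is None else round(self.auc, digits)
        return out


def confusion(labels, predictions) -> ConfusionCounts:
    """Confusion counts for binary labels/predictions (1 = driver)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if y.size == 0:
        raise ValueError("empty inputs")
    for arr, name in ((y, "labels"), (p, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: int, den: int) -> float:
    """num/den as exact Fraction -> float; 0 when the denominator is empty."""
    return float(Fraction(num, den)) if den else 0.0


def classification_report(
    counts: ConfusionCounts, labels=None, scores=None
) -> ClassificationReport:
    """Evaluate the closed-form rates from counts; AUC only when scores given."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    # harmonic mean in count form: 2TP / (2TP + FP + FN), exact
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    report = ClassificationReport(
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        precision=precision,
        recall=recall,
        f1=f1,
        tpr=recall,
        tnr=_ratio(counts.tn, counts.tn + counts.fp),
        fpr=_ratio(counts.fp, counts.tn + counts.fp),
        fnr=_ratio(counts.fn, counts.tp + counts.fn),
    )
    if scores is not None:
        if labels is None:
            raise ValueError("labels are required to compute AUC from scores")
        curve = roc_auc(labels, scores)
        report.auc = curve.auc
        report.roc = curve
    return report


def roc_auc(labels, scores) -> RocCurve:
    """AUC via the average-rank statistic plus the threshold-sweep ROC points.

    Equivalent to exhaustive comparison of every driver/passenger pair with
    ties contributing one half.  Thresholds are the unique score values with
    +/- infinity endpoints.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # average ranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc))


def evaluate(labels, predictions, scores=None) -> ClassificationReport:
    """Convenience wrapper: confusion counts + full report (+ AUC if scored)."""
    return classification_report(confusion(labels, predictions), labels=labels, scores=scores)
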