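"""Performance evaluation: confusion-matrix metrics, ROC/AUC, and
DeLong's non-parametric comparison of correlated AUCs.

Conventions: the positive class is "disease". TP counts correctly
predicted disease variants, TN correctly predicted neutral ones, FP
neutral variants called disease and FN disease variants called neutral.
AUC is the Mann-Whitney U statistic scaled to [0, 1] with ties counted
one half; its sampling variance is DeLong's placement-value estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core import logger
from .errors import DegenerateInputError, ValidationError


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_calls(cls, predicted: np.ndarray, actual: np.ndarray) -> "ConfusionCounts":
        predicted = np.asarray(predicted).astype(bool)
        actual = np.asarray(actual).astype(bool)
        return cls(
            tp=int((predicted & actual).sum()),
            tn=int((~predicted & ~actual).sum()),
            fp=int((predicted & ~actual).sum()),
            fn=int((~predicted & actual).sum()),
        )


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The six standard binary metrics.

    accuracy = (TP+TN)/total; recall = TP/(TP+FN);
    precision = TP/(TP+FP);
    balanced accuracy = 0.5*TP/(TP+FN) + 0.5*TN/(TN+FP);
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    F-measure = 2*precision*recall/(precision+recall).

    Ratios with a zero denominator are defined as 0 (with a warning for
    precision), the common convention for degenerate tables.
    """
    if c.total == 0:
        raise DegenerateInputError("all confusion counts are zero")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    accuracy = (tp + tn) / c.total
    recall = ratio(tp, tp + fn)
    if tp + fp == 0:
        logger.warning("no positive predictions; precision defined as 0")
    precision = ratio(tp, tp + fp)
    balanced = 0.5 * ratio(tp, tp + fn) + 0.5 * ratio(tn, tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    f_measure = ratio(2 * precision * recall, precision + recall)
    return {
        "accuracy": accuracy,
        "recall": recall,
        "precision": precision,
        "balanced_accuracy": balanced,
        "mcc": mcc,
        "f_measure": f_measure,
    }


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    present = np.unique(labels)
    if not np.isin(present, (0, 1)).all():
        raise ValidationError("labels must be 0 (neutral) or 1 (disease)")
    if len(present) < 2:
        raise DegenerateInputError("both classes must be present")
    return labels


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 per positive, V01 per negative."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    delong_variance: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve with tie-aware AUC and its DeLong variance.

    The curve has one point per distinct score threshold (a prediction is
    positive when the score is >= the threshold).
    """
    scores = np.asarray(scores, float)
    labels = _check_binary(labels)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1 and n > 1:
        var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    thresholds = np.unique(scores)[::-1]
    pos = labels == 1
    sens = np.array([(scores[pos] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~pos] < t).mean() for t in thresholds])
    return RocCurve(thresholds, sens, spec, auc, var)


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    return roc_auc(scores, labels).delong_variance


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both score vectors must refer to the same instances with the same
    labels. Returns the two AUCs, the z statistic and a two-sided p from
    the normal approximation. A zero-variance difference (e.g. identical
    score vectors) yields z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = _check_binary(labels)
    if scores_a.shape != scores_b.shape or len(scores_a) != len(labels):
        raise ValidationError("paired scores and labels must have equal length")
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise DegenerateInputError("need at least 2 instances per class")
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        logger.warning("zero variance of the AUC difference; p set to 1")
        return {"z": 0.0, "p": 1.0, "auc_a": auc_a, "auc_b": auc_b}
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return {"z": float(z), "p": float(p), "auc_a": auc_a, "auc_b": auc_b}


@dataclass
class EvalReport:
    """Confusion counts, the six metrics, and the ROC summary."""

    counts: ConfusionCounts
    metrics: dict[str, float]
    auc: float
    delong_variance: float

    @classmethod
    def from_scores(
        cls, scores: np.ndarray, labels: np.ndarray, cutoff: float = 50.0
    ) -> "EvalReport":
        labels = _check_binary(labels)
        scores = np.asarray(scores, float)
        counts = ConfusionCounts.from_calls(scores > cutoff, labels == 1)
        roc = roc_auc(scores, labels)
        return cls(counts, confusion_metrics(counts), roc.auc, roc.delong_variance)

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            **self.metrics,
            "auc": self.auc,
            "delong_variance": self.delong_variance,
        }
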