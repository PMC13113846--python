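"""Screening metrics with the confidence intervals the report format uses.

AUC is the rank-based (Mann-Whitney) estimator with ties contributing
1/2; its 95% CI follows Hanley & McNeil's closed-form standard error.
Accuracy, sensitivity and specificity carry standard Wald intervals
p +/- z*sqrt(p(1-p)/n) clipped to [0, 1], with z = 1.96 exactly.  The
decision threshold defaults to 0.5 (predict ischemia iff score >= 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import InvalidInputError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "roc_auc",
    "confusion_metrics",
    "wald_ci",
    "auc_ci_hanley_mcneil",
    "roc_curve",
    "metrics_report",
]

Z_95 = 1.96


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int


@dataclass
class MetricsReport:
    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    f1: float
    threshold: float
    n_total: int
    n_pos: int
    n_neg: int
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "f1": self.f1,
            "threshold": self.threshold,
            "n_total": self.n_total,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if not np.all(np.isin(classes, [0, 1])):
        raise InvalidInputError("labels must be binary 0/1")
    if classes.size < 2:
        raise InvalidInputError("both classes must be present")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 1/2 P(equal)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    ranks = rankdata(scores)  # average ranks halve the ties
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[ConfusionCounts, dict]:
    """Threshold the scores (>= predicts ischemia) and compute the
    screening metrics; f1 is defined as 0 (with a warning) when nothing
    is predicted positive."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    counts = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    accuracy = (tp + tn) / labels.size
    if tp + fp == 0:
        warnings.warn("no positive predictions; f1 set to 0")
        f1 = 0.0
    else:
        precision = tp / (tp + fp)
        f1 = 0.0 if precision + sensitivity == 0 else 2 * precision * sensitivity / (precision + sensitivity)
    return counts, {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
    }


def wald_ci(p: float, n: int, z: float = Z_95) -> tuple[float, float]:
    """Normal-approximation interval for a proportion, clipped to [0, 1]."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not 0 <= p <= 1:
        raise InvalidInputError("p must lie in [0, 1]")
    half = z * np.sqrt(p * (1 - p) / n)
    return (max(p - half, 0.0), min(p + half, 1.0))


def auc_ci_hanley_mcneil(auc: float, n_pos: int, n_neg: int, z: float = Z_95) -> tuple[float, float]:
    """Hanley-McNeil closed-form CI for the AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    if n_pos < 2 or n_neg < 2:
        raise InvalidInputError("need n_pos, n_neg >= 2")
    if not 0 <= auc <= 1:
        raise InvalidInputError("auc must lie in [0, 1]")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    se2 = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = np.sqrt(max(se2, 0.0))
    return (max(a - z * se, 0.0), min(a + z * se, 1.0))


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """(fpr, tpr, thresholds) over the unique score cut points."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    cuts = np.concatenate([distinct, [labels.size - 1]])
    tps = np.cumsum(sorted_labels)[cuts]
    fps = np.cumsum(1 - sorted_labels)[cuts]
    tpr = np.concatenate([[0.0], tps / labels.sum()])
    fpr = np.concatenate([[0.0], fps / (labels.size - labels.sum())])
    thresholds = np.concatenate([[np.inf], sorted_scores[cuts]])
    return fpr, tpr, thresholds


def metrics_report(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    ci_n: tuple[int, int, int] | None = None,
) -> MetricsReport:
    """Full report at the given threshold.

    ``ci_n`` optionally overrides the (n_total, n_pos, n_neg) used in
    the CI formulas — e.g. to compute subject-count intervals while the
    point estimates are cycle-level — otherwise the score counts are
    used for both.
    """
    labels = _check_binary(labels)
    auc = roc_auc(scores, labels)
    counts, point = confusion_metrics(scores, labels, threshold)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    n_total, ci_pos, ci_neg = (labels.size, n_pos, n_neg) if ci_n is None else ci_n
    return MetricsReport(
        auc=auc,
        auc_ci=auc_ci_hanley_mcneil(auc, ci_pos, ci_neg),
        accuracy=point["accuracy"],
        accuracy_ci=wald_ci(point["accuracy"], n_total),
        sensitivity=point["sensitivity"],
        sensitivity_ci=wald_ci(point["sensitivity"], ci_pos),
        specificity=point["specificity"],
        specificity_ci=wald_ci(point["specificity"], ci_neg),
        f1=point["f1"],
        threshold=threshold,
        n_total=labels.size,
        n_pos=n_pos,
        n_neg=n_neg,
        counts=counts,
    )
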