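"""Confusion-matrix metrics and ROC / precision-recall curves.

All curve areas are computed from first principles: the ROC area by a
trapezoidal sweep over tied-score groups (which half-credits ties, making
it equal to the pairwise-concordance statistic), the PR area by the
non-interpolated step rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_scores(cls, y_true, scores, threshold: float = 0.5) -> "ConfusionMatrix":
        y = np.asarray(y_true, dtype=int)
        pred = np.asarray(scores, dtype=float) >= threshold
        return cls(
            tp=int(np.sum(pred & (y == 1))),
            fp=int(np.sum(pred & (y == 0))),
            tn=int(np.sum(~pred & (y == 0))),
            fn=int(np.sum(~pred & (y == 1))),
        )

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def recall(self) -> float:
        return self.tp / self.n_pos if self.n_pos else math.nan

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def fpr(self) -> float:
        return self.fp / self.n_neg if self.n_neg else math.nan


def f1_score(precision: float, recall: float) -> float:
    """F1 = 2*precision*recall / (precision + recall)."""
    if precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    recall: float
    fpr: float
    precision: float
    f1: float
    auc_roc: float
    auc_pr: float

    @classmethod
    def from_parts(cls, cm: ConfusionMatrix, auc_roc: float, auc_pr: float) -> "MetricSet":
        return cls(
            accuracy=cm.accuracy,
            recall=cm.recall,
            fpr=cm.fpr,
            precision=cm.precision,
            f1=f1_score(cm.precision, cm.recall),
            auc_roc=auc_roc,
            auc_pr=auc_pr,
        )


def _tie_grouped_counts(y_true, scores):
    """Cumulative TP/FP counts at each distinct score threshold
    (descending), with tied scores collapsed into one step."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have the same shape")
    order = np.argsort(-s, kind="stable")
    s = s[order]
    y = y[order]
    # indices where a new distinct score ends
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    ends = np.r_[distinct, len(s) - 1]
    ctp = np.cumsum(y == 1)[ends]
    cfp = np.cumsum(y == 0)[ends]
    return ctp, cfp, int((y == 1).sum()), int((y == 0).sum())


def roc_curve_points(y_true, scores):
    """(fpr, tpr) points of the ROC curve, starting at (0,0).

    Tied scores form a single vertex, so trapezoidal integration gives
    ties half credit.
    """
    ctp, cfp, n_pos, n_neg = _tie_grouped_counts(y_true, scores)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for a ROC curve")
    tpr = np.r_[0.0, ctp / n_pos]
    fpr = np.r_[0.0, cfp / n_neg]
    return fpr, tpr


def auc_roc(y_true, scores) -> float:
    """Trapezoidal area under the ROC curve (ties half-credited)."""
    fpr, tpr = roc_curve_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def pr_curve_points(y_true, scores):
    """(recall, precision) points of the PR curve, starting at (0, 1)."""
    ctp, cfp, n_pos, _ = _tie_grouped_counts(y_true, scores)
    if n_pos == 0:
        raise ValueError("need positive samples for a PR curve")
    recall = np.r_[0.0, ctp / n_pos]
    precision = np.r_[1.0, ctp / (ctp + cfp)]
    return recall, precision


def auc_pr(y_true, scores) -> float:
    """Non-interpolated step-rule area: sum of dRecall * precision."""
    recall, precision = pr_curve_points(y_true, scores)
    return float(np.sum(np.diff(recall) * precision[1:]))


def confusion_matrices_matching(
    n_pos: int,
    n_neg: int,
    recall: float,
    precision: float,
    decimals: int = 3,
) -> list[ConfusionMatrix]:
    """All integer confusion matrices with the given class marginals whose
    recall and precision round to the stated values at ``decimals``."""
    out = []
    for tp in range(n_pos + 1):
        if round(tp / n_pos, decimals) != round(recall, decimals):
            continue
        for fp in range(n_neg + 1):
            if tp + fp == 0:
                continue
            if round(tp / (tp + fp), decimals) != round(precision, decimals):
                continue
            out.append(
                ConfusionMatrix(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
            )
    return out
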