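"""Binary classification metrics for site prediction.

Sensitivity, specificity, accuracy and the Matthews correlation
coefficient are computed from a confusion table at a probability
threshold (strictly greater-than, so a probability of exactly 0.5 is
called negative at the default threshold); AUC is the area under the ROC
curve, computed rank-based so it equals the Mann-Whitney probability
that a random positive outscores a random negative (ties count 1/2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels, scores, threshold: float = DEFAULT_THRESHOLD) -> ConfusionCounts:
    """Confusion counts calling positive iff score > threshold (strict)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = s > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """Sn = TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("no positive examples")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """Sp = TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("no negative examples")
    return c.tn / (c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (TP + TN + FP + FN)."""
    if c.n == 0:
        raise ZeroDivisionError("empty confusion table")
    return (c.tp + c.tn) / c.n


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator term is 0."""
    denom = ((c.tp + c.fp) * (c.tn + c.fn) * (c.tp + c.fn) * (c.tn + c.fp))
    if denom == 0:
        log.debug("MCC denominator is 0; returning 0 by convention")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_auc(labels, scores) -> tuple[float, np.ndarray]:
    """(AUC, ROC points) for binary labels and continuous scores.

    AUC is the rank statistic U/(P*N); the returned points are
    (FPR, TPR) pairs over all distinct thresholds, for plotting or
    trapezoidal re-integration (both routes agree).
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2-credit
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    distinct = np.r_[np.where(np.diff(ss))[0], len(ss) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(auc), np.column_stack([fpr, tpr])


@dataclass(frozen=True)
class EvaluationReport:
    """Sn/Sp/ACC/MCC at a threshold plus threshold-free AUC."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    threshold: float = DEFAULT_THRESHOLD

    def to_tsv(self) -> str:
        header = "Sn\tSp\tACC\tMCC\tAUC"
        row = f"{self.sn:.3f}\t{self.sp:.3f}\t{self.acc:.3f}\t{self.mcc:.3f}\t{self.auc:.3f}"
        return header + "\n" + row + "\n"


def evaluate(labels, scores, threshold: float = DEFAULT_THRESHOLD) -> EvaluationReport:
    c = confusion(labels, scores, threshold)
    auc, _ = roc_auc(labels, scores)
    return EvaluationReport(
        sn=sensitivity(c), sp=specificity(c), acc=accuracy(c),
        mcc=mcc(c), auc=auc, threshold=threshold,
    )
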