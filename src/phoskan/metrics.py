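"""Evaluation metrics for imbalanced binary site classification.

Threshold metrics (confusion counts, MCC, precision, recall/sensitivity,
specificity, F1, support-weighted F1) are computed at a configurable
probability cutoff (default 0.5).  Rank metrics use scikit-learn: AUPR is
the step-wise average precision (precision envelope summed over recall
steps, not a trapezoid), AUROC the Mann-Whitney rank statistic.  When the
labels contain a single class the rank metrics are reported as undefined
(None), never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)

from phoskan.errors import PhosKANError


@dataclass(frozen=True)
class MetricsReport:
    """All metrics of one evaluation, plus the PR curve for plotting."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    mcc: float
    precision: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]
    f1_weighted: float
    aupr: Optional[float]
    auroc: Optional[float]
    pr_curve: Tuple[np.ndarray, np.ndarray] = field(repr=False,
                                                    default=(None, None))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "MCC": self.mcc, "PRE": self.precision, "REC": self.recall,
            "SP": self.specificity, "F1": self.f1,
            "F1_weighted": self.f1_weighted, "AUPR": self.aupr,
            "AUROC": self.auroc, "threshold": self.threshold,
        }


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    A zero denominator (a degenerate confusion row/column) yields 0 by
    the usual convention.
    """
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full metric suite on binary labels (0/1 or NP/P) and probabilities."""
    y = np.asarray(
        [1 if v in (1, "P", True) else 0 for v in np.asarray(labels).ravel()]
    )
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise PhosKANError(
            f"labels ({y.shape}) and scores ({s.shape}) differ in length"
        )
    if y.size == 0:
        raise PhosKANError("cannot evaluate an empty prediction set")
    if s.min() < 0 or s.max() > 1:
        raise PhosKANError("scores must be probabilities in [0, 1]")

    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))

    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    if precision is None or recall is None or precision + recall == 0:
        f1_pos = None
    else:
        f1_pos = 2 * precision * recall / (precision + recall)

    # Support-weighted mean of per-class F1 (absent harmonic mean -> 0).
    def class_f1(cls: int) -> float:
        p = np.sum((pred == cls) & (y == cls))
        denom_p = np.sum(pred == cls)
        denom_r = np.sum(y == cls)
        pr = p / denom_p if denom_p else 0.0
        rc = p / denom_r if denom_r else 0.0
        return 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0

    support1 = int(np.sum(y == 1))
    support0 = y.size - support1
    f1_weighted = (support1 * class_f1(1) + support0 * class_f1(0)) / y.size

    both_classes = 0 < support1 < y.size
    if both_classes:
        aupr = float(average_precision_score(y, s))
        auroc = float(roc_auc_score(y, s))
        prec_curve, rec_curve, _ = precision_recall_curve(y, s)
        curve = (prec_curve, rec_curve)
    else:
        aupr = auroc = None
        curve = (None, None)

    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold,
        mcc=mcc_from_counts(tp, fp, tn, fn),
        precision=precision, recall=recall, specificity=specificity,
        f1=f1_pos, f1_weighted=float(f1_weighted),
        aupr=aupr, auroc=auroc, pr_curve=curve,
    )
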