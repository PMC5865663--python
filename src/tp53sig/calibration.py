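"""ROC analysis and accuracy-maximising cutoff selection for signature status.

The mutant/wild-type cutoff of the TP53-signature risk score is calibrated
against TP53 structural-mutation labels (the sequencing truth): a ROC curve
is swept over every threshold interval between adjacent observed scores,
the cutoff is placed at the midpoint of the interval that maximises
accuracy, and samples are then called MT when their score is strictly
greater than the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .signature import STATUS_MT, STATUS_WT

__all__ = [
    "RocCurve",
    "CutoffCalibration",
    "roc_curve",
    "auc",
    "select_cutoff",
    "assign_status",
    "confusion_metrics",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention of printed clinical rates)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered from the highest threshold (fpr 0) to the lowest (fpr 1).

    ``thresholds[k]`` produces the operating point ``(fpr[k], tpr[k])`` under
    the decision rule score > threshold => positive.  Thresholds are the
    midpoints between consecutive distinct sorted scores plus finite
    sentinels beyond the observed extremes, so every achievable confusion
    table appears exactly once.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass(frozen=True)
class CutoffCalibration:
    """Selected cutoff with its ROC summary and confusion table."""

    cutoff: float
    auc: float
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def confusion(self) -> dict[str, int]:
        return {"TP": self.tp, "FN": self.fn, "FP": self.fp, "TN": self.tn}


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0 = wild type, 1 = mutant)")
    if labels.min() == labels.max():
        raise ValueError("both label classes must be present; got a single class")
    return scores, labels


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, with finite end sentinels."""
    distinct = np.unique(scores)
    span = distinct[-1] - distinct[0]
    pad = 0.5 * span if span > 0 else 1.0
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - pad], mids, [distinct[-1] + pad]))


def roc_curve(scores, labels) -> RocCurve:
    """ROC curve of a score against binary truth labels.

    Every threshold interval between adjacent distinct observed scores is
    represented by its midpoint; sentinels below the minimum and above the
    maximum give the (1, 1) and (0, 0) endpoints.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    thresholds = _candidate_thresholds(scores)[::-1]  # descending: (0,0) -> (1,1)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    pos_calls = scores[None, :] > thresholds[:, None]
    tp = (pos_calls & (labels == 1)).sum(axis=1)
    fp = (pos_calls & (labels == 0)).sum(axis=1)
    return RocCurve(thresholds=thresholds, fpr=fp / n_neg, tpr=tp / n_pos)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under a ROC curve.

    Equals the Mann-Whitney rank statistic: the fraction of mutant/wild-type
    pairs in which the mutant scores higher, ties counted one half.
    """
    order = np.argsort(curve.fpr, kind="stable")
    return float(np.trapezoid(curve.tpr[order], curve.fpr[order]))


def confusion_metrics(predicted, truth) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of binary calls against truth."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if truth.min() == truth.max():
        raise ValueError("sensitivity/specificity undefined: truth contains a single class")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    return tp / (tp + fn), tn / (tn + fp), (tp + tn) / truth.size


def select_cutoff(scores, labels) -> CutoffCalibration:
    """Choose the accuracy-maximising cutoff for the rule score > cutoff => MT.

    Accuracy is evaluated at every threshold interval between adjacent
    observed scores (midpoint representatives, plus sentinels beyond the
    extremes).  Ties in accuracy are broken by higher sensitivity, then by
    the lower cutoff — the screening-oriented choice that favours calling
    mutants.  Confusion counts and rates are reported at the returned
    cutoff.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    curve = roc_curve(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)

    best = None
    for t in _candidate_thresholds(scores):
        pred = scores > t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn, tn = n_pos - tp, n_neg - fp
        acc = (tp + tn) / labels.size
        sens = tp / n_pos
        # lexicographic: max accuracy, then max sensitivity, then min cutoff
        key = (acc, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, tp, fn, fp, tn)

    _, cutoff, tp, fn, fp, tn = best
    return CutoffCalibration(
        cutoff=float(cutoff),
        auc=auc(curve),
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        accuracy=(tp + tn) / labels.size,
    )


def assign_status(table: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Assign MT/WT status to a risk-score table at a fixed cutoff.

    MT means risk_score strictly greater than the cutoff ("score over the
    cutoff"); a score exactly equal to the cutoff is WT.  Returns a copy
    with the ``status`` column filled.
    """
    if not np.isfinite(cutoff) or cutoff <= 0:
        raise ValueError("cutoff must be a finite positive number")
    out = table.copy()
    out["status"] = np.where(out["risk_score"] > cutoff, STATUS_MT, STATUS_WT)
    return out
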