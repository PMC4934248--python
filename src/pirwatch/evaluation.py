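"""Detection metrics: confusion-matrix rates, ROC curves, AUC.

The abnormal class (falls) is the positive class throughout:
detection rate = TP / (TP + FN), false alarm rate = FP / (FP + TN).
Continuous scores are swept over all thresholds into an ROC (detection rate
against false alarm rate) and summarized by the trapezoidal area under it,
which equals the tie-corrected Mann-Whitney statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = ["ConfusionMatrix", "ROCResult", "rates", "roc_auc", "confusion_at"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with abnormal as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCResult:
    """Empirical ROC: paired rate arrays (including (0,0) and (1,1)) and AUC."""

    false_alarm_rate: np.ndarray
    detection_rate: np.ndarray
    auc: float
    thresholds: np.ndarray | None = None


def rates(cm: ConfusionMatrix) -> tuple[float, float]:
    """(detection rate, false alarm rate) of a confusion matrix."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no abnormal samples: detection rate undefined")
    if cm.fp + cm.tn == 0:
        raise ValueError("no normal samples: false alarm rate undefined")
    return cm.tp / (cm.tp + cm.fn), cm.fp / (cm.fp + cm.tn)


def confusion_at(scores, labels_abnormal, threshold: float,
                 higher_is_normal: bool = True) -> ConfusionMatrix:
    """Confusion matrix at one operating point.

    With ``higher_is_normal`` (the pipeline convention) a sample is flagged
    abnormal when its score falls below the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels_abnormal, dtype=bool)
    pred_abn = scores < threshold if higher_is_normal else scores > threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred_abn & labels)),
        fp=int(np.sum(pred_abn & ~labels)),
        fn=int(np.sum(~pred_abn & labels)),
        tn=int(np.sum(~pred_abn & ~labels)),
    )


def roc_auc(scores, labels_abnormal, higher_is_normal: bool = True) -> ROCResult:
    """Full-threshold ROC and trapezoidal AUC.

    ``labels_abnormal`` marks the positive (abnormal) class; ``scores`` are
    oriented larger-is-more-normal by default and flipped internally so that
    larger means more abnormal before the sweep.  Equal scores share one
    threshold step.  Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels_abnormal, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to sweep an ROC")
    abnormal_score = -scores if higher_is_normal else scores
    far, dr, thr = _skm.roc_curve(labels, abnormal_score, drop_intermediate=False)
    return ROCResult(false_alarm_rate=far, detection_rate=dr,
                     auc=float(_skm.auc(far, dr)), thresholds=thr)
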