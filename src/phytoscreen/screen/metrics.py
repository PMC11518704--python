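"""Binary-classification metrics at the F1-optimal operating point.

AUROC and AUPRC come from scikit-learn (rank-based AUROC; AUPRC as the
step-wise precision-recall integral, i.e. average precision).  The
threshold is the prediction score maximising F1 over all observed score
cut-offs (ties broken toward the higher threshold); sensitivity,
specificity and accuracy are reported at that threshold with the
convention ``predicted positive iff score >= threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["EvalMetrics", "evaluate_scores"]


@dataclass(frozen=True)
class EvalMetrics:
    auroc: float
    auprc: float
    f1: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float

    def as_dict(self) -> dict:
        return {
            "AUROC": self.auroc,
            "AUPRC": self.auprc,
            "F1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "threshold": self.threshold,
        }


def evaluate_scores(scores, labels) -> EvalMetrics:
    """Metrics for prediction scores against binary labels.

    Raises on single-class label vectors (AUROC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if len(set(labels.tolist())) < 2:
        raise ValueError("labels contain a single class; AUROC undefined")

    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))

    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        # >= keeps the highest threshold among F1 ties
        if best is None or f1 >= best[0]:
            best = (f1, float(thr))
    f1, thr = best

    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / len(labels)
    return EvalMetrics(auroc, auprc, f1, sens, spec, acc, thr)
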