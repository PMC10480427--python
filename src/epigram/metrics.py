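"""Binary-classification metrics: accuracy, precision, recall, F-measure, ROC/AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    auc,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_curve,
)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    auc: float | None
    roc_points: list[tuple[float, float]]
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }


def compute_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Standard binary metrics; AUC by trapezoidal integration of the ROC.

    ``scores`` are continuous decision values; when absent the ROC is built
    from the binary predictions themselves (a single-threshold curve). With
    single-class truth the AUC is undefined and reported as ``None``.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    bad = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not bad <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(bad)}")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    accuracy = float(accuracy_score(y_true, y_pred))
    precision = float(precision_score(y_true, y_pred, zero_division=0))
    recall = float(recall_score(y_true, y_pred, zero_division=0))
    f_measure = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    if np.unique(y_true).size < 2:
        auc_val, roc_points = None, []
    else:
        s = np.asarray(scores, dtype=np.float64) if scores is not None else y_pred
        fpr, tpr, _ = roc_curve(y_true, s)
        auc_val = float(auc(fpr, tpr))
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        auc=auc_val,
        roc_points=roc_points,
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
    )
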