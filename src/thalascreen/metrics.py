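"""Confusion matrices and per-class one-vs-rest performance metrics.

For each class k against the rest: TP = M[k][k], FN = row k − TP,
FP = column k − TP, TN = everything else; sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
F1 = 2·PPV·sens/(PPV+sens).  Ratios with a zero denominator are reported as
NaN (not available), never coerced to 0.  Overall accuracy is
trace(M)/total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["ConfusionMatrix", "ClassMetrics", "confusion", "class_metrics",
           "binary_collapse", "metrics_report"]

NORMAL_LABEL = "aa_aa"


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # matrix[i, j] = count(true=labels[i], pred=labels[j])

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    per_class: pd.DataFrame  # index: class; columns: sensitivity..f1, n_true


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if not y_true:
        raise ValueError("empty input")
    label_set = set(labels)
    unseen = sorted({*y_true, *y_pred} - label_set)
    if unseen:
        raise ValueError(f"labels outside the declared set: {unseen}")
    m = _sk_confusion(y_true, y_pred, labels=list(labels))
    return ConfusionMatrix(tuple(labels), m.astype(np.int64))


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    m = cm.matrix
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    rows = {}
    for k, label in enumerate(cm.labels):
        tp = m[k, k]
        fn = m[k, :].sum() - tp
        fp = m[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        ppv = ratio(tp, tp + fp)
        npv = ratio(tn, tn + fn)
        f1 = ratio(2 * ppv * sens, ppv + sens) if not (np.isnan(ppv) or np.isnan(sens)) else float("nan")
        rows[label] = {
            "n_true": int(tp + fn),
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": npv,
            "f1": f1,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return ClassMetrics(accuracy=float(np.trace(m)) / total, per_class=per_class)


def binary_collapse(labels: Sequence[str]) -> list[str]:
    """Collapse five-class labels to the stage-1 normal/abnormal dichotomy."""
    return ["normal" if l == NORMAL_LABEL else "abnormal" for l in labels]


def metrics_report(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> dict:
    """Stage-1 (binary) and ensemble (multiclass) metrics as a JSON-ready dict."""
    ens_cm = confusion(y_true, y_pred, labels)
    ens = class_metrics(ens_cm)
    bin_cm = confusion(
        binary_collapse(y_true), binary_collapse(y_pred), ["normal", "abnormal"]
    )
    binm = class_metrics(bin_cm)

    def block(cm: ConfusionMatrix, met: ClassMetrics) -> dict:
        pc = met.per_class.copy()
        for col in ("sensitivity", "specificity", "ppv", "npv", "f1"):
            pc[col] = (pc[col] * 100).round(2)
        return {
            "accuracy_percent": round(met.accuracy * 100, 2),
            "labels": list(cm.labels),
            "confusion": cm.matrix.tolist(),
            "per_class": pc.to_dict(orient="index"),
        }

    return {"stage1": block(bin_cm, binm), "ensemble": block(ens_cm, ens)}
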