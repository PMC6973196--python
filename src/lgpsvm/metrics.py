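"""Confusion matrices and imbalance-aware classification metrics.

Overall accuracy hides minority-class failures in imbalanced microarray
data, so evaluation is built on the full confusion matrix.  Binary metrics
(precision, recall/TPR, TNR, F-measure, G-mean, accuracy) extend to the
multiclass case as the macro F-score (unweighted mean of per-class
F-measures), the G-mean (geometric mean of per-class accuracies) and the
prevalence-weighted accuracy.  Per-class accuracy is per-class recall
(diagonal over row sum) — the reading under which the multiclass G-mean
reduces to sqrt(TPR*TNR) and weighted accuracy reduces to overall accuracy
on 2x2 matrices.

Zero-denominator ratios evaluate to 0 and are flagged as undefined rather
than propagating NaN, keeping aggregates computable on degenerate folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion


@dataclass
class ConfusionMatrix:
    """C x C count table: rows are true classes, columns predicted.

    For two classes, class 0 is the positive class: counts map to
    [[TP, FN], [FP, TN]].
    """

    counts: np.ndarray
    classes: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C x C")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Count table with counts[i][j] = #{true=class_i and pred=class_j}."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred])).tolist()
    seen = set(np.unique(np.concatenate([y_true, y_pred])).tolist())
    if not seen <= set(classes):
        raise ValueError(f"labels {sorted(seen - set(classes))} not in classes")
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    return ConfusionMatrix(counts=counts, classes=list(classes))


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def binary_metrics(cm: ConfusionMatrix) -> dict:
    """Precision, recall, TNR, F-measure, G-mean and accuracy for 2 classes.

    Class 0 is positive.  The returned dict carries an ``undefined`` set
    naming any ratio whose denominator was zero (reported as 0).
    """
    if cm.counts.shape != (2, 2):
        raise ValueError("binary_metrics requires a 2x2 confusion matrix")
    (tp, fn), (fp, tn) = cm.counts
    undefined: set[str] = set()
    precision = _ratio(tp, tp + fp, "precision", undefined)
    recall = _ratio(tp, tp + fn, "recall", undefined)
    tnr = _ratio(tn, tn + fp, "tnr", undefined)
    f_den = recall + precision
    f_measure = 2 * recall * precision / f_den if f_den > 0 else 0.0
    if f_den == 0:
        undefined.add("f_measure")
    g_mean = float(np.sqrt(recall * tnr))
    accuracy = _ratio(tp + tn, tp + tn + fp + fn, "accuracy", undefined)
    return {
        "precision": precision,
        "recall": recall,
        "tnr": tnr,
        "f_measure": f_measure,
        "g_mean": g_mean,
        "accuracy": accuracy,
        "undefined": undefined,
    }


def _per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    row_sums = cm.counts.sum(axis=1)
    if np.any(row_sums == 0):
        empty = [cm.classes[i] for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"classes with no true samples: {empty}")
    return np.diag(cm.counts) / row_sums


def multiclass_g_mean(cm: ConfusionMatrix) -> float:
    """Geometric mean of per-class accuracies (recalls); 0 if any class is
    fully missed."""
    recalls = _per_class_recall(cm)
    if np.any(recalls == 0):
        return 0.0
    return float(np.prod(recalls) ** (1.0 / len(recalls)))


def multiclass_f_score(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F-measures (macro F).

    Class i's precision is diagonal over column sum, recall diagonal over
    row sum; degenerate ratios contribute 0.
    """
    counts = cm.counts
    diag = np.diag(counts).astype(float)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    f_values = []
    for i in range(len(cm.classes)):
        prec = diag[i] / col[i] if col[i] > 0 else 0.0
        rec = diag[i] / row[i] if row[i] > 0 else 0.0
        f_values.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    return float(np.mean(f_values))


def weighted_accuracy(cm: ConfusionMatrix) -> float:
    """Per-class accuracies weighted by class prevalence.

    With per-class accuracy read as recall this equals trace/total, i.e.
    the overall classification accuracy.
    """
    recalls = _per_class_recall(cm)
    weights = cm.counts.sum(axis=1) / cm.total
    return float(np.sum(recalls * weights))
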