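"""Classifier evaluation: confusion matrices, binary and micro-averaged
multiclass metrics, one-vs-all ROC/AUC, and report assembly.

Metric definitions (fractions in [0, 1], rendered as percentages at one
decimal only for presentation):

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Se  = TP / (TP + FN)        Sp = TN / (TN + FP)
    P   = TP / (TP + FP)
    BA  = (Se + Sp) / 2         F1 = 2·P·Se / (P + Se)

Multiclass metrics use micro-averaging: TP/TN/FP/FN are summed over the
one-vs-rest decomposition of every class before the ratios are formed.
For single-label problems this makes micro precision = micro
sensitivity = overall accuracy (the off-diagonal total plays the role
of both FP and FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, columns = predicted
    class_names: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        m = len(self.class_names)
        if self.counts.shape != (m, m):
            raise ValueError("confusion matrix shape does not match class names")
        if (self.counts < 0).any():
            raise ValueError("negative counts")


@dataclass
class MetricSet:
    acc: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    balanced_accuracy: float
    flags: list = field(default_factory=list)

    def as_percent(self, decimals: int = 1) -> dict:
        """Rounded-half-up percentage rendering of the fractional metrics."""

        def pct(v: float) -> float:
            scaled = v * 100 * 10**decimals
            return float(np.floor(scaled + 0.5) / 10**decimals)

        return {
            "accuracy": pct(self.acc),
            "precision": pct(self.precision),
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "f1": pct(self.f1),
            "balanced_accuracy": pct(self.balanced_accuracy),
        }


def _ratio(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(f"{name}: 0/0 defined as 0")
        return 0.0
    return num / den


def confusion(y_true, y_pred, class_names) -> ConfusionMatrix:
    """Count (true, predicted) pairs in the declared class order."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    unknown = (set(y_true) | set(y_pred)) - set(class_names)
    if unknown:
        raise ValueError(f"labels outside the declared class set: {sorted(unknown)}")
    counts = _sk_confusion(y_true, y_pred, labels=list(class_names))
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def derived_ba_f1(precision: float, sensitivity: float, specificity: float, flags: list):
    ba = (sensitivity + specificity) / 2.0
    f1 = _ratio(2 * precision * sensitivity, precision + sensitivity, "f1", flags)
    return ba, f1


def binary_metrics(cm: ConfusionMatrix, positive_class=None) -> MetricSet:
    """Two-class metrics with a designated positive class.

    The positive class defaults to 'Pathologic' when present (screening
    convention: sensitivity measures disease detection), else the second
    class name.
    """
    if len(cm.class_names) != 2:
        raise ValueError("binary_metrics requires a 2x2 confusion matrix")
    if positive_class is None:
        positive_class = "Pathologic" if "Pathologic" in cm.class_names else cm.class_names[1]
    p = cm.class_names.index(positive_class)
    n = 1 - p
    tp, fn = cm.counts[p, p], cm.counts[p, n]
    fp, tn = cm.counts[n, p], cm.counts[n, n]
    flags: list = []
    acc = _ratio(tp + tn, tp + tn + fp + fn, "acc", flags)
    se = _ratio(tp, tp + fn, "sensitivity", flags)
    sp = _ratio(tn, tn + fp, "specificity", flags)
    prec = _ratio(tp, tp + fp, "precision", flags)
    ba, f1 = derived_ba_f1(prec, se, sp, flags)
    return MetricSet(acc, prec, se, sp, f1, ba, flags)


def multiclass_micro_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Micro-averaged metrics: TP/TN/FP/FN summed over all classes."""
    c = cm.counts
    m = len(cm.class_names)
    if m < 2:
        raise ValueError("need at least 2 classes")
    total = c.sum()
    tp = np.trace(c)
    flags: list = []
    acc = _ratio(tp, total, "acc", flags)
    tp_sum = fp_sum = fn_sum = tn_sum = 0
    for k in range(m):
        tp_k = c[k, k]
        fn_k = c[k, :].sum() - tp_k
        fp_k = c[:, k].sum() - tp_k
        tn_k = total - tp_k - fn_k - fp_k
        tp_sum += tp_k
        fp_sum += fp_k
        fn_sum += fn_k
        tn_sum += tn_k
    se = _ratio(tp_sum, tp_sum + fn_sum, "sensitivity", flags)
    sp = _ratio(tn_sum, tn_sum + fp_sum, "specificity", flags)
    prec = _ratio(tp_sum, tp_sum + fp_sum, "precision", flags)
    ba, f1 = derived_ba_f1(prec, se, sp, flags)
    return MetricSet(acc, prec, se, sp, f1, ba, flags)


def roc_auc(scores, y_true, positive_class) -> tuple[pd.DataFrame, float]:
    """One-vs-all ROC curve and trapezoidal AUC for one class.

    Tied scores collapse into a single threshold step, so the AUC equals
    the concordant-pair (Mann-Whitney) statistic with ties counted 1/2.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_bin = (y_true == positive_class).astype(int)
    if y_bin.all() or not y_bin.any():
        raise ValueError("ROC undefined: truth contains a single class")
    fpr, tpr, thresholds = _sk_roc_curve(y_bin, scores)
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, auc


def report(model, test_table: pd.DataFrame, positive_class=None) -> dict:
    """Full evaluation report for a trained model on a test table.

    JSON-serializable: metrics as fractions and as 1-decimal
    percentages, the confusion matrix, per-class one-vs-all AUC, and the
    serialized model size in bytes.
    """
    from .models import model_size_bytes, predict, predict_scores

    y_true = test_table["label"].to_numpy()
    y_pred = predict(model, test_table)
    class_names = list(model.classes)
    cm = confusion(y_true, y_pred, class_names)
    if len(class_names) == 2:
        metrics = binary_metrics(cm, positive_class)
        task = "binary"
    else:
        metrics = multiclass_micro_metrics(cm)
        task = "multiclass"
    scores = predict_scores(model, test_table)
    aucs = {}
    for cls in class_names:
        try:
            _, aucs[cls] = roc_auc(scores[cls].to_numpy(), y_true, cls)
        except ValueError:
            aucs[cls] = None
    return {
        "task": task,
        "n_test_frames": int(len(test_table)),
        "class_names": class_names,
        "confusion_matrix": cm.counts.tolist(),
        "metrics": {
            "acc": metrics.acc,
            "precision": metrics.precision,
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "f1": metrics.f1,
            "balanced_accuracy": metrics.balanced_accuracy,
        },
        "metrics_percent": metrics.as_percent(),
        "metric_flags": metrics.flags,
        "auc_per_class": aucs,
        "model_size_bytes": model_size_bytes(model),
    }
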