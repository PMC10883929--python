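"""Multiclass evaluation: one-vs-rest metrics, confusion matrices, ROC.

Per-class metrics treat that class as positive and every other class as
negative: accuracy (TP+TN)/N, precision, recall (= sensitivity),
specificity TN/(TN+FP), F1, FPR = 1 - specificity, FNR = 1 - recall.
Aggregates are macro averages. Confusion matrices come in raw counts
and in a row-percentage view (each true-class row sums to 100). ROC
curves are one-vs-rest threshold sweeps over predicted probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, confusion_matrix, roc_curve

__all__ = ["ClassMetrics", "MetricsReport", "compute_metrics"]


@dataclass
class ClassMetrics:
    name: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    fpr: float
    fnr: float
    support: int

    @property
    def sensitivity(self) -> float:
        return self.recall


@dataclass
class MetricsReport:
    class_names: list[str]
    per_class: list[ClassMetrics]
    confusion: np.ndarray               # counts, rows = true class
    confusion_row_percent: np.ndarray
    accuracy: float                     # micro: trace / total
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_specificity: float
    macro_fpr: float
    macro_fnr: float
    roc: dict[str, dict] = field(default_factory=dict)   # per class: fpr/tpr/auc
    fold_id: int | None = None

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "class": m.name, "accuracy": m.accuracy, "precision": m.precision,
            "recall": m.recall, "f1": m.f1, "specificity": m.specificity,
            "fpr": m.fpr, "fnr": m.fnr, "support": m.support,
        } for m in self.per_class])

    @property
    def macro_auc(self) -> float:
        vals = [v["auc"] for v in self.roc.values() if not np.isnan(v["auc"])]
        return float(np.mean(vals)) if vals else float("nan")


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def compute_metrics(y_true, y_pred, probs: np.ndarray | None = None,
                    class_names: list[str] | None = None,
                    fold_id: int | None = None) -> MetricsReport:
    """Full report from labels (and optionally class probabilities).

    ``y_true``/``y_pred`` are integer labels; ``probs`` rows must sum to
    one when given (enables ROC/AUC).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty evaluation set")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    n_classes = len(class_names) if class_names else int(max(y_true.max(), y_pred.max())) + 1
    class_names = class_names or [f"class_{i}" for i in range(n_classes)]
    if y_true.max() >= n_classes or y_pred.max() >= n_classes or y_true.min() < 0:
        raise ValueError("label outside the class set")
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    total = cm.sum()
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = np.where(row_sums > 0, 100.0 * cm / row_sums, 0.0)

    per_class: list[ClassMetrics] = []
    for i, name in enumerate(class_names):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        per_class.append(ClassMetrics(
            name=name,
            accuracy=_safe_div(tp + tn, total),
            precision=prec,
            recall=rec,
            f1=_safe_div(2 * prec * rec, prec + rec),
            specificity=spec,
            fpr=1.0 - spec,
            fnr=1.0 - rec,
            support=int(cm[i].sum()),
        ))

    roc: dict[str, dict] = {}
    if probs is not None:
        for i, name in enumerate(class_names):
            pos = (y_true == i).astype(int)
            if pos.sum() in (0, len(pos)):
                roc[name] = {"fpr": np.array([0.0, 1.0]),
                             "tpr": np.array([0.0, 1.0]), "auc": float("nan")}
                continue
            fpr, tpr, _ = roc_curve(pos, probs[:, i])
            roc[name] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}

    return MetricsReport(
        class_names=list(class_names),
        per_class=per_class,
        confusion=cm,
        confusion_row_percent=row_pct,
        accuracy=_safe_div(np.trace(cm), total),
        macro_precision=float(np.mean([m.precision for m in per_class])),
        macro_recall=float(np.mean([m.recall for m in per_class])),
        macro_f1=float(np.mean([m.f1 for m in per_class])),
        macro_specificity=float(np.mean([m.specificity for m in per_class])),
        macro_fpr=float(np.mean([m.fpr for m in per_class])),
        macro_fnr=float(np.mean([m.fnr for m in per_class])),
        roc=roc,
        fold_id=fold_id,
    )
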