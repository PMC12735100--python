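"""Multiclass evaluation: confusion matrix, per-class metrics, macro AUC.

The confusion matrix is oriented rows = true label, columns = predicted
label. For each class c the one-vs-rest counts are

    TP = counts[c, c]                FP = column c minus TP
    FN = row c minus TP              TN = everything else

and the four per-class metrics are

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Aggregates use macro (unweighted class-mean) averaging, which treats rare
and common species symmetrically; overall accuracy is trace / total. A zero
denominator yields 0 and sets a degeneracy flag rather than NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "compute_confusion",
    "per_class_metrics",
    "aggregate_metrics",
    "evaluate_predictions",
    "multiclass_auc",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_labels: list[str]

    def __post_init__(self):
        c = np.asarray(self.counts)
        n = len(self.class_labels)
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion counts must be nonnegative")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, index: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for one class against all others."""
        c = self.counts
        tp = int(c[index, index])
        fp = int(c[:, index].sum()) - tp
        fn = int(c[index, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.class_labels, columns=self.class_labels)
        df.index.name = "true\\predicted"
        df.to_csv(path)


@dataclass
class MetricsReport:
    class_labels: list[str]
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    aggregate: dict[str, float] = field(default_factory=dict)
    degenerate_classes: list[str] = field(default_factory=list)
    auc: float | None = None
    per_class_auc: dict[str, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "orientation": "rows=true, columns=predicted",
            "averaging": "macro (unweighted class mean)",
            "per_class": self.per_class,
            "aggregate": self.aggregate,
            "degenerate_classes": self.degenerate_classes,
        }
        if self.auc is not None:
            d["auc"] = self.auc
            d["per_class_auc"] = self.per_class_auc
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        rows = [{"class": c, **m} for c, m in self.per_class.items()]
        rows.append({"class": "__aggregate__", **self.aggregate})
        pd.DataFrame(rows).to_csv(path, index=False)


def compute_confusion(true_labels, predicted_labels, class_labels) -> ConfusionMatrix:
    """Tally an n x n count table; rows are true labels, columns predictions."""
    class_labels = list(class_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_labels)}
    n = len(class_labels)
    counts = np.zeros((n, n), np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label: {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label: {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, class_labels)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest accuracy/precision/recall/F1 for every class."""
    report = MetricsReport(class_labels=list(cm.class_labels))
    for i, label in enumerate(cm.class_labels):
        tp, fp, tn, fn = cm.one_vs_rest(i)
        acc, d0 = _safe_div(tp + tn, tp + tn + fp + fn)
        prec, d1 = _safe_div(tp, tp + fp)
        rec, d2 = _safe_div(tp, tp + fn)
        f1, d3 = _safe_div(2 * prec * rec, prec + rec)
        report.per_class[label] = {
            "accuracy": acc,
            "precision": prec,
            "recall": rec,
            "f1": f1,
        }
        if d0 or d1 or d2 or d3:
            report.degenerate_classes.append(label)
    return report


def aggregate_metrics(report: MetricsReport, cm: ConfusionMatrix) -> MetricsReport:
    """Overall accuracy (trace/total) and macro precision/recall/F1."""
    if not report.per_class:
        raise ValueError("per-class metrics must be computed first")
    per = report.per_class
    report.aggregate = {
        "accuracy": float(np.trace(cm.counts)) / cm.total if cm.total else 0.0,
        "macro_precision": float(np.mean([m["precision"] for m in per.values()])),
        "macro_recall": float(np.mean([m["recall"] for m in per.values()])),
        "macro_f1": float(np.mean([m["f1"] for m in per.values()])),
    }
    return report


def evaluate_predictions(true_labels, predicted_labels, class_labels) -> tuple[ConfusionMatrix, MetricsReport]:
    """Convenience: confusion matrix plus the full metrics report."""
    cm = compute_confusion(true_labels, predicted_labels, class_labels)
    report = aggregate_metrics(per_class_metrics(cm), cm)
    return cm, report


def _binary_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Trapezoidal ROC area for one binary problem.

    Thresholds are the unique score values; equivalent to the Mann-Whitney
    statistic with the tie correction.
    """
    order = np.argsort(-score, kind="stable")
    y = y[order]
    score = score[order]
    distinct = np.r_[np.nonzero(np.diff(score))[0], y.size - 1]
    tps = np.cumsum(y)[distinct].astype(np.float64)
    fps = (distinct + 1) - tps
    tps = np.r_[0.0, tps]
    fps = np.r_[0.0, fps]
    tpr = tps / tps[-1]
    fpr = fps / fps[-1]
    return float(np.trapezoid(tpr, fpr))


def multiclass_auc(true_labels, probabilities, class_labels=None, return_per_class: bool = False):
    """Macro one-vs-rest ROC AUC from per-sample probability vectors.

    ``true_labels`` are integer class indices into the probability columns
    (or names, if ``class_labels`` is given). Classes absent from the truth —
    or present in every sample — carry no ROC curve and are excluded from the
    macro mean with a warning.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("probabilities must be (samples, classes)")
    n = p.shape[1]
    if class_labels is not None:
        index = {c: i for i, c in enumerate(class_labels)}
        truth = np.array([index[t] for t in true_labels])
        names = list(class_labels)
    else:
        truth = np.asarray(true_labels, dtype=np.int64)
        names = list(range(n))
    if truth.shape[0] != p.shape[0]:
        raise ValueError("label and probability counts differ")
    aucs: dict = {}
    for c in range(n):
        y = (truth == c).astype(np.int64)
        pos = int(y.sum())
        if pos == 0 or pos == y.size:
            warnings.warn(
                f"class {names[c]!r} has no negative or no positive samples; "
                "excluded from the macro AUC",
                stacklevel=2,
            )
            continue
        aucs[names[c]] = _binary_auc(y, p[:, c])
    if not aucs:
        raise ValueError("no class had both positive and negative samples")
    macro = float(np.mean(list(aucs.values())))
    if return_per_class:
        return macro, aucs
    return macro
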