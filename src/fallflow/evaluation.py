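"""Confusion-matrix metrics, ROC curves and AUC for binary fall detection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion table must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    """The five confusion metrics (proportions) plus optional ROC/AUC."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    counts: Optional[ConfusionCounts] = None
    roc_points: Optional[list[tuple[float, float, float]]] = None
    auc: Optional[float] = None

    _METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1")

    def as_percent(self) -> dict[str, str]:
        """Metrics formatted to one decimal place, e.g. '97.7%'."""
        out = {}
        for name in self._METRICS:
            v = getattr(self, name)
            out[name] = "nan" if np.isnan(v) else f"{100.0 * v:.1f}%"
        if self.auc is not None:
            out["auc"] = f"{self.auc:.3f}"
        return out

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in self._METRICS}
        d["percent"] = self.as_percent()
        if self.counts is not None:
            d["confusion"] = {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            }
        if self.auc is not None:
            d["auc"] = float(self.auc)
        if self.roc_points is not None:
            d["roc_points"] = [
                {"fpr": float(f), "tpr": float(t), "threshold": float(th)}
                for f, t, th in self.roc_points
            ]
        return d


def _check_binary(labels: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, True, False}:
        raise ValueError(f"{name} must be binary 0/1, found values {sorted(uniq)}")
    return arr.astype(np.int64)


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Exact 2x2 confusion counts (positive class = 1)."""
    t = _check_binary(labels_true, "labels_true")
    p = _check_binary(labels_pred, "labels_pred")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape[0]} vs {p.shape[0]}")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Accuracy, sensitivity, specificity, precision and F1 from raw counts.

    Undefined ratios (zero denominators) are reported as NaN with a warning,
    never silently coerced to 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = _ratio(tp + tn, counts.total, "accuracy")
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    specificity = _ratio(tn, tn + fp, "specificity")
    precision = _ratio(tp, tp + fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        warnings.warn("f1 undefined; reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return EvaluationReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        counts=counts,
    )


def roc_and_auc(
    labels_true, fall_probabilities
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC staircase over the distinct scores plus a sentinel, and its
    trapezoidal AUC.  Constant scores yield the chance diagonal (AUC 0.5)."""
    t = _check_binary(labels_true, "labels_true")
    p = np.asarray(fall_probabilities, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape[0]} vs {p.shape[0]}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(set(t.tolist())) < 2:
        raise ValueError("ROC requires both classes present in labels_true")
    fpr, tpr, thresholds = _sk_roc_curve(t, p, drop_intermediate=False)
    points = [(float(f), float(s), float(th)) for f, s, th in zip(fpr, tpr, thresholds)]
    return points, float(_sk_auc(fpr, tpr))


def evaluate(
    labels_true,
    labels_pred=None,
    fall_probabilities=None,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Full report: confusion metrics, plus ROC/AUC when scores are given."""
    if labels_pred is None:
        if fall_probabilities is None:
            raise ValueError("need labels_pred or fall_probabilities")
        labels_pred = (np.asarray(fall_probabilities) >= threshold).astype(np.int64)
    report = metrics(confusion(labels_true, labels_pred))
    if fall_probabilities is not None:
        report.roc_points, report.auc = roc_and_auc(labels_true, fall_probabilities)
    return report


def plot_roc(roc_points: Sequence[tuple[float, float, float]], auc_value: float, path) -> None:
    """Optional ROC figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[0] for p in roc_points]
    tpr = [p[1] for p in roc_points]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {auc_value:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
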