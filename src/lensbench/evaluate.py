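"""Confusion metrics, ROC/AUC and stratified k-fold utilities.

Metric definitions (P positives, N negatives): accuracy = (TP+TN)/(P+N),
sensitivity = TP/P, specificity = TN/N, FNR = FN/P, FPR = FP/N. Counts are
integers, so the ratios are formed in exact rational arithmetic before
conversion to float. An empty class makes the per-class rates undefined and
raises ``UndefinedMetricError`` rather than propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "FoldMetrics",
    "MetricsReport",
    "confusion_metrics",
    "roc_auc",
    "stratified_kfold",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator (P or N) is zero."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class FoldMetrics:
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    fnr: float
    fpr: float
    auc: float | None = None
    roc_points: np.ndarray | None = field(default=None, repr=False)


@dataclass
class MetricsReport:
    """Per-fold metrics with across-fold mean and sample standard deviation."""

    folds: list[FoldMetrics]

    def _stat(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.folds], dtype=float)
        delta = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), delta

    @property
    def accuracy(self) -> tuple[float, float]:
        return self._stat("accuracy")

    @property
    def sensitivity(self) -> tuple[float, float]:
        return self._stat("sensitivity")

    @property
    def specificity(self) -> tuple[float, float]:
        return self._stat("specificity")

    @property
    def auc(self) -> tuple[float, float]:
        return self._stat("auc")

    def pooled_counts(self) -> ConfusionCounts:
        return ConfusionCounts(
            TP=sum(f.counts.TP for f in self.folds),
            FN=sum(f.counts.FN for f in self.folds),
            TN=sum(f.counts.TN for f in self.folds),
            FP=sum(f.counts.FP for f in self.folds),
        )

    def as_dict(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            mu, delta = self._stat(name)
            out[name] = {"mean": mu, "std": delta}
        out["per_fold"] = [
            {
                "accuracy": f.accuracy,
                "sensitivity": f.sensitivity,
                "specificity": f.specificity,
                "fnr": f.fnr,
                "fpr": f.fpr,
                "auc": f.auc,
            }
            for f in self.folds
        ]
        return out


def confusion_metrics(labels: np.ndarray, predictions: np.ndarray) -> FoldMetrics:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape or labels.ndim != 1:
        raise ValueError("labels and predictions must be equal-length 1-D sequences")
    if len(labels) == 0:
        raise UndefinedMetricError("no samples to evaluate")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    counts = ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)
    if counts.P == 0 or counts.N == 0:
        raise UndefinedMetricError(
            f"a class is absent (P={counts.P}, N={counts.N}); per-class rates undefined"
        )
    return FoldMetrics(
        counts=counts,
        accuracy=float(Fraction(tp + tn, counts.P + counts.N)),
        sensitivity=float(Fraction(tp, counts.P)),
        specificity=float(Fraction(tn, counts.N)),
        fnr=float(Fraction(fn, counts.P)),
        fpr=float(Fraction(fp, counts.N)),
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep, and the trapezoidal AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC/AUC undefined with a single class")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(_sk_auc(fpr, tpr))


def stratified_kfold(labels: np.ndarray, k: int = 4, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold split; returns (train_idx, test_idx) pairs."""
    labels = np.asarray(labels, dtype=int)
    for cls in np.unique(labels):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(labels)), labels)]
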