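"""Confusion matrices, classification metrics, and PCA projections.

Metrics follow the standard one-vs-rest decomposition of a multiclass
confusion matrix: per class, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R); overall accuracy is the trace over the total. Aggregation is
weighted by class support by default, under which aggregate recall is
algebraically identical to accuracy (sum_i support_i/N * TP_i/support_i =
trace/N); macro averaging is available by flag. All metrics are reported as
percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["ConfusionMatrix", "MetricReport", "PCAResult", "confusion", "metrics", "pca"]


@dataclass
class ConfusionMatrix:
    """Counts[i][j] = number of samples with true class i predicted as j."""

    counts: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.counts)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (C < 0).any() or not np.issubdtype(C.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        self.counts = C
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (C.shape[0],):
            raise ValueError("one label per class required")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass
class MetricReport:
    """Aggregate and per-class metrics, all in percent."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    per_class: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_class.to_csv(path)


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.explained_variance_ratio)
        if (r < -1e-12).any() or (np.diff(r) > 1e-12).any() or r.sum() > 1 + 1e-9:
            raise ValueError("variance ratios must be nonnegative, nonincreasing, sum <= 1")


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Count matrix of true class (rows) vs predicted class (columns)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.unique(y_true) if labels is None else np.asarray(labels)
    unknown = set(np.unique(y_pred)) | set(np.unique(y_true))
    if not unknown <= set(labels.tolist()):
        raise ValueError(f"labels outside the given label set: {sorted(unknown - set(labels.tolist()))}")
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    return ConfusionMatrix(counts.astype(int), labels)


def metrics(cm: ConfusionMatrix, averaging: str = "weighted") -> MetricReport:
    """Accuracy, precision, recall and F1 (percent) from a confusion matrix.

    Division by zero (a class never predicted, or absent from the truth) gives
    a 0 metric with a warning, so aggregates stay defined.
    """
    if averaging not in ("weighted", "macro"):
        raise ValueError("averaging must be 'weighted' or 'macro'")
    C = cm.counts.astype(float)
    total = C.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(C)
    support = C.sum(axis=1)       # TP + FN per class
    predicted = C.sum(axis=0)     # TP + FP per class

    def _safe_div(num, den, what):
        bad = den == 0
        if bad.any():
            warnings.warn(f"{what} undefined for {int(bad.sum())} class(es); set to 0")
        return np.where(bad, 0.0, num / np.where(bad, 1.0, den))

    precision_c = _safe_div(tp, predicted, "precision")
    recall_c = _safe_div(tp, support, "recall")
    pr_sum = precision_c + recall_c
    f1_c = np.where(pr_sum == 0, 0.0, 2 * precision_c * recall_c / np.where(pr_sum == 0, 1.0, pr_sum))

    if averaging == "weighted":
        w = support / total
    else:
        w = np.full(len(tp), 1.0 / len(tp))
    per_class = pd.DataFrame(
        {
            "support": support.astype(int),
            "precision_pct": 100 * precision_c,
            "recall_pct": 100 * recall_c,
            "f1_pct": 100 * f1_c,
        },
        index=cm.labels,
    )
    return MetricReport(
        accuracy=float(100 * tp.sum() / total),
        precision=float(100 * (w * precision_c).sum()),
        recall=float(100 * (w * recall_c).sum()),
        f1=float(100 * (w * f1_c).sum()),
        averaging=averaging,
        per_class=per_class,
    )


def pca(X: np.ndarray, k: int) -> PCAResult:
    """Mean-centered PCA via SVD with a deterministic sign convention
    (the largest-magnitude loading of each component is positive)."""
    X = np.asarray(X, dtype=float)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n_samples, n_bands)={min(X.shape)}")
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_
    flip = np.sign(loadings[np.arange(k), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return PCAResult(
        scores=scores * flip,
        explained_variance_ratio=model.explained_variance_ratio_,
        loadings=loadings * flip[:, None],
    )
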