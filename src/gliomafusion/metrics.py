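"""Classification and clustering metrics.

The study's primary endpoint is the multiclass Matthews correlation
coefficient (MCC), computed in covariance form from the 3x3 confusion matrix:

    MCC = (c*s - sum_k t_k p_k) / sqrt((s^2 - sum_k p_k^2)(s^2 - sum_k t_k^2))

with s the total count, c the trace, and t_k / p_k the true / predicted
per-class totals.  A zero denominator (degenerate truth or prediction margins)
yields MCC = 0 by convention.  Embedding quality is scored with the
Fowlkes-Mallows index (FMI) between a k-means clustering of the embeddings and
the true labels, and group comparisons use the two-tailed Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix", "mcc", "accuracy", "balanced_accuracy", "auroc_macro",
    "fmi", "kmeans_fmi", "mannwhitney_u_two_tailed",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        self.counts = c.astype(np.int64)

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int = 3) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _counts(cm) -> np.ndarray:
    if isinstance(cm, ConfusionMatrix):
        return cm.counts.astype(np.float64)
    return ConfusionMatrix(np.asarray(cm)).counts.astype(np.float64)


def mcc(cm) -> float:
    """Multiclass Matthews correlation coefficient (covariance form), in [-1, 1]."""
    c = _counts(cm)
    s = c.sum()
    if s <= 0:
        raise ValueError("empty confusion matrix")
    trace = np.trace(c)
    t = c.sum(axis=1)  # true totals
    p = c.sum(axis=0)  # predicted totals
    cov = trace * s - t @ p
    denom = np.sqrt(s**2 - p @ p) * np.sqrt(s**2 - t @ t)
    if denom == 0.0:
        return 0.0
    return float(np.clip(cov / denom, -1.0, 1.0))


def accuracy(cm) -> float:
    c = _counts(cm)
    s = c.sum()
    if s <= 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(c) / s)


def balanced_accuracy(cm) -> float:
    """Macro-average of per-class recalls; classes absent from the truth are excluded."""
    c = _counts(cm)
    if c.sum() <= 0:
        raise ValueError("empty confusion matrix")
    t = c.sum(axis=1)
    present = t > 0
    recalls = np.diag(c)[present] / t[present]
    return float(recalls.mean())


def auroc_macro(scores, labels) -> float:
    """One-vs-rest AUROC per class (midrank tie handling), macro-averaged.

    Classes without both a positive and a negative example are skipped with a
    warning; if labels contain a single class, a ValueError is raised.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[0] != labels.shape[0]:
        raise ValueError("scores must be (n, n_classes) aligned with labels")
    if np.unique(labels).size < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    aucs = []
    for k in range(scores.shape[1]):
        pos = labels == k
        if pos.all() or not pos.any():
            warnings.warn(f"class {k} lacks positives or negatives; skipped", stacklevel=2)
            continue
        aucs.append(roc_auc_score(pos, scores[:, k]))
    return float(np.mean(aucs))


def fmi(partition_a, partition_b) -> float:
    """Fowlkes-Mallows index between two partitions of the same items.

    Over all unordered item pairs: TP = co-clustered in both partitions,
    FMI = TP / sqrt((TP+FP)(TP+FN)); 0 when either partition has no co-pairs.
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be equal-length 1-D label sequences")
    if a.size < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def pairs(x):
        return float((x * (x - 1) // 2).sum())

    tp = pairs(cont)
    pa = pairs(cont.sum(axis=1))  # TP + FP
    pb = pairs(cont.sum(axis=0))  # TP + FN
    if pa == 0.0 or pb == 0.0:
        return 0.0
    return float(tp / np.sqrt(pa * pb))


def kmeans_fmi(embeddings, labels, k: int = 3, seed: int = 0) -> float:
    """Seeded k-means (10 restarts) on the embeddings, scored by FMI against labels."""
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if X.shape[0] < k:
        raise ValueError("need at least k samples")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    pred = km.fit_predict(X)
    return fmi(pred, labels)


def mannwhitney_u_two_tailed(sample_a, sample_b) -> tuple[float, float]:
    """Rank-sum U and two-tailed p; exact for small tie-free samples (n <= 12 per
    group), normal approximation with tie correction otherwise."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
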