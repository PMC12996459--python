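"""Attention, penultimate-feature, and Shapley-value interpretability.

Attention weights come from the attention-pooling layer of patch-sequence
experts (for the mixture-of-experts model, the router-weighted mixture of the
two experts' attention vectors).  Weights are reported raw (summing to 1),
scaled (N * w, so 1 means equal attention to all tokens), and as Shannon
entropy (natural log, bounded by ln N).

Feature attribution uses Shapley values of the classification head over the
penultimate features, against a background cohort: exact coalition enumeration
for d <= 16 features, antithetic permutation sampling above.  Per-mutation
feature-importance profiles contrast mean per-feature contributions (toward
each case's own class logit) between mutation-positive and -negative groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from math import factorial

import numpy as np

from ._autodiff import Tensor, relu
from .embedding_store import EmbeddingBag, Modality, SubtypeLabel, mutations_from_label
from .fusion_models import (
    ExpertKind, FusionKind, FusionModel, Mode, PatchMeanExpert,
)

__all__ = [
    "AttentionProfile", "FeatureProfile", "Grouping", "UnsupportedOperationError",
    "extract_attention", "scaled_attention", "attention_entropy",
    "penultimate_features", "shap_explain", "mutation_profile",
    "extreme_feature_instances",
]


class UnsupportedOperationError(RuntimeError):
    pass


class Grouping(str, Enum):
    BY_CLASS = "BY_CLASS"
    BY_IDH = "BY_IDH"
    BY_CODEL = "BY_CODEL"


@dataclass
class AttentionProfile:
    case_id: str
    modality: Modality
    weights: np.ndarray   # sum 1
    scaled: np.ndarray    # N * weights, mean exactly 1
    entropy: float        # nats, <= ln N


@dataclass
class FeatureProfile:
    """Per-feature attribution aggregate; when normalized, |importance| sums to 1
    (per row for the by-class grouping)."""

    contributions: np.ndarray
    importance: np.ndarray
    grouping: Grouping
    normalized: bool = True


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def scaled_attention(weights) -> np.ndarray:
    """N * weights: 1 means equal attention across all tokens."""
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1 or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("attention weights must be a 1-D vector summing to 1")
    return w.size * w


def attention_entropy(weights) -> float:
    """Shannon entropy -sum w ln w (nats), with 0 * ln 0 = 0."""
    w = np.asarray(weights, dtype=np.float64)
    if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("attention weights must be non-negative and sum to 1")
    w = w[w > 0]
    return float(-(w * np.log(w)).sum())


def extract_attention(model: FusionModel, bag: EmbeddingBag) -> AttentionProfile:
    """Attention profile of one bag under the model's patch-sequence pooling."""
    if model.config.expert_kind is not ExpertKind.PATCH_SEQUENCE:
        raise UnsupportedOperationError("attention requires patch-sequence experts")
    mode = Mode.WSI_ONLY if bag.modality is Modality.WSI else Mode.MRI_ONLY
    kw = {"wsi": bag} if bag.modality is Modality.WSI else {"mri": bag}
    out = model.forward(mode=mode, **kw)
    w = out.attention_wsi if bag.modality is Modality.WSI else out.attention_mri
    if w is None:
        raise UnsupportedOperationError("model produced no attention for this modality")
    w = w / w.sum()  # guard round-off
    return AttentionProfile(bag.case_id, bag.modality, w, scaled_attention(w),
                            attention_entropy(w))


# ---------------------------------------------------------------------------
# Penultimate features
# ---------------------------------------------------------------------------

def penultimate_features(model: FusionModel, wsi=None, mri=None,
                         mode: Mode = Mode.MM) -> np.ndarray:
    """The vector entering the (joint) classification head for the given
    input-availability mode."""
    return model.forward(wsi=wsi, mri=mri, mode=mode).penultimate


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

def shap_explain(head_fn, features, background, exact_max_dim: int = 16,
                 n_permutations: int = 128, seed: int = 0) -> np.ndarray:
    """Shapley values of ``head_fn`` per feature per class logit.

    ``head_fn`` maps an (m, d) feature matrix to (m, n_out) outputs; a feature
    "absent" from a coalition is replaced by background values, so the
    attributions satisfy efficiency: sum_i phi_i = f(x) - mean_b f(b).  Exact
    subset enumeration is used for d <= ``exact_max_dim``; antithetic
    permutation sampling (``n_permutations`` draws) above.  Returns
    (n, d, n_out).
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    B = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if B.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if X.shape[1] != B.shape[1]:
        raise ValueError("features and background widths differ")
    d = X.shape[1]
    if d <= exact_max_dim:
        return _shap_exact(head_fn, X, B)
    return _shap_sampling(head_fn, X, B, n_permutations, seed)


def _shap_exact(f, X, B) -> np.ndarray:
    n, d = X.shape
    n_b = B.shape[0]
    n_out = np.atleast_2d(f(X[:1])).shape[1]
    weights = {s: factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)}
    subsets = []
    for size in range(d + 1):
        subsets.extend(combinations(range(d), size))
    index = {s: i for i, s in enumerate(subsets)}
    phi = np.zeros((n, d, n_out))
    for xi in range(n):
        x = X[xi]
        v = np.zeros((len(subsets), n_out))
        for s in subsets:
            rows = B.copy()
            if s:
                rows[:, list(s)] = x[list(s)]
            v[index[s]] = np.atleast_2d(f(rows)).mean(axis=0)
        for i in range(d):
            rest = [j for j in range(d) if j != i]
            for size in range(d):
                w = weights[size]
                for s in combinations(rest, size):
                    s_with = tuple(sorted(s + (i,)))
                    phi[xi, i] += w * (v[index[s_with]] - v[index[s]])
    return phi


def _shap_sampling(f, X, B, n_permutations, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n, d = X.shape
    n_out = np.atleast_2d(f(X[:1])).shape[1]
    phi = np.zeros((n, d, n_out))
    for xi in range(n):
        x = X[xi]
        acc = np.zeros((d, n_out))
        for r in range(n_permutations // 2):
            perm = rng.permutation(d)
            b = B[rng.integers(B.shape[0])]
            for order in (perm, perm[::-1]):  # antithetic pair
                cur = b.copy()
                prev = np.atleast_2d(f(cur[None, :]))[0]
                for i in order:
                    cur[i] = x[i]
                    nxt = np.atleast_2d(f(cur[None, :]))[0]
                    acc[i] += nxt - prev
                    prev = nxt
        phi[xi] = acc / (2 * (n_permutations // 2))
    return phi


# ---------------------------------------------------------------------------
# Mutation / class profiles
# ---------------------------------------------------------------------------

def mutation_profile(contributions, labels, grouping: Grouping) -> FeatureProfile:
    """Aggregate Shapley values into a feature-importance profile.

    BY_CLASS: per class, the mean contribution toward that class's logit over
    its own cases (one normalized row per class).  BY_IDH / BY_CODEL: the mean
    per-feature contribution toward each case's own-label logit is contrasted
    between the mutation-positive and -negative groups; the absolute difference
    profile is normalized to sum 1.  BY_CODEL compares only IDH-mutant cases
    (codeletion status is defined only there).
    """
    phi = np.asarray(contributions, dtype=np.float64)
    labels = [SubtypeLabel(l) for l in labels]
    if phi.ndim != 3 or phi.shape[0] != len(labels):
        raise ValueError("contributions must be (n, d, n_classes) aligned with labels")
    grouping = Grouping(grouping)
    class_order = [SubtypeLabel.GBM, SubtypeLabel.ASTRO, SubtypeLabel.OLIGO]
    lab_idx = np.array([class_order.index(l) for l in labels])
    if grouping is Grouping.BY_CLASS:
        rows, imps = [], []
        for k, lab in enumerate(class_order):
            sel = lab_idx == k
            if not sel.any():
                raise ValueError(f"no cases with label {lab.value!r}")
            mean = phi[sel, :, k].mean(axis=0)
            rows.append(mean)
            total = np.abs(mean).sum()
            imps.append(np.abs(mean) / total if total > 0 else np.abs(mean))
        return FeatureProfile(np.asarray(rows), np.asarray(imps), grouping)
    own = phi[np.arange(len(labels)), :, lab_idx]   # (n, d): own-logit contributions
    if grouping is Grouping.BY_IDH:
        status = np.array([mutations_from_label(l)[0] for l in labels])
        keep = np.ones(len(labels), dtype=bool)
    else:
        idh = np.array([mutations_from_label(l)[0] for l in labels])
        status = np.array([mutations_from_label(l)[1] for l in labels])
        keep = idh
    pos = keep & status
    neg = keep & ~status
    if not pos.any() or not neg.any():
        raise ValueError(f"{grouping.value}: a comparison group is empty")
    diff = own[pos].mean(axis=0) - own[neg].mean(axis=0)
    total = np.abs(diff).sum()
    importance = np.abs(diff) / total if total > 0 else np.abs(diff)
    return FeatureProfile(diff, importance, grouping)


# ---------------------------------------------------------------------------
# Extreme-feature instance retrieval
# ---------------------------------------------------------------------------

def _penultimate_rows(model: FusionModel, bag: EmbeddingBag) -> np.ndarray:
    """Penultimate features of each token evaluated as a singleton bag, (N, d)."""
    mode = Mode.WSI_ONLY if bag.modality is Modality.WSI else Mode.MRI_ONLY
    kw_key = "wsi" if bag.modality is Modality.WSI else "mri"
    if model.config.expert_kind is ExpertKind.PATCH_MEAN and bag.modality in model.adapters:
        # rows are independent under patch-mean experts: batch them
        adapted = model.adapt(bag.tokens, bag.modality)
        cfg = model.config
        if cfg.fusion in (FusionKind.UNIMODAL_WSI, FusionKind.UNIMODAL_MRI):
            return model.experts["expert"].linear(relu(adapted)).data
        zero = penultimate_features(model, **{kw_key: EmbeddingBag(
            bag.case_id, bag.modality, np.zeros((1, bag.dim)), bag.label,
            n_slices=1)}, mode=mode)
        if cfg.fusion is FusionKind.LATE:
            own = model.experts[bag.modality.value].linear(relu(adapted)).data
        elif cfg.fusion is FusionKind.EARLY:
            fused = adapted * 0.5  # other modality's masked mean is zero
            return model.experts["expert"].linear(relu(fused)).data
        else:  # MOE
            from ._autodiff import softmax as _sm
            w = _sm(model.routers[bag.modality](adapted), axis=-1).data  # (N, 2)
            e0 = model.experts["expert0"].linear(relu(adapted)).data
            e1 = model.experts["expert1"].linear(relu(adapted)).data
            own = w[:, :1] * e0 + w[:, 1:] * e1
        d_c = cfg.d_c
        out = np.tile(zero, (own.shape[0], 1))
        slot = 0 if bag.modality is Modality.WSI else 1
        out[:, slot * d_c:(slot + 1) * d_c] = own
        return out
    rows = []
    for i in range(bag.n_tokens):
        single = EmbeddingBag(bag.case_id, bag.modality, bag.tokens[i:i + 1],
                              bag.label, n_slices=1)
        rows.append(penultimate_features(model, **{kw_key: single}, mode=mode))
    return np.asarray(rows)


def extreme_feature_instances(model: FusionModel, bags, feature_idx: int, k: int):
    """Top-k and bottom-k (case_id, token_idx, value) of one penultimate feature,
    with per-token values computed on singleton token bags."""
    records = []
    for bag in bags:
        vals = _penultimate_rows(model, bag)
        if feature_idx >= vals.shape[1]:
            raise ValueError(f"feature_idx {feature_idx} out of range ({vals.shape[1]})")
        for i in range(vals.shape[0]):
            records.append((bag.case_id, i, float(vals[i, feature_idx])))
    if k > len(records):
        warnings.warn(f"k={k} exceeds total token count {len(records)}; truncated",
                      stacklevel=2)
        k = len(records)
    records.sort(key=lambda r: r[2])
    bottom = records[:k]
    top = list(reversed(records[-k:]))
    return top, bottom
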