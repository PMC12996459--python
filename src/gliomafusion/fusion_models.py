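"""Adapters, experts, and the three multimodal fusion architectures.

Every model is built from the same parts: a per-modality *adapter* (one linear
layer projecting foundation-model tokens to a shared width d_c), an *expert*
that condenses a token bag to a single representation, and a classification
head (2-layer MLP with one ReLU).  Two expert designs are provided:

* patch-mean — feature-wise mean over tokens, ReLU, linear layer (so a full
  unimodal model is a 4-layer MLP);
* patch-sequence — a stack of width-preserving gated sequence blocks (token
  mixing through a global-context channel with a SiLU gate and residual
  connection) followed by attention pooling, which returns both the pooled
  representation and the per-token attention weights.

Fusion variants:

* LATE  — one expert per modality, representations concatenated into a joint
  head; two additional heads give unimodal predictions.
* EARLY — adapted token sequences concatenated along the token axis into one
  (N_H + N_M) x d_c sequence consumed by a single expert (patch-mean models
  instead mean-pool the two adapted means before the nonlinearity).
* MOE   — both modalities are processed by both experts; a per-modality soft
  router (softmax over the two experts, computed on the mean adapted token)
  weights the expert outputs.  During warmup the routing is pinned one-hot so
  each expert specializes on one modality.

A masked (absent) modality is represented by a single all-zero token in the
adapted space, so unimodal-mode outputs are invariant to whatever content the
missing modality carries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, log_softmax, relu, silu, softmax
from .embedding_store import CANONICAL_DIM, EmbeddingBag, Modality

__all__ = [
    "FusionKind", "ExpertKind", "Mode", "ModelConfig", "ModelOutput",
    "ConfigError", "ModelInputError",
    "Linear", "Head", "PatchMeanExpert", "PatchSequenceExpert", "AttentionPool", "SeqBlock",
    "FusionModel", "build_model", "count_parameters", "save_model", "load_model",
]


class ConfigError(ValueError):
    pass


class ModelInputError(ValueError):
    pass


class FusionKind(str, Enum):
    UNIMODAL_WSI = "UNIMODAL_WSI"
    UNIMODAL_MRI = "UNIMODAL_MRI"
    LATE = "LATE"
    EARLY = "EARLY"
    MOE = "MOE"


class ExpertKind(str, Enum):
    PATCH_MEAN = "PATCH_MEAN"
    PATCH_SEQUENCE = "PATCH_SEQUENCE"


class Mode(str, Enum):
    MM = "MM"
    WSI_ONLY = "WSI_ONLY"
    MRI_ONLY = "MRI_ONLY"


_UNIMODAL = {FusionKind.UNIMODAL_WSI, FusionKind.UNIMODAL_MRI}

# Sequence-block inner widths tuned once per architecture family so that every
# patch-sequence model's trainable-parameter total lands in the 900k-950k band
# at the canonical input widths (1536/768).
_TUNED_INNER = {
    (FusionKind.UNIMODAL_WSI, 64): 110,
    (FusionKind.UNIMODAL_MRI, 64): 115,
    (FusionKind.LATE, 64): 105,
    (FusionKind.EARLY, 64): 173,
    (FusionKind.MOE, 16): 166,
}


@dataclass
class ModelConfig:
    fusion: FusionKind = FusionKind.MOE
    expert_kind: ExpertKind = ExpertKind.PATCH_MEAN
    d_c: int | None = None          # shared width; 64 empirically, 16 for MoE
    n_blocks: int | None = None     # 24 unimodal, 12 per expert multimodal
    d_inner: int | None = None      # sequence-block inner width (tuned per family)
    dropout: float = 0.5
    n_classes: int = 3
    d_wsi: int = CANONICAL_DIM["WSI"]
    d_mri: int = CANONICAL_DIM["MRI"]

    def __post_init__(self):
        self.fusion = FusionKind(self.fusion)
        self.expert_kind = ExpertKind(self.expert_kind)
        if self.d_c is None:
            self.d_c = 16 if self.fusion is FusionKind.MOE else 64
        if self.n_blocks is None:
            self.n_blocks = 24 if self.fusion in _UNIMODAL else 12
        if self.d_inner is None:
            self.d_inner = _TUNED_INNER.get((self.fusion, self.d_c), max(8, 2 * self.d_c))
        if self.d_c < 2:
            raise ConfigError("d_c must be >= 2")
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if min(self.d_wsi, self.d_mri, self.d_inner) < 1:
            raise ConfigError("widths must be positive")

    def to_dict(self) -> dict:
        return {
            "fusion": self.fusion.value, "expert_kind": self.expert_kind.value,
            "d_c": self.d_c, "n_blocks": self.n_blocks, "d_inner": self.d_inner,
            "dropout": self.dropout, "n_classes": self.n_classes,
            "d_wsi": self.d_wsi, "d_mri": self.d_mri,
        }


@dataclass
class ModelOutput:
    """Numpy view of one forward pass.

    ``penultimate`` is the vector entering the joint classification head.
    ``router_weights`` has one row per modality slot (WSI, MRI), each a softmax
    over the two experts.  For EARLY patch-sequence models the fused-sequence
    attention is split at the modality boundary and renormalized per modality.
    """

    mode: Mode
    available_heads: frozenset
    penultimate: np.ndarray
    logits_mm: np.ndarray | None = None
    logits_wsi: np.ndarray | None = None
    logits_mri: np.ndarray | None = None
    attention_wsi: np.ndarray | None = None
    attention_mri: np.ndarray | None = None
    router_weights: np.ndarray | None = None

    def logits(self, head: str) -> np.ndarray:
        return {"mm": self.logits_mm, "wsi": self.logits_wsi, "mri": self.logits_mri}[head]

    def primary_head(self) -> str:
        if "mm" in self.available_heads:
            return "mm"
        return next(iter(self.available_heads))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor.param(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.b = Tensor.param(np.zeros(d_out))
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_in:
            raise ModelInputError(f"expected width {self.d_in}, got {x.shape[-1]}")
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class Head:
    """Classification head: linear -> ReLU -> (dropout) -> linear."""

    def __init__(self, d_in: int, d_hidden: int, n_classes: int, dropout: float,
                 rng: np.random.Generator):
        self.l1 = Linear(d_in, d_hidden, rng)
        self.l2 = Linear(d_hidden, n_classes, rng)
        self.dropout = dropout

    def __call__(self, x: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = relu(self.l1(x))
        if train and self.dropout > 0.0 and rng is not None:
            keep = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = h * Tensor(keep)
        return self.l2(h)

    @property
    def params(self):
        return self.l1.params + self.l2.params


class PatchMeanExpert:
    """Feature-wise mean over tokens, ReLU, linear layer."""

    def __init__(self, d_c: int, rng: np.random.Generator):
        self.linear = Linear(d_c, d_c, rng)

    def __call__(self, adapted: Tensor) -> tuple[Tensor, None]:
        return self.from_mean(adapted.mean(axis=0)), None

    def from_mean(self, mean_vec: Tensor) -> Tensor:
        return self.linear(relu(mean_vec))

    @property
    def params(self):
        return self.linear.params


class SeqBlock:
    """Width-preserving gated sequence block with global-context token mixing.

    X -> X + W_out( silu(G) * (U + W_ctx(mean_rows(U))) ), where [U, G] is a
    2*d_inner projection of X.  The mean-token channel carries information
    across the sequence; the SiLU gate makes the mixing input-dependent.
    """

    def __init__(self, d_c: int, d_inner: int, rng: np.random.Generator):
        self.in_proj = Linear(d_c, 2 * d_inner, rng)
        self.ctx = Linear(d_inner, d_inner, rng)
        self.out = Linear(d_inner, d_c, rng)
        self.d_inner = d_inner

    def __call__(self, x: Tensor) -> Tensor:
        h = self.in_proj(x)
        u = h[:, : self.d_inner]
        g = h[:, self.d_inner:]
        mixed = u + self.ctx(u.mean(axis=0, keepdims=True))
        return x + self.out(silu(g) * mixed)

    @property
    def params(self):
        return self.in_proj.params + self.ctx.params + self.out.params


class AttentionPool:
    """Learned single-score attention pooling: weights = softmax(score(token))."""

    def __init__(self, d_c: int, rng: np.random.Generator):
        self.score = Linear(d_c, 1, rng)

    def __call__(self, tokens: Tensor) -> tuple[Tensor, Tensor]:
        s = self.score(tokens)                       # (N, 1)
        w = softmax(s, axis=0)
        pooled = (w * tokens).sum(axis=0)            # convex combination of rows
        return pooled, w.reshape(-1)

    @property
    def params(self):
        return self.score.params


class PatchSequenceExpert:
    """n sequence blocks followed by attention pooling."""

    def __init__(self, d_c: int, n_blocks: int, d_inner: int, rng: np.random.Generator):
        self.blocks = [SeqBlock(d_c, d_inner, rng) for _ in range(n_blocks)]
        self.pool = AttentionPool(d_c, rng)

    def __call__(self, adapted: Tensor) -> tuple[Tensor, Tensor]:
        x = adapted
        for blk in self.blocks:
            x = blk(x)
        return self.pool(x)

    @property
    def params(self):
        out = []
        for blk in self.blocks:
            out.extend(blk.params)
        return out + self.pool.params


# ---------------------------------------------------------------------------
# The fusion model
# ---------------------------------------------------------------------------

def _make_expert(cfg: ModelConfig, rng) -> PatchMeanExpert | PatchSequenceExpert:
    if cfg.expert_kind is ExpertKind.PATCH_MEAN:
        return PatchMeanExpert(cfg.d_c, rng)
    return PatchSequenceExpert(cfg.d_c, cfg.n_blocks, cfg.d_inner, rng)


class FusionModel:
    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
        cfg = config
        d_c, nc, drop = cfg.d_c, cfg.n_classes, cfg.dropout
        self.adapters: dict[Modality, Linear] = {}
        self.experts: dict[str, PatchMeanExpert | PatchSequenceExpert] = {}
        self.heads: dict[str, Head] = {}
        self.routers: dict[Modality, Linear] = {}

        if cfg.fusion is FusionKind.UNIMODAL_WSI:
            self.adapters[Modality.WSI] = Linear(cfg.d_wsi, d_c, rng)
            self.experts["expert"] = _make_expert(cfg, rng)
            self.heads["wsi"] = Head(d_c, d_c, nc, drop, rng)
        elif cfg.fusion is FusionKind.UNIMODAL_MRI:
            self.adapters[Modality.MRI] = Linear(cfg.d_mri, d_c, rng)
            self.experts["expert"] = _make_expert(cfg, rng)
            self.heads["mri"] = Head(d_c, d_c, nc, drop, rng)
        else:
            self.adapters[Modality.WSI] = Linear(cfg.d_wsi, d_c, rng)
            self.adapters[Modality.MRI] = Linear(cfg.d_mri, d_c, rng)
            if cfg.fusion is FusionKind.LATE:
                self.experts["WSI"] = _make_expert(cfg, rng)
                self.experts["MRI"] = _make_expert(cfg, rng)
                self.heads["mm"] = Head(2 * d_c, d_c, nc, drop, rng)
                self.heads["wsi"] = Head(d_c, d_c, nc, drop, rng)
                self.heads["mri"] = Head(d_c, d_c, nc, drop, rng)
            elif cfg.fusion is FusionKind.EARLY:
                self.experts["expert"] = _make_expert(cfg, rng)
                self.heads["mm"] = Head(d_c, d_c, nc, drop, rng)
            elif cfg.fusion is FusionKind.MOE:
                self.experts["expert0"] = _make_expert(cfg, rng)
                self.experts["expert1"] = _make_expert(cfg, rng)
                self.routers[Modality.WSI] = Linear(d_c, 2, rng)
                self.routers[Modality.MRI] = Linear(d_c, 2, rng)
                self.heads["mm"] = Head(2 * d_c, d_c, nc, drop, rng)

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out = []
        for a in self.adapters.values():
            out.extend(a.params)
        for e in self.experts.values():
            out.extend(e.params)
        for r in self.routers.values():
            out.extend(r.params)
        for h in self.heads.values():
            out.extend(h.params)
        return out

    # -- pieces -------------------------------------------------------------
    def adapt(self, tokens: np.ndarray | Tensor, modality: Modality) -> Tensor:
        """Project raw modality tokens to the shared width d_c (row-wise affine)."""
        modality = Modality(modality)
        if modality not in self.adapters:
            raise ModelInputError(f"model has no {modality.value} adapter")
        t = tokens if isinstance(tokens, Tensor) else Tensor(np.asarray(tokens, dtype=np.float64))
        return self.adapters[modality](t)

    def _zero_token(self) -> Tensor:
        return Tensor(np.zeros((1, self.config.d_c)))

    @staticmethod
    def _required(mode: Mode) -> set[Modality]:
        return {
            Mode.MM: {Modality.WSI, Modality.MRI},
            Mode.WSI_ONLY: {Modality.WSI},
            Mode.MRI_ONLY: {Modality.MRI},
        }[Mode(mode)]

    def _check_inputs(self, wsi, mri, mode: Mode):
        need = self._required(mode)
        if Modality.WSI in need and wsi is None:
            raise ModelInputError(f"mode {mode.value} requires a WSI bag")
        if Modality.MRI in need and mri is None:
            raise ModelInputError(f"mode {mode.value} requires an MRI bag")

    @staticmethod
    def _tokens(bag) -> np.ndarray:
        return bag.tokens if isinstance(bag, EmbeddingBag) else np.asarray(bag)

    # -- forward ------------------------------------------------------------
    def forward(self, wsi=None, mri=None, mode: Mode = Mode.MM, train: bool = False,
                rng: np.random.Generator | None = None, warmup: bool = False) -> ModelOutput:
        """Numpy-facing forward pass; see :meth:`forward_tensors` for the graph."""
        t = self.forward_tensors(wsi, mri, mode, train=train, rng=rng, warmup=warmup)
        return _to_output(t)

    def forward_tensors(self, wsi=None, mri=None, mode: Mode = Mode.MM, train: bool = False,
                        rng: np.random.Generator | None = None, warmup: bool = False) -> dict:
        mode = Mode(mode)
        cfg = self.config
        if cfg.fusion in _UNIMODAL:
            return self._forward_unimodal(wsi, mri, mode, train, rng)
        self._check_inputs(wsi, mri, mode)
        present = self._required(mode)
        adapted: dict[Modality, Tensor] = {}
        for modality, bag in ((Modality.WSI, wsi), (Modality.MRI, mri)):
            if modality in present:
                adapted[modality] = self.adapt(self._tokens(bag), modality)
            else:
                adapted[modality] = self._zero_token()  # masked: content never touched
        if cfg.fusion is FusionKind.LATE:
            return self._forward_late(adapted, present, mode, train, rng)
        if cfg.fusion is FusionKind.EARLY:
            return self._forward_early(adapted, present, mode, train, rng)
        return self._forward_moe(adapted, present, mode, train, rng, warmup)

    def _forward_unimodal(self, wsi, mri, mode, train, rng) -> dict:
        cfg = self.config
        own = Modality.WSI if cfg.fusion is FusionKind.UNIMODAL_WSI else Modality.MRI
        own_mode = Mode.WSI_ONLY if own is Modality.WSI else Mode.MRI_ONLY
        if mode is Mode.MM:
            mode = own_mode
        if mode is not own_mode:
            raise ModelInputError(f"{cfg.fusion.value} model cannot run in mode {mode.value}")
        bag = wsi if own is Modality.WSI else mri
        if bag is None:
            raise ModelInputError(f"mode {mode.value} requires a {own.value} bag")
        a = self.adapt(self._tokens(bag), own)
        repr_, att = self.experts["expert"](a)
        head_name = "wsi" if own is Modality.WSI else "mri"
        logits = self.heads[head_name](repr_, train=train, rng=rng)
        out = {
            "mode": mode, "available_heads": frozenset({head_name}),
            "penultimate": repr_, f"logits_{head_name}": logits,
        }
        if att is not None:
            out[f"attention_{head_name.lower()}"] = att
        return out

    def _forward_late(self, adapted, present, mode, train, rng) -> dict:
        reprs, atts = {}, {}
        for modality in (Modality.WSI, Modality.MRI):
            key = modality.value
            reprs[modality], atts[modality] = self.experts[key](adapted[modality])
        pen = concat([reprs[Modality.WSI].reshape(1, -1),
                      reprs[Modality.MRI].reshape(1, -1)], axis=1).reshape(-1)
        out = {"mode": mode, "penultimate": pen,
               "logits_mm": self.heads["mm"](pen, train=train, rng=rng)}
        heads = {"mm"}
        if Modality.WSI in present:
            out["logits_wsi"] = self.heads["wsi"](reprs[Modality.WSI], train=train, rng=rng)
            heads.add("wsi")
        if Modality.MRI in present:
            out["logits_mri"] = self.heads["mri"](reprs[Modality.MRI], train=train, rng=rng)
            heads.add("mri")
        for modality in present:
            if atts[modality] is not None:
                out[f"attention_{modality.value.lower()}"] = atts[modality]
        out["available_heads"] = frozenset(heads)
        return out

    def _forward_early(self, adapted, present, mode, train, rng) -> dict:
        cfg = self.config
        out = {"mode": mode, "available_heads": frozenset({"mm"})}
        if cfg.expert_kind is ExpertKind.PATCH_MEAN:
            means = [adapted[m].mean(axis=0) for m in (Modality.WSI, Modality.MRI)]
            fused = (means[0] + means[1]) * 0.5      # mean-pool the modality means
            repr_ = self.experts["expert"].from_mean(fused)
        else:
            n_wsi = adapted[Modality.WSI].shape[0]
            seq = concat([adapted[Modality.WSI], adapted[Modality.MRI]], axis=0)
            repr_, att = self.experts["expert"](seq)
            if Modality.WSI in present:
                w = att[:n_wsi]
                out["attention_wsi"] = w / w.sum()
            if Modality.MRI in present:
                w = att[n_wsi:]
                out["attention_mri"] = w / w.sum()
        out["penultimate"] = repr_
        out["logits_mm"] = self.heads["mm"](repr_, train=train, rng=rng)
        return out

    def _forward_moe(self, adapted, present, mode, train, rng, warmup) -> dict:
        pinned = {Modality.WSI: np.array([1.0, 0.0]), Modality.MRI: np.array([0.0, 1.0])}
        reprs, router_rows, atts = {}, [], {}
        for modality in (Modality.WSI, Modality.MRI):
            a = adapted[modality]
            if warmup:
                w = Tensor(pinned[modality])  # routing disabled: constant one-hot
            else:
                w = softmax(self.routers[modality](a.mean(axis=0)), axis=-1)
            r0, att0 = self.experts["expert0"](a)
            r1, att1 = self.experts["expert1"](a)
            reprs[modality] = w[0] * r0 + w[1] * r1
            router_rows.append(w.reshape(1, -1))
            if att0 is not None and modality in present:
                atts[modality] = w[0] * att0 + w[1] * att1
        pen = concat([reprs[Modality.WSI].reshape(1, -1),
                      reprs[Modality.MRI].reshape(1, -1)], axis=1).reshape(-1)
        out = {
            "mode": mode, "available_heads": frozenset({"mm"}),
            "penultimate": pen,
            "logits_mm": self.heads["mm"](pen, train=train, rng=rng),
            "router_weights": concat(router_rows, axis=0),
        }
        for modality, att in atts.items():
            out[f"attention_{modality.value.lower()}"] = att
        return out

    # -- batched patch-mean path ---------------------------------------------
    def forward_mean_batch(self, wsi_means=None, mri_means=None, mode: Mode = Mode.MM,
                           train: bool = False, rng: np.random.Generator | None = None,
                           warmup: bool = False) -> dict:
        """Batched forward for patch-mean models from per-case token means.

        Because the adapter is affine and the patch-mean expert consumes only
        the token mean, a case is fully represented by its (subsampled) token
        mean; stacking B cases into a (B, d) matrix gives bitwise the same
        logits as B independent forward passes.  Only valid for PATCH_MEAN
        experts.
        """
        cfg = self.config
        if cfg.expert_kind is not ExpertKind.PATCH_MEAN:
            raise ModelInputError("forward_mean_batch requires patch-mean experts")
        mode = Mode(mode)
        B = (np.asarray(wsi_means).shape[0] if wsi_means is not None
             else np.asarray(mri_means).shape[0])
        if cfg.fusion in _UNIMODAL:
            own = Modality.WSI if cfg.fusion is FusionKind.UNIMODAL_WSI else Modality.MRI
            means = wsi_means if own is Modality.WSI else mri_means
            if means is None:
                raise ModelInputError(f"{cfg.fusion.value} requires {own.value} means")
            a = self.adapt(np.asarray(means), own)
            repr_ = self.experts["expert"].from_mean(a)
            head = "wsi" if own is Modality.WSI else "mri"
            return {"mode": mode, "available_heads": frozenset({head}),
                    "penultimate": repr_,
                    f"logits_{head}": self.heads[head](repr_, train=train, rng=rng)}
        present = self._required(mode)
        self._check_inputs(wsi_means if Modality.WSI in present else True,
                           mri_means if Modality.MRI in present else True, mode)
        adapted: dict[Modality, Tensor] = {}
        for modality, means in ((Modality.WSI, wsi_means), (Modality.MRI, mri_means)):
            if modality in present:
                adapted[modality] = self.adapt(np.asarray(means), modality)
            else:
                adapted[modality] = Tensor(np.zeros((B, cfg.d_c)))  # masked slot
        if cfg.fusion is FusionKind.EARLY:
            fused = (adapted[Modality.WSI] + adapted[Modality.MRI]) * 0.5
            repr_ = self.experts["expert"].from_mean(fused)
            return {"mode": mode, "available_heads": frozenset({"mm"}),
                    "penultimate": repr_,
                    "logits_mm": self.heads["mm"](repr_, train=train, rng=rng)}
        if cfg.fusion is FusionKind.LATE:
            reprs = {m: self.experts[m.value].from_mean(adapted[m])
                     for m in (Modality.WSI, Modality.MRI)}
            pen = concat([reprs[Modality.WSI], reprs[Modality.MRI]], axis=1)
            out = {"mode": mode, "penultimate": pen,
                   "logits_mm": self.heads["mm"](pen, train=train, rng=rng)}
            heads = {"mm"}
            for modality in present:
                key = modality.value.lower()
                out[f"logits_{key}"] = self.heads[key](reprs[modality], train=train, rng=rng)
                heads.add(key)
            out["available_heads"] = frozenset(heads)
            return out
        # MOE
        pinned = {Modality.WSI: np.array([[1.0, 0.0]]), Modality.MRI: np.array([[0.0, 1.0]])}
        reprs = {}
        routers = {}
        for modality in (Modality.WSI, Modality.MRI):
            a = adapted[modality]
            if warmup:
                w = Tensor(np.repeat(pinned[modality], B, axis=0))
            else:
                w = softmax(self.routers[modality](a), axis=-1)
            r0 = self.experts["expert0"].from_mean(a)
            r1 = self.experts["expert1"].from_mean(a)
            reprs[modality] = w[:, 0:1] * r0 + w[:, 1:2] * r1
            routers[modality] = w
        pen = concat([reprs[Modality.WSI], reprs[Modality.MRI]], axis=1)
        return {"mode": mode, "available_heads": frozenset({"mm"}),
                "penultimate": pen,
                "logits_mm": self.heads["mm"](pen, train=train, rng=rng),
                "router_weights": routers}

    # -- inference helpers ---------------------------------------------------
    def predict_proba(self, wsi=None, mri=None, mode: Mode = Mode.MM,
                      joint_strategy: str = "head") -> np.ndarray:
        """Class probabilities from the primary head.

        ``joint_strategy='ensemble'`` (LATE models trained in the unpaired
        alternating regime, where the joint head is untrainable) averages the
        unimodal heads' probabilities instead of using the joint head.
        """
        out = self.forward(wsi=wsi, mri=mri, mode=mode)
        if joint_strategy == "ensemble" and self.config.fusion is FusionKind.LATE \
                and Mode(mode) is Mode.MM:
            probs = [_softmax_np(out.logits_wsi), _softmax_np(out.logits_mri)]
            return np.mean(probs, axis=0)
        return _softmax_np(out.logits(out.primary_head()))


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _to_output(t: dict) -> ModelOutput:
    def arr(key):
        v = t.get(key)
        return None if v is None else np.array(v.data, copy=True)

    return ModelOutput(
        mode=t["mode"], available_heads=t["available_heads"],
        penultimate=np.array(t["penultimate"].data, copy=True),
        logits_mm=arr("logits_mm"), logits_wsi=arr("logits_wsi"), logits_mri=arr("logits_mri"),
        attention_wsi=arr("attention_wsi"), attention_mri=arr("attention_mri"),
        router_weights=arr("router_weights"),
    )


def build_model(config: ModelConfig, seed: int = 0) -> FusionModel:
    return FusionModel(config, seed=seed)


def count_parameters(model: FusionModel) -> int:
    """Number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def save_model(model: FusionModel, path: str | Path) -> Path:
    """Serialize weights to ``<path>`` (.npz) with a JSON config sidecar."""
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=1))
    return path


def load_model(path: str | Path) -> FusionModel:
    path = Path(path)
    cfg = ModelConfig(**json.loads(path.with_suffix(path.suffix + ".json").read_text()))
    model = FusionModel(cfg)
    with np.load(path) as z:
        params = model.parameters()
        if len(z.files) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for i, p in enumerate(params):
            data = z[f"p{i}"]
            if data.shape != p.data.shape:
                raise ValueError("checkpoint does not match model architecture")
            p.data = data.astype(np.float64)
    return model
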