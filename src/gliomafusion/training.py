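"""Losses, permutation training, MoE warmup, early stopping, cross-validation.

Models are optimized with Adam on the sum of cross-entropy and a *soft MCC*
loss: the batch's predicted probabilities are accumulated into a soft
confusion matrix C_kj = sum_{i: y_i=k} p_ij, the multiclass Matthews
correlation is computed from C in covariance form, and the loss is
1 - MCC_soft.  At one-hot probabilities this equals 1 - hard MCC exactly; a
degenerate (zero) denominator maps to MCC_soft = 0, i.e. loss 1.

Multimodal models are trained on every input-availability permutation of each
pair (MM, WSI-only, MRI-only, via modality masking), so their unimodal
pathways are trained alongside the joint one.  The mixture-of-experts model
first runs a unimodal warmup with routing pinned one-hot (each expert sees one
modality), then trains with routing enabled for the remaining epoch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Adam, Tensor, log_softmax, softmax, stack_rows
from .embedding_store import (
    CohortManifest, FoldAssignment, Modality, make_folds, subsample_patches,
)
from .fusion_models import (
    ConfigError, ExpertKind, FusionKind, FusionModel, Mode, ModelConfig, build_model,
)
from .metrics import ConfusionMatrix, accuracy, mcc
from .pair_sampling import PairingStrategy, alternating_batches, epoch_pairs
from .synthetic_cohort import CLASSES

__all__ = [
    "TrainConfig", "TrainReport", "soft_mcc_loss", "total_loss",
    "train", "moe_warmup_train", "cross_validate", "evaluate",
]

_UNIMODAL = {FusionKind.UNIMODAL_WSI, FusionKind.UNIMODAL_MRI}


@dataclass
class TrainConfig:
    """Training conditions; defaults follow the reference protocol (batch 32,
    lr 5e-5, <=20 epochs with early stopping, weight decay 0.01, dropout 0.5,
    2000 patches subsampled per WSI case per epoch)."""

    lr: float = 5e-5
    batch_size: int = 32
    max_epochs: int = 20
    weight_decay: float = 0.01
    dropout: float = 0.5
    warmup_epochs: int = 5       # MoE only
    patience: int = 5
    lambda_mcc: float = 1.0
    patches_per_case: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("lr, batch_size and max_epochs must be positive")
        if self.lambda_mcc < 0:
            raise ConfigError("lambda_mcc must be >= 0")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")


@dataclass
class TrainReport:
    epoch_train_losses: list = field(default_factory=list)
    epoch_val_mcc: list = field(default_factory=list)
    epoch_val_acc: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    best_val_mcc: float = float("-inf")
    seed: int = 0
    joint_strategy: str = "head"   # 'ensemble' for LATE trained unpaired
    warmup_epochs_run: int = 0
    warmup_router_rows: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "epoch_train_losses": [float(x) for x in self.epoch_train_losses],
            "epoch_val_mcc": [float(x) for x in self.epoch_val_mcc],
            "epoch_val_acc": [float(x) for x in self.epoch_val_acc],
            "stopped_epoch": self.stopped_epoch, "best_epoch": self.best_epoch,
            "best_val_mcc": float(self.best_val_mcc), "seed": self.seed,
            "joint_strategy": self.joint_strategy,
            "warmup_epochs_run": self.warmup_epochs_run,
        }


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def soft_mcc_loss(probs, labels, n_classes: int = 3):
    """1 - soft multiclass MCC of a batch of probability rows.

    Differentiable when ``probs`` is an autodiff tensor; also accepts a plain
    array (rows validated to sum to 1) and returns a float.
    """
    labels = np.asarray(labels, dtype=np.int64)
    as_array = not isinstance(probs, Tensor)
    p = np.asarray(probs.data if isinstance(probs, Tensor) else probs, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != labels.shape[0]:
        raise ValueError("probs must be (B, n_classes) aligned with labels")
    if np.abs(p.sum(axis=1) - 1.0).max() > 1e-5:
        raise ValueError("probability rows must sum to 1")
    onehot = np.zeros((labels.shape[0], n_classes))
    onehot[np.arange(labels.shape[0]), labels] = 1.0
    pt = probs if isinstance(probs, Tensor) else Tensor(p)
    C = Tensor(onehot.T) @ pt                       # soft confusion, rows = true
    s = float(labels.shape[0])
    trace = (C * Tensor(np.eye(n_classes))).sum()
    t = C.sum(axis=1)
    q = C.sum(axis=0)
    cov = trace * s - (t * q).sum()
    d1 = s**2 - (q * q).sum().data
    d2 = s**2 - (t * t).sum().data
    if d1 <= 1e-12 or d2 <= 1e-12:
        loss = Tensor(1.0)                          # zero-denominator convention: MCC = 0
    else:
        denom = ((s**2 - (q * q).sum()) * (s**2 - (t * t).sum())) ** 0.5
        loss = 1.0 - cov / denom
    return float(loss.data) if as_array else loss


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels, dtype=np.int64)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(labels.shape[0]), labels] = 1.0
    return -(Tensor(onehot) * log_softmax(logits, axis=-1)).sum() * (1.0 / labels.shape[0])


def total_loss(outputs, labels, lambda_mcc: float = 1.0, heads: set | None = None) -> Tensor:
    """Mean over available heads of [cross-entropy + lambda * soft-MCC loss].

    ``outputs`` is one forward-tensors dict or a list of them (one per case of
    a batch); per-head logits are stacked across the batch.  ``heads`` can
    restrict which heads contribute (e.g. excluding an untrainable joint head).
    """
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    batched = isinstance(outputs, dict)
    if batched:
        first = outputs
    else:
        if len(outputs) != labels.shape[0]:
            raise ValueError("one output per label required")
        first = outputs[0]
    available = set(first["available_heads"])
    if heads is not None:
        available &= set(heads)
    if not available:
        raise ValueError("no heads available for the loss")
    terms = []
    for head in sorted(available):
        if batched:
            logits = outputs[f"logits_{head}"]
            if logits.ndim == 1:
                logits = logits.reshape(1, -1)
            if logits.shape[0] != labels.shape[0]:
                raise ValueError("batched logits must be (B, n_classes)")
        else:
            logits = stack_rows([o[f"logits_{head}"] for o in outputs])
        term = _cross_entropy(logits, labels)
        if lambda_mcc > 0:
            term = term + lambda_mcc * soft_mcc_loss(softmax(logits, axis=-1), labels,
                                                     n_classes=logits.shape[1])
        terms.append(term)
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _chunks(seq, size):
    return [seq[i:i + size] for i in range(0, len(seq), size)]

def _get_bag(bags, cid, modality, config, sub_rng):
    bag = bags[(cid, modality)]
    if modality is Modality.WSI and config.patches_per_case:
        bag = subsample_patches(bag, config.patches_per_case, int(sub_rng.integers(2**31)))
    return bag


def _unimodal_epoch_batches(manifest, modality, batch_size, epoch, seed):
    cases = manifest.cases_with_modality(modality)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(epoch), 9]))
    order = [cases[i] for i in rng.permutation(len(cases))]
    return [(modality, chunk) for chunk in _chunks(order, batch_size)]


def evaluate(model: FusionModel, manifest: CohortManifest, bags, case_ids,
             joint_strategy: str = "head") -> dict:
    """Predict each case in the mode its available modalities allow and score."""
    labels = manifest.case_labels()
    y_true, y_pred, scores = [], [], []
    own = {FusionKind.UNIMODAL_WSI: Modality.WSI,
           FusionKind.UNIMODAL_MRI: Modality.MRI}.get(model.config.fusion)
    for cid in case_ids:
        mods = manifest.modalities_of(cid)
        if own is not None:
            if own not in mods:
                continue
            mode = Mode.WSI_ONLY if own is Modality.WSI else Mode.MRI_ONLY
        elif mods == {Modality.WSI, Modality.MRI}:
            mode = Mode.MM
        elif mods == {Modality.WSI}:
            mode = Mode.WSI_ONLY
        else:
            mode = Mode.MRI_ONLY
        wsi = bags.get((cid, Modality.WSI)) if Modality.WSI in mods else None
        mri = bags.get((cid, Modality.MRI)) if Modality.MRI in mods else None
        probs = model.predict_proba(wsi=wsi, mri=mri, mode=mode, joint_strategy=joint_strategy)
        y_true.append(CLASSES.index(labels[cid]))
        y_pred.append(int(np.argmax(probs)))
        scores.append(probs)
    if not y_true:
        raise ValueError("no evaluable cases")
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    return {"mcc": mcc(cm), "accuracy": accuracy(cm), "n": len(y_true),
            "y_true": np.asarray(y_true), "y_pred": np.asarray(y_pred),
            "scores": np.asarray(scores)}


def _validation_scores(model: FusionModel, manifest, bags, val_cases,
                       joint_strategy: str) -> tuple[float, float]:
    """Monitored validation (MCC, accuracy).

    Unimodal models score their own modality.  Multimodal models are scored in
    every input-availability permutation the validation cases support and the
    metrics are averaged — the natural counterpart of permutation training, so
    early stopping favors epochs where all pathways perform.
    """
    if model.config.fusion in _UNIMODAL:
        val = evaluate(model, manifest, bags, val_cases, joint_strategy=joint_strategy)
        return val["mcc"], val["accuracy"]
    labels = manifest.case_labels()
    mccs, accs = [], []
    for mode in (Mode.MM, Mode.WSI_ONLY, Mode.MRI_ONLY):
        need = FusionModel._required(mode)
        cases = [c for c in val_cases if need <= manifest.modalities_of(c)]
        if not cases:
            continue
        y_true, y_pred = [], []
        for cid in cases:
            wsi = bags.get((cid, Modality.WSI)) if Modality.WSI in need else None
            mri = bags.get((cid, Modality.MRI)) if Modality.MRI in need else None
            probs = model.predict_proba(wsi=wsi, mri=mri, mode=mode,
                                        joint_strategy=joint_strategy)
            y_true.append(CLASSES.index(labels[cid]))
            y_pred.append(int(np.argmax(probs)))
        cm = ConfusionMatrix.from_predictions(y_true, y_pred)
        mccs.append(mcc(cm))
        accs.append(accuracy(cm))
    if not mccs:
        raise ValueError("no evaluable validation cases")
    return float(np.mean(mccs)), float(np.mean(accs))


def _modes_for(model: FusionModel, strategy: PairingStrategy) -> list[Mode]:
    if model.config.fusion in _UNIMODAL:
        return [Mode.WSI_ONLY if model.config.fusion is FusionKind.UNIMODAL_WSI
                else Mode.MRI_ONLY]
    return [Mode.MM, Mode.WSI_ONLY, Mode.MRI_ONLY]


def train(model: FusionModel, manifest: CohortManifest, bags,
          folds: FoldAssignment, fold_idx: int, strategy: PairingStrategy,
          config: TrainConfig, _warmup: bool = False,
          _epoch_range: tuple[int, int] | None = None,
          _report: TrainReport | None = None,
          _optimizer: Adam | None = None) -> TrainReport:
    """Train ``model`` on the training split of ``fold_idx`` under ``strategy``.

    Per epoch: pairs (or alternating unimodal batches) are re-sampled, WSI bags
    are subsampled to ``patches_per_case`` tokens, multimodal models are
    optimized on all input permutations, and the held-out fold is scored; stops
    early when validation MCC fails to improve for ``patience`` epochs.
    Deterministic for a fixed ``config.seed``.
    """
    strategy = PairingStrategy(strategy)
    train_cases, val_cases = folds.train_val_split(fold_idx)
    if not train_cases or not val_cases:
        raise ValueError("empty training or validation fold")
    train_manifest = manifest.subset(train_cases)
    labels = manifest.case_labels()
    opt = _optimizer or Adam(model.parameters(), lr=config.lr,
                             weight_decay=config.weight_decay)
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    sub_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    report = _report or TrainReport(seed=config.seed)
    is_late = model.config.fusion is FusionKind.LATE
    if is_late and strategy is PairingStrategy.UNPAIRED_ALTERNATING:
        report.joint_strategy = "ensemble"   # joint head untrainable without pairs
    lo, hi = _epoch_range or (0, config.max_epochs)
    fails = 0
    best_params = [p.data.copy() for p in model.parameters()]
    use_batched = model.config.expert_kind is ExpertKind.PATCH_MEAN

    def forward_cases(wsi_ids, mri_ids, ys, mode):
        """One loss-ready forward for a batch; uses the exact batched
        token-mean path for patch-mean experts, per-case graphs otherwise."""
        if use_batched:
            wsi_means = mri_means = None
            if wsi_ids is not None:
                wsi_means = np.stack(
                    [_get_bag(bags, c, Modality.WSI, config, sub_rng).tokens.mean(axis=0)
                     for c in wsi_ids])
            if mri_ids is not None:
                mri_means = np.stack(
                    [bags[(c, Modality.MRI)].tokens.mean(axis=0) for c in mri_ids])
            out = model.forward_mean_batch(wsi_means, mri_means, mode, train=True,
                                           rng=drop_rng, warmup=_warmup)
            if _warmup and "router_weights" in out and len(report.warmup_router_rows) < 4:
                for modality, w in out["router_weights"].items():
                    report.warmup_router_rows.append(np.array(w.data[0]))
            return out
        outs = []
        n = len(ys)
        for i in range(n):
            wsi = mri = None
            if wsi_ids is not None:
                wsi = _get_bag(bags, wsi_ids[i], Modality.WSI, config, sub_rng)
            if mri_ids is not None:
                mri = bags[(mri_ids[i], Modality.MRI)]
            o = model.forward_tensors(wsi=wsi, mri=mri, mode=mode, train=True,
                                      rng=drop_rng, warmup=_warmup)
            if _warmup and "router_weights" in o and len(report.warmup_router_rows) < 4:
                report.warmup_router_rows.append(np.array(o["router_weights"].data))
            outs.append(o)
        return outs

    for epoch in range(lo, hi):
        epoch_loss = 0.0
        n_batches = 0
        unimodal_regime = (strategy is PairingStrategy.UNPAIRED_ALTERNATING
                           or model.config.fusion in _UNIMODAL or _warmup)
        if unimodal_regime:
            if model.config.fusion in _UNIMODAL:
                modality = (Modality.WSI if model.config.fusion is FusionKind.UNIMODAL_WSI
                            else Modality.MRI)
                batches = _unimodal_epoch_batches(train_manifest, modality,
                                                  config.batch_size, epoch, config.seed)
            else:
                batches = alternating_batches(train_manifest, config.batch_size,
                                              epoch, config.seed)
            for modality, case_ids in batches:
                mode = Mode.WSI_ONLY if modality is Modality.WSI else Mode.MRI_ONLY
                ys = [CLASSES.index(labels[c]) for c in case_ids]
                outs = forward_cases(case_ids if modality is Modality.WSI else None,
                                     case_ids if modality is Modality.MRI else None,
                                     ys, mode)
                heads = {"wsi", "mri"} if is_late else None  # LATE: joint head untrainable
                loss = total_loss(outs, ys, lambda_mcc=config.lambda_mcc, heads=heads)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
        else:
            pairs = epoch_pairs(train_manifest, strategy, epoch, config.seed, bags=bags)
            for batch in _chunks(pairs, config.batch_size):
                ys = [CLASSES.index(p.label) for p in batch]
                mode_losses = []
                for mode in _modes_for(model, strategy):
                    wsi_ids = ([p.wsi_case_id for p in batch]
                               if mode in (Mode.MM, Mode.WSI_ONLY) else None)
                    mri_ids = ([p.mri_case_id for p in batch]
                               if mode in (Mode.MM, Mode.MRI_ONLY) else None)
                    outs = forward_cases(wsi_ids, mri_ids, ys, mode)
                    mode_losses.append(total_loss(outs, ys, lambda_mcc=config.lambda_mcc))
                loss = mode_losses[0]
                for t in mode_losses[1:]:
                    loss = loss + t
                loss = loss * (1.0 / len(mode_losses))
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
        report.epoch_train_losses.append(epoch_loss / max(n_batches, 1))
        val_mcc, val_acc = _validation_scores(model, manifest, bags, val_cases,
                                              report.joint_strategy)
        report.epoch_val_mcc.append(val_mcc)
        report.epoch_val_acc.append(val_acc)
        report.stopped_epoch = len(report.epoch_train_losses)
        if val_mcc > report.best_val_mcc:
            report.best_val_mcc = val_mcc
            report.best_epoch = report.stopped_epoch
            best_params = [p.data.copy() for p in model.parameters()]
            fails = 0
        else:
            fails += 1
            if not _warmup and fails >= config.patience:
                break
    if not _warmup:  # warmup hands its final weights to the fusion phase
        for p, data in zip(model.parameters(), best_params):
            p.data = data
    return report


def moe_warmup_train(model: FusionModel, manifest: CohortManifest, bags,
                     folds: FoldAssignment, fold_idx: int, strategy: PairingStrategy,
                     config: TrainConfig) -> TrainReport:
    """MoE schedule: ``warmup_epochs`` of unimodal batches with routing pinned
    one-hot, then strategy-driven multimodal training for the remaining budget
    (total epochs = ``max_epochs``)."""
    if model.config.fusion is not FusionKind.MOE:
        raise ConfigError("moe_warmup_train requires a MOE model")
    if config.warmup_epochs >= config.max_epochs:
        raise ConfigError("warmup_epochs must be < max_epochs")
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    report = TrainReport(seed=config.seed, warmup_epochs_run=config.warmup_epochs)
    train(model, manifest, bags, folds, fold_idx, PairingStrategy.UNPAIRED_ALTERNATING,
          config, _warmup=True, _epoch_range=(0, config.warmup_epochs),
          _report=report, _optimizer=opt)
    report.best_val_mcc = float("-inf")   # early stopping applies to the fusion phase
    report.best_epoch = 0
    train(model, manifest, bags, folds, fold_idx, strategy, config,
          _epoch_range=(config.warmup_epochs, config.max_epochs),
          _report=report, _optimizer=opt)
    return report


def fit(model: FusionModel, manifest, bags, folds, fold_idx, strategy, config) -> TrainReport:
    """Dispatch to the MoE two-phase schedule when applicable."""
    if model.config.fusion is FusionKind.MOE:
        return moe_warmup_train(model, manifest, bags, folds, fold_idx, strategy, config)
    return train(model, manifest, bags, folds, fold_idx, strategy, config)


def cross_validate(manifest: CohortManifest, bags, model_config: ModelConfig,
                   strategy: PairingStrategy, config: TrainConfig,
                   k: int = 5, repeats: int = 2):
    """k-fold x repeats cross-validation (folds fixed, training seeds vary).

    Returns (runs, summary): one (model, report, fold_metrics) triple per run
    and the pooled mean/std of validation MCC and accuracy.
    """
    folds = make_folds(manifest, k, seed=config.seed)
    runs = []
    for rep in range(repeats):
        for fold_idx in range(k):
            run_seed = int(np.random.SeedSequence(
                [config.seed, rep, fold_idx]).generate_state(1)[0] % (2**31))
            run_cfg = replace(config, seed=run_seed)
            model = build_model(model_config, seed=run_seed)
            report = fit(model, manifest, bags, folds, fold_idx, strategy, run_cfg)
            _, val_cases = folds.train_val_split(fold_idx)
            val = evaluate(model, manifest, bags, val_cases,
                           joint_strategy=report.joint_strategy)
            runs.append((model, report, {"fold": fold_idx, "repeat": rep,
                                         "mcc": val["mcc"], "accuracy": val["accuracy"],
                                         "val_cases": val_cases}))
    mccs = [r[2]["mcc"] for r in runs]
    accs = [r[2]["accuracy"] for r in runs]
    summary = {"mcc_mean": float(np.mean(mccs)), "mcc_std": float(np.std(mccs)),
               "accuracy_mean": float(np.mean(accs)), "accuracy_std": float(np.std(accs)),
               "n_models": len(runs), "k": k, "repeats": repeats}
    return runs, summary
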