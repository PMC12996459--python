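"""Desk-scale synthetic experiments mirroring the study's main analyses.

These drivers generate complementary-signal synthetic cohorts (reduced
embedding widths 96/48, 60 patient-matched cases per subtype) and train
patch-mean models under a fixed desk-scale training configuration, repeating
everything over independently seeded runs:

* fusion benefit   — multimodal (mixture-of-experts) vs unimodal validation MCC;
* unimodal robustness — the multimodal model evaluated with one modality
  masked vs the matched unimodal baseline;
* embedding quality — k-means/FMI of penultimate features in joint vs
  single-modality availability modes;
* pairing strategies — patient-matched vs label-paired random vs
  label-agnostic pairing (the latter two on a "de-paired" view of the cohort
  that emulates two unpaired source datasets).

The desk-scale training configuration (lr 5e-3, 128 patches per case) departs
from the full-scale defaults because these cohorts provide ~100x fewer
optimizer steps per epoch; see the methods note.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .embedding_store import FoldAssignment, Modality, make_folds
from .fusion_models import FusionKind, Mode, ModelConfig, build_model
from .metrics import ConfusionMatrix, kmeans_fmi, mcc
from .pair_sampling import PairingStrategy
from .synthetic_cohort import CLASSES, SyntheticSpec, depair_manifest, generate_paired_cohort
from .training import TrainConfig, evaluate, fit

__all__ = [
    "desk_spec", "desk_train_config", "run_fusion_suite", "run_pairing_suite",
    "evaluate_mode", "mode_features",
]


#: embedding-quality holdout: extra same-geometry cases per class, never trained on
HOLDOUT_PER_CLASS = 40


def desk_spec(seed: int, n_paired_per_class: int = 60,
              holdout_per_class: int = HOLDOUT_PER_CLASS) -> SyntheticSpec:
    """The complementary-signal paired cohort used by the experiment suites.

    Cross-modal case noise is independent (corr 0), so each modality is an
    independently noisy view of the class and fusion strictly adds Fisher
    information.  The generator draws ``n_paired_per_class + holdout_per_class``
    cases per class; the surplus is reserved as an untouched holdout for
    embedding-quality scoring.
    """
    return SyntheticSpec(n_per_class_wsi=0, n_per_class_mri=0,
                         n_paired_per_class=n_paired_per_class + holdout_per_class,
                         cross_modal_corr=0.0, seed=seed)


def desk_train_config(seed: int) -> TrainConfig:
    return TrainConfig(lr=1e-2, patches_per_case=128, seed=seed)


def _split_holdout(manifest, n_train_per_class: int):
    """Per-class index split: cases 0..n-1 train/validate, the rest hold out."""
    train, hold = [], []
    for cid in manifest.paired_case_ids():
        (train if int(cid.rsplit("_", 1)[1]) < n_train_per_class else hold).append(cid)
    return manifest.subset(train), hold


def _run_seed(seed: int, run: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(run), int(tag)])
               .generate_state(1)[0] % (2**31))


def evaluate_mode(model, manifest, bags, case_ids, mode: Mode) -> float:
    """Validation MCC with the input-availability mode forced (e.g. the
    multimodal model run WSI-only on paired cases)."""
    labels = manifest.case_labels()
    y_true, y_pred = [], []
    for cid in case_ids:
        wsi = bags.get((cid, Modality.WSI)) if mode in (Mode.MM, Mode.WSI_ONLY) else None
        mri = bags.get((cid, Modality.MRI)) if mode in (Mode.MM, Mode.MRI_ONLY) else None
        probs = model.predict_proba(wsi=wsi, mri=mri, mode=mode)
        y_true.append(CLASSES.index(labels[cid]))
        y_pred.append(int(np.argmax(probs)))
    return mcc(ConfusionMatrix.from_predictions(y_true, y_pred))


def mode_features(model, manifest, bags, case_ids, mode: Mode):
    """Penultimate features of each case under a forced availability mode."""
    labels = manifest.case_labels()
    X, y = [], []
    for cid in case_ids:
        wsi = bags.get((cid, Modality.WSI)) if mode in (Mode.MM, Mode.WSI_ONLY) else None
        mri = bags.get((cid, Modality.MRI)) if mode in (Mode.MM, Mode.MRI_ONLY) else None
        out = model.forward(wsi=wsi, mri=mri, mode=mode)
        X.append(out.penultimate)
        y.append(CLASSES.index(labels[cid]))
    return np.asarray(X), np.asarray(y)


def _model_cfg(fusion: FusionKind, spec: SyntheticSpec) -> ModelConfig:
    return ModelConfig(fusion=fusion, d_wsi=spec.d_wsi, d_mri=spec.d_mri)


def run_fusion_suite(seed: int, n_runs: int = 10, n_paired_per_class: int = 60) -> dict:
    """Fusion benefit + unimodal robustness + embedding quality, one pass.

    Per run: a fresh paired cohort, 5 folds, fold 0 held out; trains UM-WSI,
    UM-MRI and the patch-mean mixture-of-experts model (patient-matched
    pairing, warmup schedule) and scores the held-out fold.
    Returns per-run lists of validation metrics.
    """
    out = {key: [] for key in
           ["um_wsi_mcc", "um_mri_mcc", "mm_mcc", "mm_wsi_only_mcc", "mm_mri_only_mcc",
            "fmi_joint", "fmi_wsi_only", "fmi_mri_only"]}
    out["models"] = []
    for run in range(n_runs):
        rs = _run_seed(seed, run, 1)
        spec = desk_spec(rs, n_paired_per_class)
        full_manifest, bags = generate_paired_cohort(spec)
        manifest, holdout = _split_holdout(full_manifest, n_paired_per_class)
        folds = make_folds(manifest, 5, rs)
        _, val_cases = folds.train_val_split(0)
        cfg = desk_train_config(rs)
        models = {}
        for name, fusion in (("um_wsi", FusionKind.UNIMODAL_WSI),
                             ("um_mri", FusionKind.UNIMODAL_MRI),
                             ("mm", FusionKind.MOE)):
            model = build_model(_model_cfg(fusion, spec), seed=_run_seed(seed, run, 2))
            fit(model, manifest, bags, folds, 0, PairingStrategy.PATIENT_MATCHED, cfg)
            models[name] = model
        out["um_wsi_mcc"].append(evaluate(models["um_wsi"], manifest, bags, val_cases)["mcc"])
        out["um_mri_mcc"].append(evaluate(models["um_mri"], manifest, bags, val_cases)["mcc"])
        mm = models["mm"]
        out["mm_mcc"].append(evaluate_mode(mm, manifest, bags, val_cases, Mode.MM))
        out["mm_wsi_only_mcc"].append(evaluate_mode(mm, manifest, bags, val_cases, Mode.WSI_ONLY))
        out["mm_mri_only_mcc"].append(evaluate_mode(mm, manifest, bags, val_cases, Mode.MRI_ONLY))
        for key, mode in (("fmi_joint", Mode.MM), ("fmi_wsi_only", Mode.WSI_ONLY),
                          ("fmi_mri_only", Mode.MRI_ONLY)):
            X, y = mode_features(mm, full_manifest, bags, holdout, mode)
            out[key].append(kmeans_fmi(X, y, k=3, seed=rs))
        out["models"].append(models)
    return out


def _depaired_folds(folds: FoldAssignment, renamed: dict[str, str]) -> FoldAssignment:
    assignment = dict(folds.case_to_fold)
    for old, new in renamed.items():
        assignment[new] = assignment[old]
    return FoldAssignment(case_to_fold=assignment, k=folds.k)


def pairing_spec(seed: int, n_paired_per_class: int = 60) -> SyntheticSpec:
    """Cohort for the pairing-strategy comparison: modality strengths are
    asymmetric (histology twice the MRI effect), emulating the regime where the
    pathology pathway dominates; label-agnostic pairing then collapses the
    multimodal model toward the unimodal-histology level instead of toward an
    ensemble of two equally strong views."""
    return SyntheticSpec(n_per_class_wsi=0, n_per_class_mri=0,
                         n_paired_per_class=n_paired_per_class,
                         cross_modal_corr=0.0, effect_wsi=2.0, effect_mri=1.0, seed=seed)


def run_pairing_suite(seed: int, n_runs: int = 10, n_paired_per_class: int = 60) -> dict:
    """Pairing-strategy comparison (patient-matched / label-random /
    label-agnostic mixture-of-experts arms plus a unimodal-WSI reference).

    Label-random and label-agnostic arms train on the de-paired view of the
    cohort (two unpaired source datasets over the same patients); every arm is
    scored on the original paired validation fold in multimodal mode.
    """
    out = {"patient_matched_mcc": [], "label_random_mcc": [],
           "label_agnostic_mcc": [], "um_wsi_mcc": []}
    for run in range(n_runs):
        rs = _run_seed(seed, run, 1)
        spec = pairing_spec(rs, n_paired_per_class)
        manifest, bags = generate_paired_cohort(spec)
        folds = make_folds(manifest, 5, rs)
        _, val_cases = folds.train_val_split(0)
        d_manifest, d_bags, renamed = depair_manifest(manifest, bags)
        d_folds = _depaired_folds(folds, renamed)
        cfg = desk_train_config(rs)
        um = build_model(_model_cfg(FusionKind.UNIMODAL_WSI, spec),
                         seed=_run_seed(seed, run, 2))
        fit(um, manifest, bags, folds, 0, PairingStrategy.PATIENT_MATCHED, cfg)
        out["um_wsi_mcc"].append(evaluate(um, manifest, bags, val_cases)["mcc"])
        for key, strategy, man, bg, fl in (
                ("patient_matched_mcc", PairingStrategy.PATIENT_MATCHED,
                 manifest, bags, folds),
                ("label_random_mcc", PairingStrategy.LABEL_RANDOM,
                 d_manifest, d_bags, d_folds),
                ("label_agnostic_mcc", PairingStrategy.LABEL_AGNOSTIC,
                 d_manifest, d_bags, d_folds)):
            model = build_model(_model_cfg(FusionKind.MOE, spec),
                                seed=_run_seed(seed, run, 2))
            fit(model, man, bg, fl, 0, strategy, cfg)
            out[key].append(evaluate_mode(model, manifest, bags, val_cases, Mode.MM))
    return out
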