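"""Class-conditional synthetic embedding cohorts.

The generator emulates the statistical shape of foundation-model embedding
cohorts for glioma subtyping without touching any real data: each case has a
latent token signature ``z = effect * u_class + case_noise`` built on three
mutually orthogonal per-modality class directions; a fraction rho of the
case's tokens are "informative" (z plus token noise), the rest are pure noise.
MRI bags follow the 197-tokens-per-slice geometry (196 patch tokens + 1 global
token that is the mean of its slice's patch tokens plus a small perturbation).

Case noise lives in the 3-dim class-signal subspace, so class overlap is
controlled directly by the effect size (in units of case-noise sd).  For
paired cases the noise coordinates are correlated across modalities with
coefficient ``cross_modal_corr``: at 1 the two modalities are redundant, below
1 each modality is an independently noisy view of the class and fusing them
strictly adds information.

All randomness flows from ``SyntheticSpec.seed``; identical specs produce
identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding_store import (
    CohortManifest, EmbeddingBag, Modality, SubtypeLabel,
    PATCH_TOKENS_PER_SLICE, TOKENS_PER_SLICE, write_bag,
)

__all__ = [
    "SyntheticSpec", "class_signal_vectors",
    "generate_unimodal_cohort", "generate_paired_cohort", "generate_mixed_cohort",
    "depair_manifest", "write_cohort", "bag_means",
]

CLASSES = (SubtypeLabel.GBM, SubtypeLabel.ASTRO, SubtypeLabel.OLIGO)

#: type of the in-memory bag store used throughout: (case_id, Modality) -> EmbeddingBag
BagStore = dict


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic embedding cohort.

    Defaults are desk-scale: reduced embedding widths (96/48) with the full
    foundation-model widths (1536/768) available by override, 60 cases per
    class per unimodal modality, and a 30% diagnosis-discordance rate matching
    the share of cases whose pre-molecular histological diagnosis disagrees
    with the WHO 2021 label in the patient-matched cohort the package emulates.
    Effect sizes are class-mean separations in units of case-noise sd.
    """

    n_per_class_wsi: int = 60
    n_per_class_mri: int = 60
    n_paired_per_class: int = 20
    d_wsi: int = 96
    d_mri: int = 48
    wsi_token_range: tuple[int, int] = (50, 200)
    mri_slices: int = 1
    effect_wsi: float = 2.0
    effect_mri: float = 2.0
    informative_fraction: float = 0.3
    sigma: float = 1.0
    cross_modal_corr: float = 0.5
    discordance_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_class_wsi, self.n_per_class_mri, self.n_paired_per_class) < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.d_wsi < 3 or self.d_mri < 3:
            raise ValueError("embedding widths must be >= 3")
        lo, hi = self.wsi_token_range
        if not (1 <= lo <= hi):
            raise ValueError("wsi_token_range must be ordered and >= 1")
        if not (0.0 < self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must be in (0, 1]")
        if not (0.0 <= self.cross_modal_corr <= 1.0):
            raise ValueError("cross_modal_corr must be in [0, 1]")
        if not (0.0 <= self.discordance_rate < 1.0):
            raise ValueError("discordance_rate must be in [0, 1)")
        if self.effect_wsi < 0 or self.effect_mri < 0 or self.sigma < 0:
            raise ValueError("effect sizes and sigma must be non-negative")
        if self.mri_slices < 1:
            raise ValueError("mri_slices must be >= 1")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(stream)]))


def class_signal_vectors(spec: SyntheticSpec) -> dict[Modality, np.ndarray]:
    """Three mutually orthogonal unit class directions per modality, (3, d) rows.

    Deterministic given ``spec.seed`` (independent of cohort sizes).
    """
    out: dict[Modality, np.ndarray] = {}
    for modality, d in ((Modality.WSI, spec.d_wsi), (Modality.MRI, spec.d_mri)):
        rng = _rng(spec, 1000 + (0 if modality is Modality.WSI else 1))
        a = rng.standard_normal((d, 3))
        q, r = np.linalg.qr(a)
        q = q * np.sign(np.diag(r))  # fix QR sign ambiguity
        out[modality] = q.T.copy()
    return out


def _effect(spec: SyntheticSpec, modality: Modality) -> float:
    return spec.effect_wsi if modality is Modality.WSI else spec.effect_mri


def _latent(spec: SyntheticSpec, modality: Modality, class_idx: int,
            eps: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Case latent z in embedding space from signal-subspace coordinates."""
    coords = eps.copy()
    coords[class_idx] += _effect(spec, modality)
    return coords @ basis


def _wsi_bag(spec: SyntheticSpec, case_id: str, label: SubtypeLabel, z: np.ndarray,
             rng: np.random.Generator) -> EmbeddingBag:
    lo, hi = spec.wsi_token_range
    n = int(rng.integers(lo, hi + 1))
    tokens = spec.sigma * rng.standard_normal((n, spec.d_wsi))
    n_info = max(1, int(round(spec.informative_fraction * n)))
    info = np.sort(rng.choice(n, size=n_info, replace=False))
    tokens[info] += z
    return EmbeddingBag(case_id, Modality.WSI, tokens, label, informative_idx=info)


def _mri_bag(spec: SyntheticSpec, case_id: str, label: SubtypeLabel, z: np.ndarray,
             rng: np.random.Generator) -> EmbeddingBag:
    rows = []
    info_all = []
    for s in range(spec.mri_slices):
        patch = spec.sigma * rng.standard_normal((PATCH_TOKENS_PER_SLICE, spec.d_mri))
        n_info = max(1, int(round(spec.informative_fraction * PATCH_TOKENS_PER_SLICE)))
        info = np.sort(rng.choice(PATCH_TOKENS_PER_SLICE, size=n_info, replace=False))
        patch[info] += z
        glob = patch.mean(axis=0) + (spec.sigma / np.sqrt(PATCH_TOKENS_PER_SLICE)) \
            * rng.standard_normal(spec.d_mri)
        rows.append(np.vstack([patch, glob[None, :]]))
        info_all.append(info + s * TOKENS_PER_SLICE)
    tokens = np.vstack(rows)
    return EmbeddingBag(case_id, Modality.MRI, tokens, label, n_slices=spec.mri_slices,
                        informative_idx=np.concatenate(info_all))


def _manifest_row(case_id, modality, label, source, initial_diagnosis=""):
    return {
        "case_id": case_id, "modality": modality.value, "label": label.value,
        "source": source, "initial_diagnosis": initial_diagnosis or label.value,
        "embedding_path": "",
    }


def generate_unimodal_cohort(spec: SyntheticSpec, modality: Modality
                             ) -> tuple[CohortManifest, BagStore]:
    """Generate a single-modality cohort of ``n_per_class`` cases per subtype."""
    modality = Modality(modality)
    n_per_class = spec.n_per_class_wsi if modality is Modality.WSI else spec.n_per_class_mri
    if n_per_class <= 0:
        raise ValueError(f"no cases requested for {modality.value}")
    basis = class_signal_vectors(spec)[modality]
    rng = _rng(spec, 10 if modality is Modality.WSI else 11)
    make = _wsi_bag if modality is Modality.WSI else _mri_bag
    rows, bags = [], {}
    for ci, label in enumerate(CLASSES):
        for i in range(n_per_class):
            case_id = f"{modality.value.lower()}_{label.value}_{i:04d}"
            eps = rng.standard_normal(3)
            z = _latent(spec, modality, ci, eps, basis)
            bags[(case_id, modality)] = make(spec, case_id, label, z, rng)
            rows.append(_manifest_row(case_id, modality, label, f"synthetic-{modality.value.lower()}"))
    return CohortManifest(pd.DataFrame(rows)), bags


def generate_paired_cohort(spec: SyntheticSpec, return_latents: bool = False):
    """Generate patient-matched cases: one WSI and one MRI bag per case.

    Signal-subspace case-noise coordinates are correlated across the two
    modalities with coefficient ``cross_modal_corr``.  With probability
    ``discordance_rate`` a case's initial (histomorphological) diagnosis is set
    to a different subtype or to the retired 'oa' category, while the WHO 2021
    label is kept — emulating diagnosis-discordant cases.
    """
    if spec.n_paired_per_class <= 0:
        raise ValueError("n_paired_per_class must be > 0 for a paired cohort")
    bases = class_signal_vectors(spec)
    rng = _rng(spec, 12)
    rho = spec.cross_modal_corr
    rows, bags = [], {}
    latents = {}
    for ci, label in enumerate(CLASSES):
        others = [l.value for l in CLASSES if l is not label] + ["oa"]
        for i in range(spec.n_paired_per_class):
            case_id = f"pair_{label.value}_{i:04d}"
            shared = rng.standard_normal(3)
            eps_w = rho * shared + np.sqrt(1.0 - rho**2) * rng.standard_normal(3)
            eps_m = rho * shared + np.sqrt(1.0 - rho**2) * rng.standard_normal(3)
            z_w = _latent(spec, Modality.WSI, ci, eps_w, bases[Modality.WSI])
            z_m = _latent(spec, Modality.MRI, ci, eps_m, bases[Modality.MRI])
            bags[(case_id, Modality.WSI)] = _wsi_bag(spec, case_id, label, z_w, rng)
            bags[(case_id, Modality.MRI)] = _mri_bag(spec, case_id, label, z_m, rng)
            if return_latents:
                latents[case_id] = (eps_w + _effect(spec, Modality.WSI) * np.eye(3)[ci],
                                    eps_m + _effect(spec, Modality.MRI) * np.eye(3)[ci])
            initial = label.value
            if rng.random() < spec.discordance_rate:
                initial = others[rng.integers(len(others))]
            rows.append(_manifest_row(case_id, Modality.WSI, label, "synthetic-paired", initial))
            rows.append(_manifest_row(case_id, Modality.MRI, label, "synthetic-paired", initial))
    manifest = CohortManifest(pd.DataFrame(rows))
    if return_latents:
        return manifest, bags, latents
    return manifest, bags


def generate_mixed_cohort(spec: SyntheticSpec) -> tuple[CohortManifest, BagStore]:
    """Union of the two unpaired unimodal cohorts plus the paired cohort."""
    parts = []
    bags: BagStore = {}
    if spec.n_per_class_wsi > 0:
        m, b = generate_unimodal_cohort(spec, Modality.WSI)
        parts.append(m.df)
        bags.update(b)
    if spec.n_per_class_mri > 0:
        m, b = generate_unimodal_cohort(spec, Modality.MRI)
        parts.append(m.df)
        bags.update(b)
    if spec.n_paired_per_class > 0:
        m, b = generate_paired_cohort(spec)
        parts.append(m.df)
        bags.update(b)
    return CohortManifest(pd.concat(parts, ignore_index=True)), bags


def depair_manifest(manifest: CohortManifest, bags: BagStore,
                    suffix: str = "__mri") -> tuple[CohortManifest, BagStore, dict[str, str]]:
    """Break patient matching by renaming the MRI row of every paired case.

    The result looks like two unpaired source datasets drawn from the same
    underlying patients — the regime in which label-paired random sampling is
    meaningful.  Returns (manifest, bags, renamed) where ``renamed`` maps the
    original case id to the new MRI case id.
    """
    paired = set(manifest.paired_case_ids())
    df = manifest.df.copy()
    renamed = {}
    for i, row in df.iterrows():
        if row["case_id"] in paired and row["modality"] == Modality.MRI.value:
            new_id = row["case_id"] + suffix
            renamed[row["case_id"]] = new_id
            df.at[i, "case_id"] = new_id
    new_bags: BagStore = {}
    for (cid, mod), bag in bags.items():
        if cid in renamed and mod is Modality.MRI:
            nid = renamed[cid]
            new_bags[(nid, mod)] = EmbeddingBag(nid, bag.modality, bag.tokens, bag.label,
                                                bag.n_slices, bag.informative_idx)
        else:
            new_bags[(cid, mod)] = bag
    return CohortManifest(df), new_bags, renamed


def write_cohort(manifest: CohortManifest, bags: BagStore, outdir: str | Path,
                 fmt: str = "h5") -> Path:
    """Write every bag to ``outdir`` and a manifest CSV with filled paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = manifest.df.copy()
    for i, row in df.iterrows():
        key = (row["case_id"], Modality(row["modality"]))
        path = outdir / f"{row['case_id']}_{row['modality'].lower()}.{fmt}"
        write_bag(bags[key], path)
        df.at[i, "embedding_path"] = str(path)
    out = CohortManifest(df)
    out.save(outdir / "manifest.csv")
    return outdir / "manifest.csv"


def bag_means(manifest: CohortManifest, bags: BagStore, modality: Modality
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-case token-mean features and integer labels — the simplest probe
    of cohort separability (used by calibration checks and baselines)."""
    X, y = [], []
    for cid in manifest.cases_with_modality(modality):
        bag = bags[(cid, Modality(modality))]
        X.append(bag.tokens.mean(axis=0))
        y.append(CLASSES.index(bag.label))
    return np.asarray(X), np.asarray(y)
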