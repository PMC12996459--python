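"""Pairing strategies for training multimodal models on unpaired cohorts.

The central idea: two unimodal datasets that share a label space can be fused
at training time by giving every case a sampled complement.  For each anchor
case, the case's own bag is used for any modality it has; for a missing
modality a case with the same label is drawn uniformly from the complementary
dataset.  A fresh pairing is drawn every epoch, so over training each WSI is
seen alongside many different label-matched MRIs (and vice versa) — a form of
augmentation that mimics the biopsy-site variability of heterogeneous gliomas.

Four regimes are provided: PATIENT_MATCHED (true pairs only), LABEL_RANDOM
(the label-matched sampling above), LABEL_AGNOSTIC (complement drawn ignoring
the label — a control that destroys cross-modal label agreement), and
UNPAIRED_ALTERNATING (no pairing at all: alternating single-modality batches).

All sampling is a pure function of (manifest, strategy, seed, epoch).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .embedding_store import CohortManifest, EmbeddingBag, Modality, SubtypeLabel

__all__ = [
    "PairProvenance", "PairingStrategy", "TrainingPair", "SamplingError",
    "sample_complement", "epoch_pairs", "alternating_batches",
]


class SamplingError(ValueError):
    pass


class PairProvenance(str, Enum):
    OWN_OWN = "OWN_OWN"          # both bags belong to the anchor case
    OWN_SAMPLED = "OWN_SAMPLED"  # own WSI, sampled MRI
    SAMPLED_OWN = "SAMPLED_OWN"  # sampled WSI, own MRI
    UNIMODAL = "UNIMODAL"


class PairingStrategy(str, Enum):
    PATIENT_MATCHED = "PATIENT_MATCHED"
    LABEL_RANDOM = "LABEL_RANDOM"
    UNPAIRED_ALTERNATING = "UNPAIRED_ALTERNATING"
    LABEL_AGNOSTIC = "LABEL_AGNOSTIC"


@dataclass
class TrainingPair:
    """A (WSI case, MRI case) pair with the anchor's label and pairing provenance."""

    wsi_case_id: str | None
    mri_case_id: str | None
    label: SubtypeLabel
    provenance: PairProvenance
    wsi: EmbeddingBag | None = None
    mri: EmbeddingBag | None = None


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(epoch)]))


def _attach(pair: TrainingPair, bags) -> TrainingPair:
    if bags is not None:
        if pair.wsi_case_id is not None:
            pair.wsi = bags[(pair.wsi_case_id, Modality.WSI)]
        if pair.mri_case_id is not None:
            pair.mri = bags[(pair.mri_case_id, Modality.MRI)]
    return pair


def sample_complement(case_id: str, label: SubtypeLabel, manifest: CohortManifest,
                      rng: np.random.Generator, bags=None,
                      label_matched: bool = True) -> TrainingPair:
    """Complete a case to a full (WSI, MRI) pair.

    For each modality the case's own bag is used when present; otherwise a case
    of that modality is drawn uniformly from the eligible set (same label when
    ``label_matched``, the whole complementary dataset otherwise).
    """
    label = SubtypeLabel(label)
    own = manifest.modalities_of(case_id)
    if not own:
        raise SamplingError(f"case {case_id!r} not present in the manifest")
    labels = manifest.case_labels()
    chosen: dict[Modality, str] = {}
    for modality in (Modality.WSI, Modality.MRI):
        if modality in own:
            chosen[modality] = case_id
            continue
        eligible = [c for c in manifest.cases_with_modality(modality)
                    if (not label_matched) or labels[c] == label]
        if not eligible:
            raise SamplingError(
                f"no eligible {modality.value} case"
                + (f" with label {label.value!r}" if label_matched else ""))
        chosen[modality] = eligible[int(rng.integers(len(eligible)))]
    if chosen[Modality.WSI] == case_id and chosen[Modality.MRI] == case_id:
        prov = PairProvenance.OWN_OWN
    elif chosen[Modality.WSI] == case_id:
        prov = PairProvenance.OWN_SAMPLED
    else:
        prov = PairProvenance.SAMPLED_OWN
    pair = TrainingPair(chosen[Modality.WSI], chosen[Modality.MRI], label, prov)
    return _attach(pair, bags)


def epoch_pairs(manifest: CohortManifest, strategy: PairingStrategy, epoch: int,
                seed: int, bags=None) -> list[TrainingPair]:
    """One :class:`TrainingPair` per anchor case for one epoch.

    Anchors are the seeded-shuffled case list; each case is the anchor exactly
    once per epoch, and a new random pairing is drawn every epoch (reproducible
    for a fixed (seed, epoch)).
    """
    strategy = PairingStrategy(strategy)
    if strategy is PairingStrategy.UNPAIRED_ALTERNATING:
        raise ValueError("use alternating_batches() for the unpaired regime")
    rng = _epoch_rng(seed, epoch)
    labels = manifest.case_labels()
    if strategy is PairingStrategy.PATIENT_MATCHED:
        cases = manifest.paired_case_ids()
        if not cases:
            raise SamplingError("PATIENT_MATCHED pairing requires paired cases")
    else:
        cases = manifest.case_ids
    order = [cases[i] for i in rng.permutation(len(cases))]
    pairs = []
    for cid in order:
        if strategy is PairingStrategy.PATIENT_MATCHED:
            pairs.append(_attach(
                TrainingPair(cid, cid, labels[cid], PairProvenance.OWN_OWN), bags))
        else:
            pairs.append(sample_complement(
                cid, labels[cid], manifest, rng, bags=bags,
                label_matched=(strategy is PairingStrategy.LABEL_RANDOM)))
    return pairs


def alternating_batches(manifest: CohortManifest, batch_size: int, epoch: int,
                        seed: int) -> list[tuple[Modality, list[str]]]:
    """Unpaired regime: alternating single-modality batches, each case once per
    epoch.  When one modality runs out, the remaining batches are the other
    modality alone."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = _epoch_rng(seed, epoch)
    per_mod: dict[Modality, list[list[str]]] = {}
    for modality in (Modality.WSI, Modality.MRI):
        cases = manifest.cases_with_modality(modality)
        order = [cases[i] for i in rng.permutation(len(cases))]
        per_mod[modality] = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    if not per_mod[Modality.WSI] or not per_mod[Modality.MRI]:
        raise SamplingError("alternating batches require both modalities in the manifest")
    batches: list[tuple[Modality, list[str]]] = []
    i = j = 0
    while i < len(per_mod[Modality.WSI]) or j < len(per_mod[Modality.MRI]):
        if i < len(per_mod[Modality.WSI]):
            batches.append((Modality.WSI, per_mod[Modality.WSI][i]))
            i += 1
        if j < len(per_mod[Modality.MRI]):
            batches.append((Modality.MRI, per_mod[Modality.MRI][j]))
            j += 1
    return batches
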