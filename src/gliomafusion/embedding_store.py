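"""Embedding bags, cohort manifests, stratified folds, and patch subsampling.

A *case* is one patient-level record for one modality: a whole-slide histology
image (WSI) represented as a variable-length bag of 1536-dim patch embeddings,
or a multiparametric MRI slice stack represented as 197 tokens per axial slice
(4 sequences x 49 patch tokens + 1 global token) of width 768.  Embeddings are
produced upstream by frozen foundation models; this package only consumes them.

Bags are stored one file per case (HDF5, with an NPZ fallback dialect), and a
cohort is driven by a CSV manifest mapping (case_id, modality) to a label under
the WHO 2021 glioma classification and to the bag file.  Patient-matched cases
appear as two manifest rows sharing a case_id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Modality", "SubtypeLabel", "EmbeddingBag", "CohortManifest", "FoldAssignment",
    "ManifestSchemaError", "BagFormatError",
    "CANONICAL_DIM", "TOKENS_PER_SLICE", "PATCH_TOKENS_PER_SLICE",
    "mutations_from_label", "load_manifest", "read_bag", "write_bag",
    "make_folds", "subsample_patches", "validate_bag",
]

TOKENS_PER_SLICE = 197          # 4 MRI sequences x 49 patch tokens + 1 global token
PATCH_TOKENS_PER_SLICE = 196
CANONICAL_DIM = {"WSI": 1536, "MRI": 768}

MANIFEST_COLUMNS = ["case_id", "modality", "label", "source", "initial_diagnosis", "embedding_path"]


class ManifestSchemaError(ValueError):
    """Manifest file violates the expected schema."""


class BagFormatError(ValueError):
    """Embedding-bag file or object violates the bag invariants."""


class Modality(str, Enum):
    WSI = "WSI"
    MRI = "MRI"

    @classmethod
    def parse(cls, token: str) -> "Modality":
        try:
            return cls(str(token).upper())
        except ValueError:
            raise ValueError(f"unknown modality {token!r}") from None


class SubtypeLabel(str, Enum):
    """WHO 2021 adult-type diffuse glioma subtypes."""

    GBM = "gbm"      # glioblastoma, IDH-wildtype
    ASTRO = "astro"  # astrocytoma, IDH-mutant, 1p/19q intact
    OLIGO = "oligo"  # oligodendroglioma, IDH-mutant, 1p/19q codeleted

    @classmethod
    def parse(cls, token: str) -> "SubtypeLabel":
        try:
            return cls(str(token).lower())
        except ValueError:
            raise ValueError(f"unknown subtype label {token!r}") from None


#: retired pre-2021 diagnosis allowed only as an initial (histomorphological) call
INITIAL_DIAGNOSES = {"gbm", "astro", "oligo", "oa", ""}


def mutations_from_label(label: SubtypeLabel) -> tuple[bool, bool]:
    """Map a WHO 2021 subtype to its defining (idh_mutant, 1p/19q codeleted) status."""
    label = SubtypeLabel(label)
    if label is SubtypeLabel.GBM:
        return (False, False)
    if label is SubtypeLabel.ASTRO:
        return (True, False)
    return (True, True)


# ---------------------------------------------------------------------------
# Embedding bags
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingBag:
    """One case's token matrix for one modality, with label and provenance.

    ``informative_idx`` is synthetic-cohort bookkeeping (which token rows carry
    class signal); it is absent for real data and ignored by the models.
    """

    case_id: str
    modality: Modality
    tokens: np.ndarray
    label: SubtypeLabel
    n_slices: int = 1
    informative_idx: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[0]

    @property
    def dim(self) -> int:
        return self.tokens.shape[1]


def validate_bag(bag: EmbeddingBag, strict_dims: bool = False) -> None:
    """Check bag invariants; raise :class:`BagFormatError` on violation.

    MRI row geometry (197 tokens per slice) and finiteness are always enforced.
    ``strict_dims`` additionally requires the canonical foundation-model widths
    (WSI 1536 / MRI 768); synthetic cohorts may use reduced widths.
    """
    t = np.asarray(bag.tokens)
    if t.ndim != 2 or t.shape[0] < 1:
        raise BagFormatError(f"{bag.case_id}: tokens must be a non-empty 2-D matrix, got shape {t.shape}")
    if not np.isfinite(t).all():
        raise BagFormatError(f"{bag.case_id}: tokens contain non-finite values")
    if bag.modality is Modality.MRI:
        if bag.n_slices < 1 or t.shape[0] != TOKENS_PER_SLICE * bag.n_slices:
            raise BagFormatError(
                f"{bag.case_id}: MRI bag must have {TOKENS_PER_SLICE} x n_slices rows; "
                f"got {t.shape[0]} rows for n_slices={bag.n_slices}"
            )
    if strict_dims and t.shape[1] != CANONICAL_DIM[bag.modality.value]:
        raise BagFormatError(
            f"{bag.case_id}: {bag.modality.value} bag width {t.shape[1]} != "
            f"canonical {CANONICAL_DIM[bag.modality.value]}"
        )


def write_bag(bag: EmbeddingBag, path: str | Path, strict_dims: bool = False) -> Path:
    """Write a bag to ``path`` (.h5/.hdf5 or .npz); returns the path."""
    validate_bag(bag, strict_dims=strict_dims)
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("tokens", data=np.asarray(bag.tokens))
            f.attrs["case_id"] = bag.case_id
            f.attrs["modality"] = bag.modality.value
            f.attrs["label"] = bag.label.value
            f.attrs["n_slices"] = bag.n_slices
            if bag.informative_idx is not None:
                f.create_dataset("informative_idx", data=np.asarray(bag.informative_idx, dtype=np.int64))
    elif path.suffix == ".npz":
        extra = {}
        if bag.informative_idx is not None:
            extra["informative_idx"] = np.asarray(bag.informative_idx, dtype=np.int64)
        np.savez(
            path,
            tokens=np.asarray(bag.tokens),
            case_id=np.array(bag.case_id),
            modality=np.array(bag.modality.value),
            label=np.array(bag.label.value),
            n_slices=np.array(bag.n_slices),
            **extra,
        )
    else:
        raise BagFormatError(f"unsupported bag container suffix {path.suffix!r} (use .h5/.hdf5/.npz)")
    return path


def read_bag(path: str | Path) -> EmbeddingBag:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "tokens" not in f:
                raise BagFormatError(f"{path}: missing 'tokens' dataset")
            bag = EmbeddingBag(
                case_id=str(f.attrs["case_id"]),
                modality=Modality.parse(f.attrs["modality"]),
                tokens=f["tokens"][()],
                label=SubtypeLabel.parse(f.attrs["label"]),
                n_slices=int(f.attrs.get("n_slices", 1)),
                informative_idx=f["informative_idx"][()] if "informative_idx" in f else None,
            )
    elif path.suffix == ".npz":
        with np.load(path) as z:
            bag = EmbeddingBag(
                case_id=str(z["case_id"]),
                modality=Modality.parse(str(z["modality"])),
                tokens=z["tokens"],
                label=SubtypeLabel.parse(str(z["label"])),
                n_slices=int(z["n_slices"]),
                informative_idx=z["informative_idx"] if "informative_idx" in z.files else None,
            )
    else:
        raise BagFormatError(f"unsupported bag container suffix {path.suffix!r} (use .h5/.hdf5/.npz)")
    validate_bag(bag)
    return bag


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Validated registry of (case_id, modality, label, source, initial_diagnosis, embedding_path) rows."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestSchemaError(f"manifest missing required column(s): {missing}")
        df = df[MANIFEST_COLUMNS].copy()
        df["case_id"] = df["case_id"].astype(str)
        df["source"] = df["source"].fillna("").astype(str)
        df["initial_diagnosis"] = df["initial_diagnosis"].fillna("").astype(str).str.lower()
        df["embedding_path"] = df["embedding_path"].fillna("").astype(str)
        for i, row in df.iterrows():
            try:
                df.at[i, "modality"] = Modality.parse(row["modality"]).value
            except ValueError as e:
                raise ManifestSchemaError(f"row {i}: {e}") from None
            try:
                df.at[i, "label"] = SubtypeLabel.parse(row["label"]).value
            except ValueError:
                raise ValueError(
                    f"row {i} (case {row['case_id']}): invalid label {row['label']!r}; "
                    f"'oa' is admitted only in initial_diagnosis"
                ) from None
            if row["initial_diagnosis"] not in INITIAL_DIAGNOSES:
                raise ValueError(
                    f"row {i} (case {row['case_id']}): invalid initial_diagnosis "
                    f"{row['initial_diagnosis']!r}"
                )
        dup = df.duplicated(subset=["case_id", "modality"])
        if dup.any():
            dupes = df.loc[dup, ["case_id", "modality"]].values.tolist()
            raise ManifestSchemaError(f"duplicate (case_id, modality) rows: {dupes}")
        lab_per_case = df.groupby("case_id")["label"].nunique()
        bad = lab_per_case[lab_per_case > 1]
        if len(bad):
            raise ManifestSchemaError(f"cases with conflicting labels across modalities: {list(bad.index)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def case_ids(self) -> list[str]:
        """Distinct case ids in first-appearance order."""
        return list(dict.fromkeys(self.df["case_id"]))

    def label_of(self, case_id: str) -> SubtypeLabel:
        rows = self.df[self.df["case_id"] == case_id]
        if rows.empty:
            raise KeyError(case_id)
        return SubtypeLabel(rows.iloc[0]["label"])

    def case_labels(self) -> dict[str, SubtypeLabel]:
        return {cid: SubtypeLabel(lab) for cid, lab in
                self.df.drop_duplicates("case_id")[["case_id", "label"]].itertuples(index=False)}

    def cases_with_modality(self, modality: Modality) -> list[str]:
        return list(self.df.loc[self.df["modality"] == Modality(modality).value, "case_id"])

    def modalities_of(self, case_id: str) -> set[Modality]:
        return {Modality(m) for m in self.df.loc[self.df["case_id"] == case_id, "modality"]}

    def paired_case_ids(self) -> list[str]:
        """Cases present in both modalities (patient-matched)."""
        counts = self.df.groupby("case_id")["modality"].nunique()
        paired = set(counts[counts == 2].index)
        return [c for c in self.case_ids if c in paired]

    def path_of(self, case_id: str, modality: Modality) -> str:
        sel = self.df[(self.df["case_id"] == case_id) & (self.df["modality"] == Modality(modality).value)]
        if sel.empty:
            raise KeyError((case_id, modality))
        return sel.iloc[0]["embedding_path"]

    def resolve_paths(self) -> list[str]:
        """Return the rows whose embedding_path is missing on disk (flagged, not fatal)."""
        missing = []
        for _, row in self.df.iterrows():
            p = row["embedding_path"]
            if not p or not Path(p).exists():
                missing.append(f"{row['case_id']}/{row['modality']}")
        return missing

    def subset(self, case_ids) -> "CohortManifest":
        keep = set(case_ids)
        return CohortManifest(self.df[self.df["case_id"].isin(keep)].reset_index(drop=True))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, index=False)
        return path


def load_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return CohortManifest(df)


# ---------------------------------------------------------------------------
# Stratified folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Case-level fold partition; a paired case's two modality rows share a fold."""

    case_to_fold: dict[str, int]
    k: int
    repeats: int = 1

    def fold_cases(self, fold: int) -> list[str]:
        return [c for c, f in self.case_to_fold.items() if f == fold]

    def train_val_split(self, fold: int) -> tuple[list[str], list[str]]:
        val = self.fold_cases(fold)
        train = [c for c, f in self.case_to_fold.items() if f != fold]
        return train, val


def make_folds(manifest: CohortManifest, k: int, seed: int) -> FoldAssignment:
    """Label-stratified case-level partition into ``k`` folds.

    Cases are shuffled with a seeded generator, grouped by label, and dealt
    round-robin; per-fold class counts deviate from proportionality by at most
    one case.  Deterministic for a fixed (manifest, k, seed).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = manifest.case_labels()
    cases = sorted(labels)
    if k > len(cases):
        raise ValueError(f"k={k} exceeds number of cases ({len(cases)})")
    rng = np.random.default_rng(seed)
    order = [cases[i] for i in rng.permutation(len(cases))]
    by_label: dict[SubtypeLabel, list[str]] = {}
    for c in order:
        by_label.setdefault(labels[c], []).append(c)
    for lab, group in by_label.items():
        if len(group) < k:
            warnings.warn(
                f"label {lab.value!r} has only {len(group)} case(s) for k={k}; "
                "some folds will lack this label", stacklevel=2)
    assignment: dict[str, int] = {}
    cursor = 0  # continue the deal across label groups to balance fold totals
    for lab in sorted(by_label, key=lambda l: l.value):
        for c in by_label[lab]:
            assignment[c] = cursor % k
            cursor += 1
    return FoldAssignment(case_to_fold=assignment, k=k)


# ---------------------------------------------------------------------------
# Patch subsampling
# ---------------------------------------------------------------------------

def subsample_patches(bag: EmbeddingBag, m: int, seed: int) -> EmbeddingBag:
    """Sample exactly ``m`` WSI patch tokens (without replacement when the bag is
    large enough, with replacement otherwise); MRI bags pass through unchanged."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if bag.modality is not Modality.WSI:
        return bag
    rng = np.random.default_rng(seed)
    n = bag.n_tokens
    if n >= m:
        idx = rng.choice(n, size=m, replace=False)
    else:
        idx = rng.choice(n, size=m, replace=True)
    new_info = None
    if bag.informative_idx is not None:
        informative = np.zeros(n, dtype=bool)
        informative[np.asarray(bag.informative_idx, dtype=np.int64)] = True
        new_info = np.nonzero(informative[idx])[0]
    return replace(bag, tokens=bag.tokens[idx], informative_idx=new_info)
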