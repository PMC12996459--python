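import numpy as np
import pandas as pd
import pytest

from gliomafusion.embedding_store import CohortManifest, EmbeddingBag, Modality, SubtypeLabel
from gliomafusion.fusion_models import ExpertKind, FusionKind, ModelConfig, build_model
from gliomafusion.synthetic_cohort import SyntheticSpec, generate_mixed_cohort, generate_paired_cohort


def manifest_from_rows(rows):
    return CohortManifest(pd.DataFrame(rows, columns=[
        "case_id", "modality", "label", "source", "initial_diagnosis", "embedding_path"]))


@pytest.fixture
def wsi_bag():
    rng = np.random.default_rng(0)
    return EmbeddingBag("case_w", Modality.WSI, rng.standard_normal((5, 1536)),
                        SubtypeLabel.GBM)


@pytest.fixture
def tiny_spec():
    """Small reduced-dimension cohort spec shared across unit tests."""
    return SyntheticSpec(n_per_class_wsi=4, n_per_class_mri=4, n_paired_per_class=3,
                         d_wsi=24, d_mri=12, wsi_token_range=(8, 16), seed=7)


@pytest.fixture
def tiny_cohort(tiny_spec):
    return generate_mixed_cohort(tiny_spec)


@pytest.fixture
def paired_cohort(tiny_spec):
    return generate_paired_cohort(tiny_spec)


def tiny_model(fusion, expert=ExpertKind.PATCH_MEAN, seed=0, **kw):
    cfg = ModelConfig(fusion=fusion, expert_kind=expert, d_wsi=24, d_mri=12,
                      d_c=kw.pop("d_c", 8), n_blocks=kw.pop("n_blocks", 2),
                      d_inner=kw.pop("d_inner", 12), **kw)
    return build_model(cfg, seed=seed)
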