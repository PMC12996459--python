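import numpy as np
import pytest

from gliomafusion._autodiff import Tensor
from gliomafusion.embedding_store import EmbeddingBag, Modality, SubtypeLabel
from gliomafusion.fusion_models import (
    AttentionPool, ConfigError, ExpertKind, FusionKind, Linear, Mode, ModelConfig,
    ModelInputError, PatchMeanExpert, build_model, count_parameters, load_model,
    save_model,
)

from conftest import tiny_model

rng = np.random.default_rng(0)

MULTIMODAL = [FusionKind.LATE, FusionKind.EARLY, FusionKind.MOE]


def bag(modality, n, d, seed=0, case="c"):
    r = np.random.default_rng(seed)
    return EmbeddingBag(case, modality, r.standard_normal((n, d)), SubtypeLabel.GBM)


class TestConfig:
    def test_defaults(self):
        assert ModelConfig(fusion=FusionKind.MOE).d_c == 16
        assert ModelConfig(fusion=FusionKind.LATE).d_c == 64
        assert ModelConfig(fusion=FusionKind.UNIMODAL_WSI).n_blocks == 24
        assert ModelConfig(fusion=FusionKind.LATE).n_blocks == 12

    @pytest.mark.parametrize("kw", [{"dropout": 1.5}, {"dropout": -0.1},
                                    {"d_c": 1}, {"n_blocks": 0}])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            ModelConfig(fusion=FusionKind.LATE, **kw)


class TestAdapter:
    def test_zero_input_yields_bias_rows(self):
        m = tiny_model(FusionKind.UNIMODAL_WSI)
        out = m.adapt(np.zeros((4, 24)), Modality.WSI).data
        assert np.allclose(out, m.adapters[Modality.WSI].b.data)

    def test_row_wise_independence(self):
        m = tiny_model(FusionKind.LATE)
        x = rng.standard_normal(24)
        one = m.adapt(x[None, :], Modality.WSI).data
        many = m.adapt(np.tile(x, (50, 1)), Modality.WSI).data
        assert np.allclose(many, one)

    def test_width_mismatch_rejected(self):
        m = tiny_model(FusionKind.LATE)
        with pytest.raises(ModelInputError):
            m.adapt(np.zeros((3, 12)), Modality.WSI)  # MRI-width into WSI adapter


class TestPatchMeanExpert:
    def test_permutation_invariance_and_constant_rows(self):
        e = PatchMeanExpert(8, rng)
        x = rng.standard_normal((6, 8))
        a = e(Tensor(x))[0].data
        b = e(Tensor(x[::-1].copy()))[0].data
        assert np.allclose(a, b)
        v = rng.standard_normal(8)
        assert np.allclose(e(Tensor(np.tile(v, (7, 1))))[0].data,
                           e(Tensor(v[None, :]))[0].data)

    def test_direct_recomputation_oracle(self):
        e = PatchMeanExpert(8, rng)
        x = rng.standard_normal((5, 8))
        expected = np.maximum(x.mean(axis=0), 0) @ e.linear.W.data + e.linear.b.data
        assert np.abs(e(Tensor(x))[0].data - expected).max() < 1e-12


class TestAttentionPool:
    def test_single_token_weight_is_exactly_one(self):
        pool = AttentionPool(8, rng)
        _, w = pool(Tensor(rng.standard_normal((1, 8))))
        assert w.data.tolist() == [1.0]

    @pytest.mark.parametrize("n", [1, 7, 197])
    def test_weights_are_probability_vector(self, n):
        pool = AttentionPool(8, rng)
        _, w = pool(Tensor(rng.standard_normal((n, 8))))
        assert (w.data >= 0).all() and abs(w.data.sum() - 1) < 1e-6

    def test_identical_tokens_uniform(self):
        pool = AttentionPool(8, rng)
        _, w = pool(Tensor(np.tile(rng.standard_normal(8), (5, 1))))
        assert np.allclose(w.data, 0.2)

    def test_pooled_in_convex_hull(self):
        pool = AttentionPool(8, rng)
        x = rng.standard_normal((9, 8))
        pooled, _ = pool(Tensor(x))
        assert (pooled.data >= x.min(axis=0) - 1e-12).all()
        assert (pooled.data <= x.max(axis=0) + 1e-12).all()


class TestForward:
    @pytest.mark.parametrize("fusion", MULTIMODAL)
    @pytest.mark.parametrize("expert", list(ExpertKind))
    def test_masking_erases_missing_modality_content(self, fusion, expert):
        m = tiny_model(fusion, expert)
        wsi = bag(Modality.WSI, 10, 24)
        out1 = m.forward(wsi=wsi, mri=bag(Modality.MRI, 197, 12, seed=1), mode=Mode.WSI_ONLY)
        out2 = m.forward(wsi=wsi, mri=bag(Modality.MRI, 197, 12, seed=2), mode=Mode.WSI_ONLY)
        for a, b in [(out1.penultimate, out2.penultimate),
                     (out1.logits(out1.primary_head()), out2.logits(out2.primary_head()))]:
            assert np.array_equal(a, b)  # bit-identical

    def test_missing_required_bag_rejected(self):
        m = tiny_model(FusionKind.LATE)
        with pytest.raises(ModelInputError):
            m.forward(wsi=bag(Modality.WSI, 5, 24), mode=Mode.MM)

    def test_late_mm_populates_all_three_heads(self):
        m = tiny_model(FusionKind.LATE)
        out = m.forward(wsi=bag(Modality.WSI, 5, 24), mri=bag(Modality.MRI, 197, 12),
                        mode=Mode.MM)
        assert out.available_heads == {"mm", "wsi", "mri"}
        assert all(np.isfinite(out.logits(h)).all() for h in out.available_heads)

    def test_early_sequence_consumes_concatenated_tokens(self):
        m = tiny_model(FusionKind.EARLY, ExpertKind.PATCH_SEQUENCE)
        out = m.forward(wsi=bag(Modality.WSI, 2000, 24), mri=bag(Modality.MRI, 197, 12),
                        mode=Mode.MM)
        # fused sequence of N_H + N_M = 2197 tokens, split back per modality
        assert len(out.attention_wsi) == 2000
        assert len(out.attention_mri) == 197

    def test_attention_vectors_are_probability_vectors(self):
        m = tiny_model(FusionKind.LATE, ExpertKind.PATCH_SEQUENCE)
        out = m.forward(wsi=bag(Modality.WSI, 13, 24), mri=bag(Modality.MRI, 197, 12),
                        mode=Mode.MM)
        for w in (out.attention_wsi, out.attention_mri):
            assert (w >= -1e-12).all() and abs(w.sum() - 1) < 1e-6

    def test_unimodal_model_rejects_other_mode(self):
        m = tiny_model(FusionKind.UNIMODAL_WSI)
        with pytest.raises(ModelInputError):
            m.forward(mri=bag(Modality.MRI, 197, 12), mode=Mode.MRI_ONLY)


class TestMoE:
    def test_warmup_pins_routing_exactly(self):
        m = tiny_model(FusionKind.MOE)
        out = m.forward(wsi=bag(Modality.WSI, 5, 24), mri=bag(Modality.MRI, 197, 12),
                        mode=Mode.MM, warmup=True)
        assert out.router_weights.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_router_rows_are_softmax(self):
        m = tiny_model(FusionKind.MOE)
        out = m.forward(wsi=bag(Modality.WSI, 5, 24), mri=bag(Modality.MRI, 197, 12),
                        mode=Mode.MM)
        assert np.allclose(out.router_weights.sum(axis=1), 1.0)
        assert ((out.router_weights >= 0) & (out.router_weights <= 1)).all()

    def test_router_depends_only_on_token_mean(self):
        m = tiny_model(FusionKind.MOE)
        wsi = bag(Modality.WSI, 8, 24)
        perm = EmbeddingBag("c", Modality.WSI, wsi.tokens[::-1].copy(), wsi.label)
        mri = bag(Modality.MRI, 197, 12)
        a = m.forward(wsi=wsi, mri=mri, mode=Mode.MM).router_weights
        b = m.forward(wsi=perm, mri=mri, mode=Mode.MM).router_weights
        assert np.allclose(a, b)


class TestParameterCounts:
    def test_bare_affine_map(self):
        lin = Linear(768, 64, rng)
        assert sum(p.data.size for p in lin.params) == 49216

    @pytest.mark.parametrize("fusion", [FusionKind.UNIMODAL_WSI, FusionKind.UNIMODAL_MRI,
                                        FusionKind.LATE, FusionKind.EARLY])
    def test_patch_sequence_band(self, fusion):
        m = build_model(ModelConfig(fusion=fusion, expert_kind=ExpertKind.PATCH_SEQUENCE))
        assert 900_000 <= count_parameters(m) <= 950_000

    def test_patch_mean_unimodal_and_ratio(self):
        um = build_model(ModelConfig(fusion=FusionKind.UNIMODAL_WSI,
                                     expert_kind=ExpertKind.PATCH_MEAN))
        mm = build_model(ModelConfig(fusion=FusionKind.LATE,
                                     expert_kind=ExpertKind.PATCH_MEAN))
        n_um, n_mm = count_parameters(um), count_parameters(mm)
        assert 95_000 <= n_um <= 125_000        # ~110k
        assert 1.4 <= n_mm / n_um <= 2.2        # multimodal roughly doubles


class TestBatchedPath:
    @pytest.mark.parametrize("fusion", MULTIMODAL + [FusionKind.UNIMODAL_WSI])
    @pytest.mark.parametrize("mode", [Mode.MM, Mode.WSI_ONLY, Mode.MRI_ONLY])
    def test_mean_batch_equals_per_case_forward(self, fusion, mode):
        if fusion is FusionKind.UNIMODAL_WSI and mode is not Mode.WSI_ONLY:
            pytest.skip("unimodal model has a single mode")
        m = tiny_model(fusion)
        wsis = [bag(Modality.WSI, 5 + i, 24, seed=i) for i in range(3)]
        mris = [bag(Modality.MRI, 197, 12, seed=10 + i) for i in range(3)]
        wm = np.stack([b.tokens.mean(axis=0) for b in wsis])
        mm_ = np.stack([b.tokens.mean(axis=0) for b in mris])
        out = m.forward_mean_batch(
            wm if mode in (Mode.MM, Mode.WSI_ONLY) else None,
            mm_ if mode in (Mode.MM, Mode.MRI_ONLY) else None, mode)
        head = sorted(out["available_heads"])[0]
        batched = out[f"logits_{head}"].data
        for i in range(3):
            o = m.forward(wsi=wsis[i] if mode in (Mode.MM, Mode.WSI_ONLY) else None,
                          mri=mris[i] if mode in (Mode.MM, Mode.MRI_ONLY) else None,
                          mode=mode)
            assert np.allclose(batched[i], o.logits(head), atol=1e-10)


def test_checkpoint_round_trip(tmp_path):
    m = tiny_model(FusionKind.MOE, ExpertKind.PATCH_SEQUENCE)
    wsi = bag(Modality.WSI, 6, 24)
    mri = bag(Modality.MRI, 197, 12)
    before = m.forward(wsi=wsi, mri=mri, mode=Mode.MM).logits_mm
    save_model(m, tmp_path / "ckpt.npz")
    back = load_model(tmp_path / "ckpt.npz")
    after = back.forward(wsi=wsi, mri=mri, mode=Mode.MM).logits_mm
    assert np.array_equal(before, after)
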