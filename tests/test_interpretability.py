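import itertools
import math

import numpy as np
import pytest

from gliomafusion._autodiff import Tensor
from gliomafusion.embedding_store import EmbeddingBag, Modality, SubtypeLabel, make_folds
from gliomafusion.fusion_models import ExpertKind, FusionKind, Mode, ModelConfig, build_model
from gliomafusion.interpretability import (
    Grouping, UnsupportedOperationError, attention_entropy, extract_attention,
    extreme_feature_instances, mutation_profile, penultimate_features, scaled_attention,
    shap_explain, _penultimate_rows,
)
from gliomafusion.pair_sampling import PairingStrategy
from gliomafusion.synthetic_cohort import SyntheticSpec, generate_unimodal_cohort
from gliomafusion.training import TrainConfig, train

from conftest import tiny_model

rng = np.random.default_rng(0)


class TestAttentionArithmetic:
    @pytest.mark.parametrize("weights, expected", [
        (np.full(4, 0.25), [1, 1, 1, 1]),
        ([1.0, 0.0, 0.0, 0.0], [4, 0, 0, 0]),
        ([0.5, 0.25, 0.25], [1.5, 0.75, 0.75]),
    ])
    def test_scaling(self, weights, expected):
        assert np.allclose(scaled_attention(weights), expected)

    def test_scaled_mean_is_one_and_validation(self):
        w = rng.dirichlet(np.ones(50))
        assert scaled_attention(w).mean() == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValueError):
            scaled_attention(np.ones(5))

    @pytest.mark.parametrize("weights, expected", [
        (np.full(100, 0.01), math.log(100)),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.5, 0.25, 0.25], 1.5 * math.log(2)),
    ])
    def test_entropy_closed_forms(self, weights, expected):
        assert attention_entropy(weights) == pytest.approx(expected, abs=1e-12)

    def test_entropy_bounded_and_permutation_invariant(self):
        w = rng.dirichlet(np.ones(30))
        assert attention_entropy(w) <= math.log(30) + 1e-12
        assert attention_entropy(w) == pytest.approx(attention_entropy(w[::-1]))


class TestExtractAttention:
    def _bag(self, n=9, d=24, case="c"):
        return EmbeddingBag(case, Modality.WSI, rng.standard_normal((n, d)),
                            SubtypeLabel.GBM)

    def test_patch_mean_model_unsupported(self):
        with pytest.raises(UnsupportedOperationError):
            extract_attention(tiny_model(FusionKind.UNIMODAL_WSI), self._bag())

    def test_single_token_bag(self):
        m = tiny_model(FusionKind.UNIMODAL_WSI, ExpertKind.PATCH_SEQUENCE)
        prof = extract_attention(m, self._bag(n=1))
        assert prof.weights.tolist() == [1.0]
        assert prof.entropy == 0.0

    def test_identical_tokens_uniform_scaled_ones(self):
        m = tiny_model(FusionKind.UNIMODAL_WSI, ExpertKind.PATCH_SEQUENCE)
        tokens = np.tile(rng.standard_normal(24), (6, 1))
        prof = extract_attention(m, EmbeddingBag("c", Modality.WSI, tokens,
                                                 SubtypeLabel.GBM))
        assert np.allclose(prof.scaled, 1.0)

    def test_moe_mixture_is_probability_vector(self):
        m = tiny_model(FusionKind.MOE, ExpertKind.PATCH_SEQUENCE)
        prof = extract_attention(m, self._bag(n=7))
        assert (prof.weights >= 0).all()
        assert prof.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_trained_model_attends_to_informative_tokens(self):
        # sparse informative tokens (rho=0.15) carry the class signal; after
        # training, their mean scaled attention exceeds the noise tokens'
        spec = SyntheticSpec(n_per_class_wsi=20, n_per_class_mri=0, n_paired_per_class=0,
                             d_wsi=24, wsi_token_range=(20, 40),
                             informative_fraction=0.15, effect_wsi=3.0, seed=21)
        man, bags = generate_unimodal_cohort(spec, Modality.WSI)
        folds = make_folds(man, 5, 21)
        model = build_model(ModelConfig(
            fusion=FusionKind.UNIMODAL_WSI, expert_kind=ExpertKind.PATCH_SEQUENCE,
            d_c=8, n_blocks=2, d_inner=16, d_wsi=24, dropout=0.0), seed=21)
        cfg = TrainConfig(lr=2e-2, max_epochs=40, patience=40,
                          patches_per_case=0, seed=21)
        train(model, man, bags, folds, 0, PairingStrategy.PATIENT_MATCHED, cfg)
        gaps = []
        for bag in bags.values():
            prof = extract_attention(model, bag)
            info = np.zeros(bag.n_tokens, bool)
            info[bag.informative_idx] = True
            gaps.append(prof.scaled[info].mean() - prof.scaled[~info].mean())
        assert np.mean(gaps) > 0


class TestPenultimate:
    def test_dimension_per_architecture(self):
        wsi = EmbeddingBag("c", Modality.WSI, rng.standard_normal((5, 24)), SubtypeLabel.GBM)
        mri = EmbeddingBag("c", Modality.MRI, rng.standard_normal((197, 12)), SubtypeLabel.GBM)
        assert penultimate_features(tiny_model(FusionKind.UNIMODAL_WSI), wsi=wsi,
                                    mode=Mode.WSI_ONLY).shape == (8,)
        for fusion, d in ((FusionKind.LATE, 16), (FusionKind.EARLY, 8), (FusionKind.MOE, 16)):
            assert penultimate_features(tiny_model(fusion), wsi=wsi, mri=mri,
                                        mode=Mode.MM).shape == (d,)

    def test_masked_slot_constant(self):
        m = tiny_model(FusionKind.MOE)
        wsi = EmbeddingBag("c", Modality.WSI, rng.standard_normal((5, 24)), SubtypeLabel.GBM)
        a = penultimate_features(m, wsi=wsi, mode=Mode.WSI_ONLY)
        b = penultimate_features(m, wsi=wsi,
                                 mri=EmbeddingBag("c", Modality.MRI,
                                                  rng.standard_normal((197, 12)),
                                                  SubtypeLabel.GBM),
                                 mode=Mode.WSI_ONLY)
        assert np.array_equal(a, b)


class TestShapley:
    def test_efficiency_and_linear_closed_form(self):
        d = 5
        w = rng.standard_normal((d, 3))
        f = lambda X: np.atleast_2d(X) @ w
        X = rng.standard_normal((6, d))
        B = rng.standard_normal((15, d))
        phi = shap_explain(f, X, B)
        for k in range(3):
            expected = (X - B.mean(axis=0)) * w[:, k]
            assert np.abs(phi[:, :, k] - expected).max() < 1e-8
        eff = phi.sum(axis=1) - (f(X) - f(B).mean(axis=0))
        assert np.abs(eff).max() < 1e-8

    def test_exact_matches_coalition_enumeration(self):
        d = 3
        W1 = rng.standard_normal((d, 5))
        b1 = rng.standard_normal(5)
        W2 = rng.standard_normal((5, 3))
        f = lambda X: np.maximum(np.atleast_2d(X) @ W1 + b1, 0) @ W2
        X = rng.standard_normal((3, d))
        B = rng.standard_normal((8, d))
        phi = shap_explain(f, X, B)
        for xi in range(3):
            x = X[xi]
            brute = np.zeros((d, 3))
            for i in range(d):
                others = [j for j in range(d) if j != i]
                for r in range(d):
                    for S in itertools.combinations(others, r):
                        wgt = math.factorial(r) * math.factorial(d - r - 1) / math.factorial(d)

                        def v(ss):
                            rows = B.copy()
                            if ss:
                                rows[:, list(ss)] = x[list(ss)]
                            return f(rows).mean(axis=0)

                        brute[i] += wgt * (v(tuple(S) + (i,)) - v(S))
            assert np.abs(phi[xi] - brute).max() < 1e-10

    def test_sampling_mode_approximates_linear_values(self):
        d = 20  # above the exact-enumeration cutoff
        w = rng.standard_normal(d)
        f = lambda X: (np.atleast_2d(X) @ w)[:, None]
        X = rng.standard_normal((2, d))
        B = rng.standard_normal((10, d))
        phi = shap_explain(f, X, B, n_permutations=200, seed=1)
        expected = (X - B.mean(axis=0)) * w
        # linear models: every permutation gives x_i*w_i against the drawn
        # background row, so error comes only from background subsampling
        assert np.abs(phi[:, :, 0] - expected).max() < 1.0
        assert np.corrcoef(phi[:, :, 0].ravel(), expected.ravel())[0, 1] > 0.95

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            shap_explain(lambda X: X, np.ones((1, 2)), np.empty((0, 2)))


class TestMutationProfile:
    def _phi(self, labels, signal_feature=2, d=6):
        """Contributions where one feature separates IDH-mutant from wildtype."""
        n = len(labels)
        phi = np.zeros((n, d, 3))
        for i, lab in enumerate(labels):
            k = [SubtypeLabel.GBM, SubtypeLabel.ASTRO, SubtypeLabel.OLIGO].index(lab)
            phi[i, signal_feature, k] = 1.0 if lab is not SubtypeLabel.GBM else -1.0
            phi[i, 0, k] = 0.3  # equal in both groups: cancels in the contrast
        return phi

    def test_importance_normalized_and_signal_feature_dominates(self):
        labels = [SubtypeLabel.GBM] * 4 + [SubtypeLabel.ASTRO] * 3 + [SubtypeLabel.OLIGO] * 3
        prof = mutation_profile(self._phi(labels), labels, Grouping.BY_IDH)
        assert np.abs(prof.importance).sum() == pytest.approx(1.0)
        assert prof.importance.argmax() == 2

    def test_ignored_feature_zero_importance(self):
        labels = [SubtypeLabel.GBM] * 3 + [SubtypeLabel.ASTRO] * 3
        prof = mutation_profile(self._phi(labels), labels, Grouping.BY_IDH)
        assert prof.importance[4] == 0.0

    def test_codel_grouping_restricted_to_idh_mutant(self):
        labels = [SubtypeLabel.GBM] * 2 + [SubtypeLabel.ASTRO] * 3 + [SubtypeLabel.OLIGO] * 3
        phi = np.zeros((8, 4, 3))
        phi[5:, 1, 2] = 1.0   # oligo cases load feature 1
        phi[2:5, 3, 1] = 1.0  # astro cases load feature 3
        prof = mutation_profile(phi, labels, Grouping.BY_CODEL)
        assert prof.importance.argmax() in (1, 3)
        with pytest.raises(ValueError):
            mutation_profile(phi[:2], labels[:2], Grouping.BY_CODEL)  # no mutants

    def test_by_class_rows_normalized(self):
        labels = [SubtypeLabel.GBM] * 2 + [SubtypeLabel.ASTRO] * 2 + [SubtypeLabel.OLIGO] * 2
        phi = rng.standard_normal((6, 5, 3))
        prof = mutation_profile(phi, labels, Grouping.BY_CLASS)
        assert prof.importance.shape == (3, 5)
        assert np.allclose(np.abs(prof.importance).sum(axis=1), 1.0)


class TestExtremeInstances:
    def _bags(self, counts=(3, 4)):
        return [EmbeddingBag(f"c{i}", Modality.WSI, rng.standard_normal((n, 24)),
                             SubtypeLabel.GBM) for i, n in enumerate(counts)]

    def test_argmax_argmin_retrieval(self):
        m = tiny_model(FusionKind.UNIMODAL_WSI)
        bags = self._bags((3,))
        vals = _penultimate_rows(m, bags[0])[:, 1]
        top, bottom = extreme_feature_instances(m, bags, feature_idx=1, k=1)
        assert top[0][1] == int(vals.argmax())
        assert bottom[0][1] == int(vals.argmin())

    def test_sorted_and_disjoint(self):
        m = tiny_model(FusionKind.MOE)
        top, bottom = extreme_feature_instances(m, self._bags((5, 5)), feature_idx=0, k=3)
        assert [t[2] for t in top] == sorted([t[2] for t in top], reverse=True)
        assert [b[2] for b in bottom] == sorted([b[2] for b in bottom])
        assert not (set((t[0], t[1]) for t in top) & set((b[0], b[1]) for b in bottom))

    def test_oversized_k_truncates_with_warning(self):
        m = tiny_model(FusionKind.UNIMODAL_WSI)
        with pytest.warns(UserWarning, match="truncated"):
            top, bottom = extreme_feature_instances(m, self._bags((2,)), 0, k=10)
        assert len(top) == 2

    @pytest.mark.parametrize("fusion", [FusionKind.LATE, FusionKind.MOE, FusionKind.EARLY])
    def test_vectorized_patch_mean_path_matches_singleton_loop(self, fusion):
        m = tiny_model(fusion)
        bag = self._bags((4,))[0]
        fast = _penultimate_rows(m, bag)
        for i in range(bag.n_tokens):
            single = EmbeddingBag(bag.case_id, bag.modality, bag.tokens[i:i + 1],
                                  bag.label)
            ref = penultimate_features(m, wsi=single, mode=Mode.WSI_ONLY)
            assert np.allclose(fast[i], ref, atol=1e-10)
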