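# Methods

This note documents the models, the training procedure, the synthetic data
generator, and the numerical and design choices behind `gliomafusion`. It is
the place to look when a default seems arbitrary — most were fixed once, for
the reasons given here, and are exercised by the test suite.

## Problem setting

A case is a bag of foundation-model tokens per modality: whole-slide histology
(WSI) as a variable-length N×1536 matrix of patch embeddings, multiparametric
MRI as 197×768 per axial slice (49 patch tokens for each of the four sequences
T1, T1c, T2, FLAIR, plus one global token). The target is the WHO 2021 glioma
subtype — glioblastoma (IDH-wildtype), astrocytoma (IDH-mutant, 1p/19q
intact), oligodendroglioma (IDH-mutant, 1p/19q codeleted) — so the molecular
markers are a deterministic function of the label (`mutations_from_label`).
The foundation models themselves are out of scope: only their output
embeddings are consumed, and in tests those embeddings are synthetic.

## Architectures

All models share three parts:

* **Adapter** — one linear layer per modality projecting tokens to a shared
  width d_C (row-wise, so token count is free). d_C defaults to 64; the
  mixture-of-experts model uses d_C = 16 so that individual penultimate
  features stay interpretable.
* **Expert** — *patch-mean*: feature-wise mean → ReLU → linear (a unimodal
  model is then a 4-layer MLP, ≈107k parameters at full input widths);
  *patch-sequence*: n width-preserving sequence blocks followed by attention
  pooling. n = 24 for unimodal models and 12 per expert for multimodal ones.
* **Head** — 2-layer MLP with one ReLU (hidden width d_C), dropout applied to
  the hidden activation during training.

**Sequence block.** The contract is any width-preserving sequence-to-sequence
block. The implementation is a gated global-context block: project tokens to
[U, G] at inner width d_i, add a linear transform of the mean token of U to
every row (the cross-token mixing channel), gate with SiLU(G), project back,
and add residually. It is deliberately simple — differentiable with plain
matrix ops, O(N·d_C·d_i), and sufficient for the bag-classification regime the
tests probe. It is *not* a selective state-space model: it is permutation
invariant and has no recurrent state, so order-dependent structure in a token
sequence is invisible to it (token order carries no information in these bags
anyway). The inner widths are tuned once per architecture family so that every
patch-sequence model lands in the 900k–950k trainable-parameter band at the
canonical input widths: d_i = 110 (unimodal WSI, 909,524 total), 115 (unimodal
MRI, 910,772), 105 (late fusion, 922,411), 173 (early fusion, 916,740), 166
(mixture of experts at d_C=16, 902,489).

**Fusion.**

* *Late (MM-LF)*: one expert per modality; representations concatenated into a
  joint head; two additional unimodal heads.
* *Early (MM-EF)*: patch-sequence — adapted token sequences concatenated along
  the token axis into one (N_H + N_M)×d_C sequence for a single expert;
  patch-mean — the two adapted means are mean-pooled *before* the ReLU,
  keeping the fusion stage symmetric with the token-level variant.
* *Mixture of experts (MM-MoE)*: both modalities pass through both experts;
  a per-modality router (linear + softmax over the two experts, computed on
  the mean adapted token, so it is order-invariant by construction) mixes the
  expert outputs; the two modality representations are concatenated into the
  joint head, symmetric with late fusion.

**Masking.** An absent modality is replaced by a single all-zero token *after*
the adapter. Consequences: outputs in a unimodal mode are bit-identical under
any change of the missing modality's content (tested), router inputs for a
masked modality are exactly zero, and sequence lengths stay finite. The
per-token position of the masked slot in the penultimate vector is a learned
constant.

**Attention pooling** uses a single learned linear score per token,
softmax-normalized; the pooled vector is the convex combination of the token
representations. For MM-MoE, the reported attention is the router-weighted
mixture of the two experts' attention vectors, since neither expert alone is
"the" modality expert after routing.

## Training

Cross-entropy plus a soft MCC loss, equally weighted (λ = 1), averaged over
the available output heads, optimized with Adam. The soft confusion matrix
accumulates predicted probabilities by true class; the multiclass MCC is
computed from it in covariance form and the loss is 1 − MCC_soft. At one-hot
probabilities this equals 1 − hard MCC exactly (oracle-tested); a degenerate
denominator maps to MCC_soft = 0 (loss 1), the same convention as the hard
metric. The denominator guard makes the loss non-differentiable only at that
degenerate point.

Reference protocol (TrainConfig defaults): batch 32, learning rate 5e-5, at
most 20 epochs with early stopping, weight decay 0.01 (the conventional
reading of "L2 normalization, strength 0.01"), dropout 0.5, 2000 patches
subsampled per WSI case per epoch (without replacement when the bag is large
enough, with replacement otherwise, so batch geometry is fixed).

Multimodal models train on all input-availability permutations of every pair
(MM, WSI-only, MRI-only via masking), so the unimodal pathways are first-class
citizens of the optimization. Early stopping monitors the validation MCC
averaged over those same permutations (patience 5, best-epoch weights
restored) — the natural counterpart of permutation training; monitoring the
joint mode alone systematically under-trains the unimodal pathways. MM-MoE
first trains `warmup_epochs` (default 5) on alternating unimodal batches with
the routing pinned exactly one-hot (WSI→expert 0, MRI→expert 1), establishing
a modality bias per expert, then trains the remaining budget with routing
free; the total epoch budget is unchanged. In the unpaired alternating regime
the late-fusion joint head receives no gradient (it needs a pair); it is
flagged in the report and replaced at inference by averaging the unimodal
heads' probabilities.

Pairing regimes (`pair_sampling`): each epoch, every case anchors exactly one
pair; its own bag is used for any modality it has and a uniformly drawn
same-label case completes it (label-random), or the complement ignores the
label (label-agnostic control), or only true pairs are used
(patient-matched), or no pairing at all (alternating unimodal batches). A new
pairing is drawn every epoch; everything is a pure function of
(manifest, strategy, seed, epoch). Complements are drawn with replacement
across anchors — independent uniform draws, the plain reading of the sampling
algorithm.

Cross-validation: label-stratified case-level folds (seeded shuffle +
round-robin deal, per-fold class counts within one case of proportional;
paired cases keep both modality rows in one fold), k = 5, each fold trained
twice with different seeds → 10 models.

## Synthetic cohorts

The generator emulates the *statistical shape* of frozen-encoder embedding
cohorts, not their content. Per modality, three orthonormal class directions
u_c are drawn once from the seed. A case of class c has latent

    z = effect · u_c + Σ_k ε_k u_k,   ε ~ N(0, 1³),

i.e. case-to-case variation lives in the class-signal subspace with unit sd,
so `effect` is the class separation in case-noise units. A fraction ρ of the
case's tokens are informative (z plus token noise σ·N(0, I)); the rest are
pure token noise. MRI bags follow the 197-per-slice geometry with the global
token equal to the mean of its slice's 196 patch tokens plus a small
(σ/√196) perturbation. For paired cases the ε coordinates are correlated
across modalities with coefficient `cross_modal_corr`; at 1 the modalities are
redundant views, at 0 each is an independently noisy measurement of the class
and fusing them strictly adds Fisher information. With probability
`discordance_rate` a paired case's *initial* (histomorphological) diagnosis is
set to a different subtype or the retired "oligoastrocytoma" category while
the molecular label is kept, emulating diagnosis-discordant cases at the ~30%
rate seen in patient-matched cohorts re-labelled under the 2021 criteria.

Defaults, chosen once: reduced widths d_wsi 96 / d_mri 48 (full 1536/768
available by override — reduced bags are valid everywhere except under
`strict_dims` validation), 60 cases per class per modality, WSI token counts
uniform in [50, 200], effect 2.0 per modality, ρ = 0.3, σ = 1,
cross_modal_corr 0.5, discordance 0.3. Effect 2.0 puts a linear probe on bag
means in the ~0.8 accuracy range — hard enough that fusion has headroom, easy
enough that 5-fold training on 180 cases is stable.

What the generator does **not** model: real foundation-model feature geometry
(unknown; spherical Gaussians about orthogonal class directions are a stated
modeling choice), scanner/site batch effects, inter-slide heterogeneity
within a case, class imbalance, and any pixel-level structure. Passing the
synthetic experiments therefore demonstrates that the architectures, losses,
and sampling strategies behave as designed in a controlled regime — not that
the reported real-cohort numbers transfer.

## Desk-scale experiments

The experiment suites (`experiments.py`, also driven by
`scripts/acceptance.py` and the end-to-end tests) train patch-mean models on
reduced-width cohorts of 60 paired cases per class, 10 independently seeded
runs per suite, fold 0 of 5 held out:

* **Fusion benefit / robustness / embedding quality** use a
  modality-symmetric *complementary* cohort (effects 2/2, cross_modal_corr 0):
  independent case noise is exactly the regime where combining modalities
  adds information. An extra 40 same-geometry cases per class are generated
  and held out purely for the embedding-quality comparison (k-means + FMI of
  penultimate features under joint / WSI-only / MRI-only availability);
  criterion MCCs are computed on the validation fold.
* **Pairing strategies** use an asymmetric cohort (effect_wsi 2, effect_mri
  1), emulating the regime where the histology pathway dominates. This is
  deliberate: in a symmetric cohort with conditionally independent modalities,
  a label-agnostic-trained joint head converges to a per-modality posterior
  ensemble, which is already near-optimal fusion — the degradation of
  label-agnostic pairing toward the unimodal-histology level is only
  observable when the modalities differ in strength. Label-random and
  label-agnostic arms train on a "de-paired" view of the cohort (the MRI row
  of each case is renamed, turning one paired cohort into two unpaired
  datasets over the same patients — otherwise complement sampling would simply
  return the case's own bag and collapse onto patient-matched training); all
  arms are scored on the original paired validation fold in multimodal mode.

Desk-scale training config: lr 1e-2, 128 patches per case, other defaults
unchanged. The reference learning rate (5e-5) is coupled to epochs with
hundreds of optimizer steps; these cohorts provide ~5 steps per epoch, where
5e-5 cannot move Adam-scale weights measurably within 20 epochs. The ~100×
larger rate compensates for the ~100× fewer steps and was fixed before the
acceptance assertions were frozen.

## Numerical choices and conventions

* Models run on an internal reverse-mode autodiff engine over numpy
  (`_autodiff.py`), float64 throughout; gradients are verified against finite
  differences in the test suite. For patch-mean models, training uses an
  algebraically identical batched path (the adapter is affine and the expert
  consumes only the token mean, so a case collapses to its subsampled token
  mean; equality with the per-case path is asserted to 1e-10).
* MCC: zero denominator → 0; the returned value is clipped to [−1, 1] against
  round-off. FMI: no co-pairs in either partition → 0. AUROC: one-vs-rest
  with midrank tie handling; a class missing positives or negatives is
  skipped with a warning.
* Mann–Whitney U: exact null for tie-free samples up to n = 12 per group,
  normal approximation with tie correction otherwise (SciPy backend).
* Shapley values: "absent" features are replaced by background rows, so
  efficiency holds against the mean-of-background baseline. Exact subset
  enumeration up to d = 16; antithetic permutation sampling (default 128
  permutations) above. The default background is the cohort's own feature
  matrix.
* Per-token feature values for extreme-instance retrieval evaluate each token
  as a singleton bag (for patch-mean experts this is computed in one
  vectorized pass; the equivalence is tested). How bag-level models should be
  probed at token level is genuinely underdetermined; singleton-bag evaluation
  is the choice here.
* Attention entropy is computed on the normalized weights in nats (0·ln 0 = 0);
  the "scaled" attention N·w is a display convention and does not change the
  entropy.
* Seeds: every stochastic component (generator streams, fold shuffles,
  per-epoch pairing, patch subsampling, dropout, parameter init) derives from
  an explicit integer seed through independent `SeedSequence` streams;
  identical inputs reproduce identical runs bit-for-bit.

## Known limitations

* The sequence block is a width-preserving token mixer, not a state-space
  scan; conclusions about order-sensitive sequence modeling do not transfer.
* The 220k multimodal patch-mean parameter figure sometimes quoted for this
  model family does not follow from the stated architecture (the 1536-wide
  WSI adapter dominates and is not duplicated); this implementation yields
  ≈173k, about 1.6× the unimodal model, and the tests assert only the loose
  ratio.
* Whether the association between attention entropy and correctness has a
  stable direction is cohort-dependent; the package computes entropy but
  asserts nothing about that association.
* The label-agnostic degradation result depends on asymmetric modality
  strength (see above); it should be read as a property of that regime.
* Real-cohort performance (AUC/MCC/accuracy on TCGA-like data) is outside the
  reach of the synthetic suites and is not claimed.
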