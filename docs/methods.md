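# Methods

`damlm` implements a domain-adaptive learning model for multi-center
brain MRI: a hybrid 3D CNN–transformer encoder trained jointly for tumor
grading (and optionally segmentation) on two acquisition domains, with a
trilevel domain-adaptation objective. Because multi-center MRI cohorts
cannot ship with a software package, the library includes a synthetic
phantom generator that reproduces the *structure* of the problem —
paired anatomies observed under two acquisition styles — at sizes a
single CPU handles in minutes. This note records the model, the
generator, the numerical choices, and what the desk-scale experiments do
and do not demonstrate.

## Model

**Preprocessing.** Each sequence (T1, T1ce, T2, FLAIR) is z-score
normalized within the brain mask (population variance, ddof = 0;
background voxels stay 0). Bias fields follow the multiplicative model
`v = b · t + ε`; the estimator smooths log-intensities with a masked
(normalized-convolution) Gaussian of width `smoothness_mm` (default
8 mm), exponentiates the deviation from its in-mask mean, and divides.
Under this estimator the additive residual is identically zero — the
multiplicative model absorbs high-frequency structure into `t` — so the
reconstruction `v = b · t` is exact to floating tolerance. Skull
stripping multiplies by the binary mask; resampling is trilinear for
images and nearest-neighbor for masks with output shape
`round(shape · spacing / δ)`; registration supports affine application
only (phantoms are generated in a common frame, so the default
transform is the identity). Patch extraction uses a sliding window with
stride τ plus a flush-to-end origin per axis, so patch footprints cover
the grid exactly; the desk-scale default patch is 16³–32³ (the
full-scale configuration of 96³ with stride 48 is reachable through the
same config).

**Encoder.** A stem of `L_c` multi-scale residual blocks
`R(U) = proj(U) + PReLU(BN(W₃∗U + W₅∗U))` with parallel 3³ and 5³
branches; `proj` is a 1³ convolution only where channels or resolution
change. Batch-norm statistics are always computed jointly over the full
mixed-domain batch (never per domain) and running estimates use
momentum 0.9. A squeeze-excitation channel attention
`s = σ(W₂ ReLU(W₁ GAP(F)))` rescales channels before tokenization.
Tokens are the flattened feature grid (x fastest) plus positional
encodings — sinusoidal by default (per-axis sin/cos bands concatenated
and fit to C), zero-initialized learned encodings as an option. Each of
the `L_t` transformer layers computes single-head (configurable)
self-attention `softmax(QKᵀ/√C)·V` on pre-layer-normalized tokens
followed by a two-layer ReLU feed-forward, added residually. The
attention scale is √C by default with a plain-C variant exposed
(`attention_scale`), since either reading is defensible. Global average
pooling over tokens yields the embedding `g` used by the classifier,
the discriminator and all alignment losses. `cnn_only` skips the
transformer stack; `transformer_only` replaces the stem with a linear
patch embedding of non-overlapping cells (no segmentation decoder in
this mode, as there is no convolutional grid to mirror).

**Heads.** The classifier is a single affine map with a max-subtracted
softmax; cross-entropy is ε-clamped (1e-12) before the log. The
segmentation decoder mirrors the stem: one transposed convolution
(k = stride = 2) per strided block, concatenating the stem feature at
the matching resolution (raw input at full resolution), a 3³ fusion
convolution with PReLU, and a 1³ head with per-voxel softmax over
{background, edema, core, enhancing}. The segmentation loss is soft
Dice averaged over the three foreground classes with ε = 1e-5; an empty
class predicted empty contributes Dice ≈ 1.

**Adaptation.** Three alignment terms act on `g`:

- *Adversarial*: a 2-layer MLP discriminator (hidden C/2, ReLU,
  sigmoid) is trained on binary cross-entropy of the domain label; the
  encoder minimizes the symmetric confusion loss
  `−½[log ŷ_d + log(1−ŷ_d)]`, whose unique minimum ln 2 sits at
  ŷ_d = ½. The gradient-reversal formulation (discriminator BCE against
  the symmetrized target ½) is available behind `grl_enabled` and is
  algebraically identical, which a test pins to 1e-6.
- *Contrastive*: InfoNCE over temperature-scaled cosine similarities
  (τ = 0.1). Positives are the two renderings of the same anatomy in
  the two domains; negatives are all other cross-domain samples in the
  batch; the loss is averaged over both directions.
- *Covariance*: `‖Σ_src − Σ_tgt‖_F²` with unbiased (n−1) covariance of
  the batch embeddings, requiring ≥ 2 samples per domain.

Combined as `L_DA = 0.5·L_adv + 1.0·L_con + 0.1·L_cov` by default, and
`L_total = L_cls + λ_seg·L_seg + λ_DA·L_DA` (λ_DA = 1; the segmentation
term is absent when the decoder is disabled).

**Optimization.** AdamW (β = 0.9/0.999, ε = 1e-8, decoupled weight
decay 1e-4) under a cosine schedule with floor,
`η(t) = η_min + ½(η₀−η_min)(1+cos πt/T)` with η₀ = 3e-4, η_min = 1e-6
and T the total step count. Batches are half-and-half mixed:
`batch_size/2` anatomy pairs are drawn without replacement per epoch and
each contributes its source and target rendering, which guarantees both
domains in every batch and supplies the contrastive positives. Each
step first updates the discriminator on detached embeddings, then takes
a joint step on `L_total` with confusion-loss gradients discarded on
the discriminator's parameters, so no gradient ever crosses between the
two players. Augmentation applies, each with probability 0.5: elastic
deformation (max 1 voxel), intensity scaling within ±10%, rotation
within ±15°, and patch dropout (a random cuboid zeroed); geometric
operators co-transform the masks. Early stopping monitors
`α_val = γ·α_src + (1−γ)·α_tgt` (γ = 0.5, patience 20 by default) and
restores the best parameters. Training is bit-reproducible per seed in
full precision.

All tensors are float64 on a purpose-built reverse-mode autograd engine
over numpy (exact analytic gradients; verified against central finite
differences at 1e-4 relative or better across every parameter group).

## Synthetic phantoms

An anatomy is a brain-shaped ellipsoid with a smooth background field
and a nested tumor: necrotic core, enhancing rim, and edema, each an
ellipsoidal shell with per-anatomy jittered radii and axes. Per-sequence
tissue intensities follow clinical ordering (rim brightest on T1ce,
edema brightest on FLAIR, core dark on T1/T1ce). The class label (a
grade analog, K = 2 by default) is drawn uniformly and then expressed
geometrically as the enhancing-rim thickness — higher grade, thicker
shell — so classification is learnable from the image and label
proportions are balanced by construction.

A domain style renders an anatomy as `v = b · t_c + ε`: `b` is the
exponential of amplitude-scaled smoothed white noise (smoothness in
mm), `ε` is i.i.d. Gaussian noise, and `t_c` compresses tissue contrast
about the in-brain mean by `contrast_gain`. A pure global gain would be
erased exactly by z-score normalization and carry no domain
information, which is why the gain acts on contrast; gain 1, amplitude
0, noise 0 reproduces the anatomy bit-exactly. Both renderings of an
anatomy share its region mask voxel-for-voxel, giving the contrastive
pairing table. Style spacing is carried as acquisition metadata rather
than resampled at render time, so pairs stay voxel-aligned; spacing
harmonization belongs to the preprocessing stage.

Perturbations (intensity scaling, additive Gaussian noise relative to
the in-mask intensity std, elastic deformation, directional motion
blur) come in three documented severities — gains {0.95, 0.90, 0.80},
noise ratios {0.05, 0.10, 0.20}, max displacements {1, 2, 4} voxels,
kernel lengths {2, 3, 5} — plus an identity ("zero") severity for
testing. Scanner profiles emulate dataset-level shifts: low-field
(smoothing + noise at std/snr_factor), sequence-wise bias fields,
smooth coil gain maps, and a combined high-noise/low-contrast
degradation that shrinks inter-tissue gaps about the in-brain mean.
Everything is a pure function of (inputs, seed).

What the phantoms do **not** emulate: real neuroanatomy, lesion
biology, k-space/MR physics, registration errors, or site effects
beyond the four modeled factors. Passing the desk-scale experiments
demonstrates that the pipeline, objectives and harnesses behave as
specified — not that the model reaches any particular performance on
clinical data.

## Desk-scale benchmark

The packaged benchmark (also what `scripts/acceptance.py` runs) uses 60
volumes per domain on a 16³ grid (one 16³ patch per volume), C = 16,
two stem blocks (both strided, for early downsampling at this scale),
two transformer layers, batch 16, 30 epochs, and source/target styles
differing by contrast gain 0.7, bias amplitude 0.3 and a doubled noise
level. Anatomy pairs are split 70/15/15 (stratified by class); both
variants — full trilevel adaptation and a control with all three
adaptation weights zeroed — train on **source labels only**, with
target images entering unlabeled (the cross-domain protocol), and are
evaluated without fine-tuning. Transfer accuracy is measured on a
fresh 40-pairs-per-domain evaluation cohort with unseen anatomies:
with only 9 test volumes per domain from the split itself, per-seed
accuracy comparisons would be dominated by sampling noise, and the
generator makes held-out data free. Reported quantities: in-domain and
cross-domain accuracy per variant, the source→target degradation, the
held-out covariance gap before and after training (full and
no-adaptation variants), R_deg per perturbation and severity, D_shift
per scanner profile (each measured on 60 freshly rendered volumes per
seed, enough that accuracy-based ratios are not dominated by single
samples), and a CI95 over seeds (1.96·σ/√n, ddof = 1).

A caveat the harness surfaces honestly: the *absolute* held-out
covariance gap of the full model typically ends **above** its value at
random initialization. Randomly initialized features are nearly
domain-blind after harmonized preprocessing, so the initial gap is
close to zero; training makes features informative, and informative
features separate the domains more than noise does, even while the
covariance penalty (weight 0.1) holds the gap far below the
no-adaptation control's. The meaningful alignment comparison is
therefore full-model vs. no-adaptation, which the acceptance script
reports.

## Numerical choices

- Probability clamps at 1e-12 before any log; softmax and log-softmax
  use max subtraction.
- BatchNorm ε = 1e-5, LayerNorm ε = 1e-6; Dice ε = 1e-5.
- Kaiming-uniform initialization (bound √(6/fan_in)); PReLU slope 0.25;
  learned positional encodings zero-initialized.
- Stratified splits use per-class largest-remainder rounding with ties
  broken toward the earlier partition (train > val > test).
- Paired t-tests: all-zero differences return p = 1; zero-variance
  nonzero differences return p = 0 with a warning. Dice/Jaccard of an
  empty region against an empty region is 1 by convention.
- Degenerate guards: z-scoring rejects constant in-mask intensities;
  covariance requires ≥ 2 samples per domain; `R_deg` with a zero
  baseline is reported as missing with a warning.
- Gradient clipping exists behind a flag and is off by default.

## Known limitations

- Single-device, full-precision numpy execution: suitable for desk
  scale, not for 96³ patches at realistic cohort sizes.
- The discriminator and adaptation losses act on the pooled embedding
  only; token-level alignment is not implemented.
- Deformable registration, learned skull stripping and uncertainty
  quantification are out of scope.
- With K > 2 the grade analog is an ordinal rim-thickness code; real
  tumor subtype structure is richer.
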