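# Methods

## Problem and model

`nodulefusion` classifies the invasiveness of subsolid lung nodules on
volumetric chest CT into two groups — G1 (pre-invasive and minimally
invasive adenocarcinoma spectrum) and G2 (invasive adenocarcinoma) — by
fusing three complementary feature sets per nodule:

1. **Hand-crafted radiomics** (36-d). Each nodule-bearing slice is filtered
   in-plane with Laplacian-of-Gaussian (LoG) band-pass kernels at
   spatial-scale-filter (SSF) values of 0 (no filtration), 2, 3, 4, 5 and
   6 mm.  The kernel samples the closed form
   `LoG(x,y) = -1/(pi s^4) (1 - r^2/(2 s^2)) exp(-r^2/(2 s^2))`
   at integer pixel offsets (s = sigma in pixels, converted from mm with
   the in-plane spacing only), truncated at `ceil(4 s)` and shifted to sum
   exactly to zero.  Responses at in-mask voxels are pooled across slices
   — filtration is 2-D, the statistics are volumetric — and summarised by
   Mean, population SD, base-2 Shannon entropy of a 64-bin histogram over
   the sample range, mean of positive pixels (MPP; 0 with a flag when no
   positive values exist), population skewness and excess kurtosis (0 with
   a flag when the SD is 0).  6 scales x 6 statistics = 36 features in a
   fixed SSF-major order.
2. **Temporal (inter-slice) path.** Lung-parenchyma images (lung-masked,
   lung-window normalised, 256x256) are embedded per slice by the
   bottleneck of a convolutional auto-encoder trained unsupervised under
   mean squared reconstruction error; the per-case sequence, zero-padded to
   25 slices with a validity mask, passes through 3 transformer-encoder
   stacks with fixed sinusoidal positional encoding, masked global max
   pooling (padded positions are excluded from attention keys and from the
   pool, so padding is exactly inert), and a 32-unit rectified MLP.
3. **Spatial (within-slice) path.** Nodule patches (tight mask bounding box
   + 8 px margin, normalised, zero-padded symmetrically to 224x224) pass
   through a four-stage shifted-window attention hierarchy with 4x4 patch
   embedding and patch merging between stages; the spatially averaged
   stage-4 map is the slice feature and subject-level global max pooling
   gives one vector per case.

The three features are z-scored with training-fold statistics, linearly
projected (no bias) to a common dimension of 100, reshaped row-major to
10x10 maps, and fused by **criss-cross attention**: the radiomic map is Q,
the spatial map K and the temporal map V; for each position the affinity
against the H+W-1 K-positions in its row and column (centre counted once)
is softmax-normalised and used to aggregate V over the same set.  There is
no `1/sqrt(C)` scaling, no temperature and, by default, no residual term
(flag available).  The flattened fused map feeds a 2-unit dense layer with
softmax.  G2 is the positive class throughout.

## Evaluation protocol

Patient-level, class-stratified k-fold cross-validation.  Per fold: the
auto-encoder is pre-trained and fine-tuned on training-fold slices (during
fine-tuning only the bottleneck dense layers and the adjacent convolutions
update; all other weights stay bitwise unchanged); the temporal and spatial
encoders are trained with binary cross-entropy on training-fold cases;
feature z-scores and the fusion head are fitted on training-fold features
with early stopping on an internal 80/20 split; the test fold is scored
once.  Radiomics involves no fitting and is computed once per case.
Metrics: accuracy, sensitivity, specificity, precision, per-class F1
(ratios with zero denominators are reported as absent with a flag, never as
0), ROC/AUC by threshold sweep with trapezoidal integration (identical to
the Mann-Whitney rank statistic with half credit for ties), per-fold
mean +- SD and the coefficient of variation (100 x SD/mean of fold
accuracies).

## Synthetic phantoms

The generator emulates the structure of the cohort the method targets:
chest-like volumes (64x128x128 voxels, 2.0 mm slices, 0.7 mm in-plane) with
an elliptical soft-tissue body (0 HU) in air (-1000 HU), two ellipsoidal
lung fields (-800 HU plus ~20 HU smoothed parenchymal noise), and one
sub-3-cm nodule per case visible on 2-25 slices: a ground-glass region
(-500 HU) with an optional solid core (+20 HU), an in-plane boundary
modulated by a random low-order angular Fourier series, and additive
band-limited texture.  Intensities are clipped to [-1024, 400] HU.
Everything is deterministic at case and cohort level under a fixed seed.

Class effects (G2 > G1) are placed where invasiveness expresses on CT:

* coarse-band texture SD multiplier — `separable` preset 1.0 vs 2.5 on a
  40 HU base (the texture field is Gaussian-correlated at
  `6 mm / sqrt 2`, the correlation length with maximal power in the 6 mm
  LoG band, and extends into a 12 mm peri-nodular halo; without the halo,
  mask clipping suppresses nearly all coarse-band power in small nodules,
  mirroring peri-lesional parenchymal distortion of invasive lesions);
* boundary irregularity amplitude — 0.05 vs 0.18;
* solid-core fraction — 0.15 vs 0.55.

Presets: `separable` (above; the default study condition), `hard` (1.0/1.3,
0.06/0.09, 0.20/0.30) and `null` (identical classes; single-feature rank
AUC indistinguishable from 0.5).  Effect magnitudes are calibrated only
against the generator's own oracle — under the defaults the single
coarse-band SD feature separates classes with rank AUC >= 0.9 at 30 cases
per class, and the expected in-mask coarse-band SD rises strictly with the
multiplier.  The phantoms do not emulate airways, vessels, scanner
reconstruction kernels or annotation noise, so passing tests demonstrate
correctness and learnability of the pipeline, not clinical performance.

## Model scales and training budgets

The published protocol (the package's config defaults) assumes GPU-scale
training of an ImageNet-pretrained SWin-B backbone and an externally
pretrained auto-encoder.  This package trains everything from random
initialisation in (CPU-only) numpy, so all evaluation runs use a `reduced`
scale; the `full` scale is constructed and forward-tested at the published
dimensions (SWin-B depths 2/2/18/2, width 128, window 7; CAE filters
16/32/64/128/256, 256-d bottleneck; transformer width 256) and accepts
external weights through an npz hook.

Reduced scale: spatial backbone on 64-px downsampled patches, window 2,
width 32, depths 2/2/2/2, heads 1/2/4/8; auto-encoder on 128-px downsampled
lung images, filters 8/16/32/32/64, 64-d embedding (64-px input proved too
coarse for sub-centimetre nodule texture); temporal encoder width follows
the embedding.  Study budgets (`reduced_config()`): auto-encoder Adam 1e-3
x 6 epochs (batch 32) + fine-tune 1e-4 x 2; temporal encoder Adam 1e-3 x 60
epochs (batch 16, dropout 0.3); spatial AdamW 3e-4 x 20 epochs (batch 8,
weight decay 0.05, patience 6, dropout 0.1); fusion AdamW 1e-3 x 20 epochs
(batch 8, weight decay 0.05, patience 5) as published.  The two published
fine-tuning learning rates (1e-5, 1e-6) are raised because nothing is
pretrained here; batch sizes above 1 for the spatial stage and a linear
learning-rate warmup over the first 20 steps are required for stable
from-scratch training (see below).  The default study size — 60 phantoms,
5 folds — keeps a full run in minutes on one CPU while leaving at least
four test cases per fold and class.

## Numerical and design choices

* **Zero-padding tokens.** Nodule patches are mostly zero padding.  Tokens
  whose 4x4 pixel block is exactly zero have zero channel variance, which
  makes layer normalisation's backward pass explosive (amplification
  ~1/sqrt(eps) per layer) when training from random initialisation; a
  pretrained backbone never exposes this because its biases are nonzero.
  The backbone therefore masks padding tokens out of attention keys and the
  final pooling and keeps them exactly zero between blocks
  (`mask_padding=True`, switchable for ablation with pretrained weights).
  This also realises the assumption that the model assigns padding no
  attention — exactly rather than approximately.
* **Optimisation stability.** AdamW excludes biases and normalisation
  parameters from weight decay; gradients are clipped to global norm 5;
  classification heads start at zero weights (the chance-level loss
  plateau); the supervised stages ramp the learning rate linearly over
  their first 20 steps; Adam moments are kept in double precision (squared
  gradients can overflow the engine's single-precision compute dtype
  during transients).
* **Temporal input scale.** Auto-encoder embeddings are small relative to
  the O(1) positional code, so they are standardised per dimension with
  statistics fitted on the training fold's valid rows (padded rows stay
  exactly zero).  A row-local layer normalisation was rejected: it
  discards the embedding-magnitude information that carries part of the
  class signal.
* **Criss-cross index set.** The cross set has H+W-1 members with the
  centre counted once (the canonical criss-cross formulation); the batched
  implementation materialises H+W affinities with the duplicate centre
  masked to -inf before the softmax, which is algebraically identical.
* **Entropy binning.** 64 bins over the per-sample range, base-2 logs;
  population (not sample) moments, excess kurtosis.  The upstream texture
  software's exact binning is proprietary, so these conventions are fixed
  here so that tests are unambiguous.
* **Convolution boundaries.** Radiomic filtration pads reflectively
  (symmetric); kernels are point-symmetric so convolution equals
  correlation; FFT-based convolution is used with a brute-force per-pixel
  oracle in the tests.
* **Degenerate inputs.** Empty masks, single-class folds, all-padding
  patches, >25-slice sequences and undefined metric ratios all fail loudly
  or are flagged; nothing is silently coerced.
* **Ten-fold vs five-fold.** The cross-validation driver defaults to k=10
  (the published protocol); the study-scale runs use k=5 because 30 cases
  per class leave only 3 test cases per class per fold at k=10, making
  fold metrics too granular at desk scale.

## Known limitations

* Study-scale results quantify the pipeline on synthetic phantoms whose
  class signal is by construction strong and well-placed; they say nothing
  about performance on patient data.
* The fused prediction aggregates the *temporal* map (V) under
  radiomic-by-spatial attention, so fused accuracy is bounded in practice
  by the quality of the temporal path; this is a property of the published
  fusion design, not of this implementation.
* The morphological lung segmenter is a stand-in interface default; a
  trained segmenter can be registered as a plugin.
* Training the full-scale configurations from scratch is out of reach on a
  CPU; the hooks for external checkpoints exist but no checkpoints ship
  with the package.
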