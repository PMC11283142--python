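# Methods

## The problem and the approach

Binary image classifiers for small clinical datasets (hundreds of labeled
images) are data-starved. `fundex` enlarges a training set with synthetic
variants of its own images: an autoencoder abstracts each image to a
compact embedding, the embedding is perturbed in controlled ways, and the
decoder maps the perturbed embedding back to a realistic image. Because
the synthetic images stay close to the data manifold the codec has
learned, they add diversity without the hallucination risk of adversarial
or diffusion generators, which is exactly the regime where training data
are too scarce to fit those heavier generative models in the first place.

## Dual-level codec

* **Level 1 (patch codec).** Input images are tiled into non-overlapping
  12×12×3 patches, row-major; tiling is exactly invertible. The encoder is
  a residual contraction group (two blocks, 12→6→3 spatially, channels
  3→24→48) followed by a 3×3 full-support convolution to a 48-d vector.
  The decoder mirrors it with transposed convolutions and ends in a
  sigmoid, so reconstructions live in [0, 1]. Patches are encoded
  independently, so a patch's embedding does not depend on its grid
  position.
* **Level 2 (latent codec).** The 48×G×G latent grid (G = side/12) is
  contracted by residual blocks (channels doubling from 48) to a 2×2 map,
  then a full-support head convolution produces the embedding. The default
  embedding width is 16·G², i.e. 1024 for a 96×96 image — a fixed 3×
  compression of the latent grid at every size. The decoder mirrors the
  encoder. Grid sides must be powers of two (image sizes 12, 24, 48,
  96, …).
* **Blocks.** Contraction: 3×3 stride-2 convolution → leaky ReLU → 3×3
  convolution, summed with a 1×1 stride-2 projection of the input, then a
  final leaky ReLU (negative slope 0.01 throughout). Expansion: 4×4
  stride-2 transposed convolution → leaky ReLU → 3×3 convolution, summed
  with a 2×2 stride-2 transposed projection. These internal choices are
  pinned by shape constraints and standard residual design; the endpoint
  dimensions (48-d patch embedding, 48×8×8 latent, 1024-d composed
  embedding at 96×96) are the architecture's fixed points and are asserted
  exactly in tests. Parameter counts are pure functions of the channel
  configuration and are frozen by the suite.
* **Training.** Loss is the mean absolute error between a stage's input
  and its reconstruction; optimiser AdamW, lr 3e-4, weight decay 5e-7.
  Level 1 trains on raw patches; Level 2 trains on the frozen latents
  Level 1 produces (its MAE is in latent units — the direct analogue of
  the pixel loss one level up), and never updates Level-1 parameters; a
  `joint` mode fine-tunes both through the full pixel round-trip. Training
  runs a fixed step budget with per-step loss logging rather than early
  stopping; at desk scale (hundreds of steps on tens of images) validation
  machinery would add noise, not signal. Half-precision weight storage is
  an optional checkpoint flag, default off; all computation is
  double-precision. Initialisation is seeded (He-scaled normals), so runs
  are bit-reproducible.

## Perturbation and expansion

The perturbation operator applies to the composed (Level-2) embedding —
the framework's headline representation; perturbing the Level-1 latent
instead is a one-line variant but is not the default. Three kinds, all
seeded, all exactly the identity at magnitude 0:

* **additive-gaussian** (default σ = 4.0): add σ·N(0, I).
* **channel-scale** (default 2.0): multiply elementwise by 1 + m·U(−1, 1).
* **latent-interpolate** (default 0.8): blend toward the embedding of a
  random same-class training image.

Magnitudes were calibrated on fixture codecs. Trained embeddings have
standard deviation ≈ 2, and the decoder contracts off-manifold
perturbations back toward plausible images, so pixel-space deviation
saturates: the defaults produce synthetic-vs-source deviations of roughly
1.3–2.5× the codec's reconstruction error depending on kind (≈ 1.8× on
average). Pushing all kinds to 2–4× uniformly is not achievable without
magnitudes so large that the class signal — and with it the enhancement
effect — degrades; the chosen point favours label-preserving variation.

The expansion plan is fixed arithmetic: 3 candidates per real training
image, one third of the 3N candidates selected uniformly at random
(a single global draw, not stratified per image or per class), yielding
exactly N synthetics and a 100 % expansion. Synthetics inherit the source
label — the protocol supervises on expanded sets, so labels must carry
over — and record the source image id. A leakage audit before every
classifier run verifies that each synthetic's origin resolves inside the
training split.

## Classifier and evaluation

The downstream model is a patch-token vision transformer (learned
positional embeddings, pre-norm blocks, mean pooling, 2-class head).
The backbone is deliberately configurable — the object of study is the
training data, not the architecture: `toy` (dim 32, depth 2, heads 2,
patch 8) trains in seconds on a CPU and is used throughout the tests;
`full` builds a standard full-size variant (dim 768, depth 12, patch 16)
with the same code path. Recipe: resize to a uniform square (default 224,
tests use 24–32), intensities in [0, 1], AdamW lr 6e-4 / weight decay
6e-2, batch 16, cross-entropy with 0.1 label smoothing, fixed epochs with
the best-validation-AUC parameters retained when a validation set is
supplied. Class imbalance can be handled by majority downsampling or
inverse-frequency loss weights.

Evaluation reports AUC (Mann–Whitney, ties half), sensitivity and
specificity at a fixed 0.5 threshold on the predicted case probability
(Youden-optimal thresholding available and recorded in the report), the
2×2 confusion matrix, and 95 % confidence intervals from a stratified
percentile bootstrap (2000 resamples by default, seeded; coverage verified
≈ 95 % on binormal simulations in the suite). Percentile intervals on tiny
samples can exclude the point estimate by rounding; reports widen the
interval minimally so it always brackets the point.

The experiment driver holds one stratified 80/20 split fixed, trains the
codec on the training side only, and for each training fraction compares
baseline vs expanded arms on the byte-identical validation set. Fractional
subsamples are prefixes of one seeded permutation, so they are nested
across fractions under a shared seed. Every run writes a manifest with the
full configuration and a config hash.

## Fixture generator

Fixtures emulate square region-of-interest crops around the optic nerve
head: an anti-aliased bright disc (radius 0.32 of the side) on a dark
fundus-coloured background, a concentric brighter cup whose radius ratio
to the disc (the CDR) is drawn per class — controls N(0.35, 0.08²), cases
N(0.65, 0.08²), clipped to (0.05, 0.95) — plus up to ±2 px placement
jitter, three vessel-like dark lines, and additive Gaussian pixel noise
(σ = 0.04–0.05) clipped to [0, 1]. One root seed; each image derives its
generator from (seed, index), so content is order-independent. Region-of-
interest extraction on larger frames is a brightness-centroid crop — a
declared stand-in for model-based disc segmentation, valid because on
disc-like images the luminance centroid falls on the disc.

What the fixtures do *not* model: photographic vignetting and colour
variation between cameras, vessel topology, peripapillary atrophy,
co-morbid pathology, label noise. Passing tests therefore demonstrate that
the machinery is correct and that the enhancement effect operates when the
class signal is geometric and recoverable — not that any particular AUC
transfers to real fundus photographs.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: codecs train
for 500 (Level-1) + 300 (Level-2) steps on 64 images; the enhancement
experiment uses a 300-image fixture at 48×48 with 3 seeds and a 30 %
training fraction; protocol-arithmetic checks run the full pipeline on
12×12 images where reconstruction quality is irrelevant to the counted
quantities. Degenerate inputs are rejected loudly (odd spatial sides,
non-multiple image sizes, single-class training sets, empty datasets,
untrained codecs, non-finite losses). Ties in AUC are handled by midranks;
selection and splitting use `numpy` Generator streams keyed by explicit
seed lists, never global state.

## Known limitations

* The numpy autodiff core is single-threaded BLAS-bound; the full-scale
  transformer and 200k-iteration codec pretraining are constructible but
  not practically trainable here.
* The encoder is deterministic; a variational reading (stochastic
  embeddings with a regularised posterior) is a possible extension.
* Perturbation magnitudes are calibrated on fixtures; real datasets will
  need their own calibration of the deviation-to-reconstruction ratio.
* Level-2 independent training optimises latent-space MAE; images it was
  never composed with at pixel level may benefit from brief `joint`
  fine-tuning.
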