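# Methods

## The method in brief

`pslearn` implements pseudo-lesion segmentation (PS) self-supervised
pretraining for lesion classification in CT-like images. The idea: real
tumor annotations are expensive and noisy, but one can *insert* synthetic
tumor-mimicking blobs into unlabeled slices and thereby obtain a
segmentation task whose ground truth is pixel-perfect for free. An encoder
pretrained to segment these pseudo-lesions carries tumor-relevant visual
representations into a downstream classifier, which then needs far fewer
labeled images.

The pipeline has three steps:

1. **Pseudo-lesion generation and insertion.** A binary mask is composed
   as the union of 2–5 overlapping simple shapes (circles, rotated
   ellipses, convex polygons), smoothed by a morphological closing. The
   union of simple shapes produces "atypical" blobs that vary widely in
   silhouette — the point being variety, not organ-specific realism, which
   is deliberately avoided as poorly reproducible. The mask is placed
   inside the organ region of a slice and composited in as a hypodense
   intensity offset with a Gaussian-feathered margin.
2. **Pretext training.** A small encoder–decoder segments the inserted
   lesions (BCE + soft-Dice loss). A configurable fraction of examples
   are clean negatives so the network also learns to predict absence.
3. **Classification fine-tuning.** The pretrained encoder plus a global-
   pooling + linear head is trained end-to-end with cross-entropy on
   labeled slices; the comparison baseline is the identical recipe
   started from a random encoder.

## Pseudo-lesion model

- **Primitives.** Circle (radius r), ellipse (semi-axes a,b, rotation),
  convex polygon (5–9 vertices at jittered radii; the rasterized region is
  the hull of the vertices). The per-primitive "effective size" (radius /
  geometric-mean semi-axis / mean vertex radius) is drawn uniformly from
  `size_range`; kinds are drawn uniformly unless `kind_probs` is given.
- **Rasterization rule.** A pixel belongs to a primitive iff its integer
  center lies inside the closed analytic region. This makes the
  composition's union semantics exact: with smoothing disabled the
  emitted mask equals the OR of the independently rasterized recipe.
- **Connectivity by construction.** Each subsequent primitive's center is
  drawn from a dilation of the current union (radius = half the new
  primitive's inradius) and accepted only if the union stays 8-connected.
- **Bounds.** Compositions whose effective diameter (equal-area circle)
  leaves `[d_min, d_max]` are rejected and redrawn; 100 failed draws raise
  a `GenerationError` naming the configuration, surfacing infeasible
  configs instead of looping.

## Insertion model

The feather field is the Gaussian blur (zero-padded, truncation 4σ) of the
placed binary mask; the output is `input + α·Δ` with Δ drawn from
`delta_range` (default −60..−20 HU — hypodense, as pancreatic
adenocarcinoma typically enhances poorly against parenchyma). Outside the
truncation band α is exactly zero, so pixels there are bit-identical to
the source. The emitted supervision is the *hard* mask, not the feathered
field: the pretext stays a standard binary segmentation problem.

Placement enumerates every admissible center exactly (integer correlation
of the region mask with the lesion mask) and draws one uniformly; under
region-constrained placement a center is admissible when at least
`min_inside_fraction` (default 1.0) of lesion pixels fall inside the organ
region, under anywhere-in-body when the center lies in an automatic body
mask (threshold −500 HU, largest component, holes filled). An empty
admissible set raises a `PlacementError`; `build_ps_dataset` redraws the
lesion up to 10 times first, since a single large lesion may simply not
fit a small organ region.

## Phantoms

The phantom generator supplies the downstream task and all fixtures: body
ellipse (~50 HU) with a subcutaneous fat ring (−90 HU) on air (−1000 HU),
a brighter pancreas-like blob (110 HU, emulating portal-venous
enhancement) built from a low-order harmonic star shape, and — for the
cancer class — a feathered hypodense tumor blob placed fully inside the
pancreas. The optional benign class is a sharply bounded fluid-attenuation
(~5 HU) disc, mirroring a cystic lesion's appearance in contrast to the
ill-defined cancer. Correlated noise is white Gaussian noise blurred at
`noise_corr_scale` and rescaled back to the target sd.

The tumor's drawn diameter is preserved through placement (retries keep
the diameter fixed; only the blob shape and position are redrawn), so the
stage-proxy distribution matches the configured diameter distribution.
`stage_proxy` — effective diameter in mm — supports T-stage-like
stratified evaluation (≤20 mm T1-like, 20–40 mm T2-like).

What the phantoms do **not** emulate: anatomy beyond the three-tissue
layout, scanner-specific noise texture, contrast-phase dynamics, partial
volume effects, or inter-patient appearance variability. Passing tests on
phantoms therefore demonstrates the *mechanics* of the method (exact
supervision, transferability, the small-data benefit in a controlled
regime) — not clinical performance.

## Networks and training

The training stack is a compact, dependency-light NumPy network library
with explicit forward/backward passes (im2col convolutions, max-pooling,
nearest-neighbor upsampling, single-head scaled-dot-product attention,
layer norm), an Adam optimizer with cosine decay, and a deterministic
binary checkpoint format. Two encoder families stand in for the CNN and
transformer families at desk scale:

- `tinyunet-w{W}-l{L}` — U-shaped conv encoder (widths W, 2W, …; output
  stride 2^(L−1)) with a skip-connection decoder;
- `pyrattn-w{W}` — two-stage conv stem (output stride 4) followed by one
  self-attention block and one MLP block over the token grid, with a
  skip-free upsampling decoder.

Inputs are normalized with a fixed soft-tissue window (center 50 HU,
width 400 HU → [−0.5, 0.5]); no per-image statistics, so train and test
processing are identical by construction. Pretext loss is BCE + soft-Dice
with equal weights (the Dice term counteracts foreground/background
imbalance from small lesions). Weights are float32; every random draw
(init, shuffling, splits) flows from explicit seeds, and Adam iterates
parameters in sorted-name order, so training is bit-reproducible.

The classifier head pools the deepest feature map globally and applies a
linear layer. Max pooling is the default: a 4–12 px tumor activates only
a few positions of a 16×16 feature map, and averaging dilutes that signal
by roughly the map-to-lesion area ratio, whereas the max responds to one
strong activation anywhere. (Frozen-feature linear probes on the standard
benchmark scored ~0.60 with max pooling against ~0.46 with average
pooling at 10 labels; average pooling remains available via the head's
``pooling`` option.) Fine-tuning is end-to-end by default; a
``freeze_encoder`` flag and a ``warmup_epochs`` option (head-only epochs
before unfreezing) support ablations — a warmup probe did not improve the
pretrained arm on the standard benchmark, so the default stays at 0.

Best-epoch selection uses the validation metric (Dice for the pretext,
accuracy for the classifier) with ties resolved toward the *later* epoch:
on few-sample validation splits the metric is coarse, and preferring the
most-trained among equals avoids snapshotting near-initial weights.

Gradient correctness of every layer is verified against central finite
differences in the test suite (float64, relative error < 1e-6).

## Desk benchmarks

Two canonical 64×64 regimes (2 mm spacing — an abdominal field of view
scaled down fourfold) drive the package's own experiments:

- **easy**: noiseless, tumor Δ −70..−50 HU. Used for pretext-learnability
  and Grad-CAM checks.
- **standard**: correlated noise 15 HU, tumor Δ −60..−40 HU. Used for the
  labeled-fraction experiment.

The standard regime was *calibrated before freezing*: at Δ −45..−25 under
15 HU noise the 10%-fraction task (5 labeled slices per class) was
unlearnable for pretrained and baseline encoders alike — both at chance,
leaving the comparison without dynamic range. The contrast was moved to
the middle of the separability dial (the phantom module exposes exactly
this dial, and a monotonicity test pins it down) so that the downstream
task is learnable but noisy; the setting has not been revisited since.

Benchmark cohort sizes: 50 slices/class for training, 40/class held out;
the pretext pool is the 100 training slices × 2 insertions (200 examples,
25% clean negatives). Pretext training: 20 epochs, batch 8, lr 3e-3,
patience 6. Fine-tuning: 60 epochs, batch 4, lr 1e-3 — in the ~10-labeled-
slice regime the step count, not data passes, limits convergence, hence
small batches and many epochs. These sizes keep the full suite and the
acceptance script within a desktop-CPU budget; they are the package's
chosen study conditions, stated here once.

## Evaluation

- **Clopper–Pearson.** Exact binomial CI via Beta quantiles:
  lower = Q_Beta(α/2; x, n−x+1) (0 at x=0), upper = Q_Beta(1−α/2; x+1, n−x)
  (1 at x=n). Equivalence with direct binomial-tail inversion is asserted
  to 1e-9 for all n ≤ 40. Each proportion's CI uses its own denominator.
- **Undefined ratios** (e.g. precision with no positive predictions) are
  reported absent-with-reason, never zero-filled — zero-filling corrupts
  averages.
- **AUC** is the Mann–Whitney statistic with midrank ties (computed via
  scikit-learn; an exhaustive pair-counting oracle cross-checks it in the
  tests). No CI is attached to AUC: the exact-interval machinery covers
  proportions only.
- **Grad-CAM** targets the last encoder feature map in both families:
  channel weights are the spatially pooled gradients of the target-class
  *softmax probability* (whose gradient contrasts the target against the
  other classes; a raw-logit gradient keeps a class-agnostic component
  that measurably blurs localization), and the rectified weighted sum is
  bilinearly upsampled and max-normalized (an all-zero map stays
  all-zero).
- **Stratified accuracy** partitions cases into no-tumor plus
  tumor-size bins; a count-weighted mean of stratum accuracies equals the
  overall accuracy (asserted), and empty strata report absent-with-reason.

## Numerical and degenerate-case choices

- Dice of two empty masks is 1.0 (an all-negative example predicted clean
  is a perfect prediction).
- The rasterizer's inclusive boundary (≤) makes tiny primitives (r ≥ 1)
  reliably nonempty; configurations with sub-pixel primitives are
  rejected at validation.
- `subsample_training_set` uses one seeded permutation per class with
  round-half-up counts, so subsets at increasing fractions are nested —
  the fraction curve is monotone-comparable across fractions.
- The two experiment conditions differ only in encoder initialization:
  identical subsample, seed, and schedule.
- Checkpoints are a JSON-header + raw-buffer container (no timestamps),
  so identical states give identical bytes and every CLI stage is
  byte-deterministic under a fixed seed.

## Known limitations

- Phantom realism as above; absolute accuracies here say nothing about
  clinical data.
- The pretraining benefit is measured as a mean over 5 paired seeds at
  the smallest fraction; individual seeds can go either way — the
  variance of 10-labeled-slice fine-tuning is intrinsically large.
- The NumPy stack is CPU-only and sized for ≤128-px rasters; it is a
  reference implementation of the method, not a performance substrate.
- Per-slice classification only: the package has no notion of patients,
  so patient-level aggregation is out of scope.
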