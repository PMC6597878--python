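# Methods

This document records what the package models, the parameter defaults and
the reasoning behind them, the numerical choices in the hand-rolled
network engine, and the known limitations.

## Pipeline model

The package implements the classical two-branch mitosis pipeline for H&E
high-power fields:

```
frames ── color normalization ── blue-ratio candidate detection ──┬── 71×71×3 patches ── CNN classifier
                                                                  └── 128×128×4 patches ── encoder–decoder segmenter
```

### Color normalization (`mitoscope.stain`)

Per-channel statistics transfer in CIE L\*a\*b\* (D65 white point, via
scikit-image), with Reinhard's original lαβ log-opponent space available
through `space="lalphabeta"`. Decisions:

- **Population variance (ddof = 0)** everywhere. The convention is
  declared and tested; with frame-sized pixel counts the choice is
  numerically irrelevant but must be consistent between source and target.
- **Pooled-pixel target moments.** The target statistics of a frame
  collection are the moments of the union of all pixels (computed exactly
  from per-frame sums and sums of squares), *not* the moments of an
  averaged image. Averaging frames first would collapse σ_t toward zero
  and produce washed-out output.
- **Single global target** per run. Per-class or per-region targets are
  out of scope.
- **Gamut clipping** on the way back to RGB. The statistics-recovery
  invariant (post-normalization std within 5 % of target) is only
  guaranteed in a low-clipping regime (< 1 % of pixels clipped); the test
  suite verifies it on a low-noise scene configuration for that reason.

### Candidate detection (`mitoscope.candidates`)

Blue-ratio transform with constants (c₁, c₂) = (100, 256), threshold
T = 30 (inclusive: `BR ≥ T`), opening with a radius-1 disk (the 3×3
cross), 8-connected component labeling, unweighted component centroids.
These defaults are part of the published recipe and are fixed before any
outcome was observed; the test suite checks *monotonicity* in threshold
and minimum area rather than tuning them.

Candidate↔truth matching for recall accounting is greedy one-to-one
nearest-distance matching with a 12-pixel tolerance (roughly one nuclear
radius at the synthetic scale).

### Patch corpora (`mitoscope.patches`)

- Classification patches are 71×71×3, cut from normalized frames with
  reflective padding at borders; the candidate centroid maps to the
  center pixel (index 35, 35).
- Rotation augmentation uses 0°/45°/90°/180°. Right-angle rotations are
  exact (`np.rot90`); 45° is bilinear resampling about the patch center
  with reflection fill.
- **Leakage rule:** splits are computed on un-augmented source patches;
  every rotated copy inherits its source's split part. This is tested.
- **Hold-out-then-balance:** the test set is held out per class first,
  then the majority class of the remainder is down-sampled to the
  minority count. With the published corpus sizes (1273 mitotic = 327
  true + 946 look-alike, 3585 non-mitotic; hold-outs 197 and 701) this
  yields exactly 2 × 1076 = 2152 training-pool patches.
- Splits are stratified per class with largest-remainder apportionment,
  assumed (and documented here) because the source recipe does not state
  the splitting scheme.
- Segmentation patches are 128×128×4 (R, G, B, blue-ratio on the [0, 255]
  scale) with a two-layer boolean mask (mitotic cell, non-mitotic cell).

### Networks (`mitoscope.models`, `mitoscope.nn`)

No deep-learning framework is available in the supported environment, so
the package ships a small NumPy engine: NHWC float32 tensors, 'same'
padding, explicit forward/backward passes per layer, all gradient-checked
against central finite differences.

- Convolution is computed as a sum of k² shifted matrix products (one
  contiguous GEMM per kernel tap) rather than an im2col buffer; this is
  the fastest formulation measured for these shapes on one core and is
  exactly equivalent.
- Max pooling is 2×2 stride 2 with one-hot argmax routing in the backward
  pass; odd trailing rows/columns are dropped.
- Upsampling is nearest-neighbour 2×; its backward pass is the exact
  adjoint (window sum).
- Dropout is inverted (scaled at train time) with its own seeded
  generator, so a fixed build seed reproduces the mask sequence.
- The classifier's first layer subtracts a fixed 0.5 from the [0, 1]
  inputs (`Center`). All-positive inputs made SGD training of the deep
  stack unstable; fixed centering removes that failure mode without
  touching the "divide by 255 exactly once" contract and without any
  data-dependent statistics.
- Losses: softmax cross-entropy (classifier) and log-sum-exp-stable
  per-pixel sigmoid binary cross-entropy summed over both mask channels
  (segmenter).

Architectures:

- **Classifier** (AlexNet-style): five convolutional stages
  (96, 256, 384, 384, 256 channels; 7×7 stride 2 + pool, 5×5 + pool,
  three 3×3 with a final pool) and two 4096-unit dense layers with
  dropout 0.5, two-way softmax head. A `width_multiplier` scales every
  width; the **desk preset** is 0.25 (conv 24–96 channels, dense 1024),
  chosen by this package so training fits in CPU minutes.
- **Segmenter** (U-Net-style): depth-4 encoder–decoder, skip
  concatenation per level, doubling widths from `base_width`, bottleneck
  at 2× the deepest width, 1×1 output convolution to two logit maps.
  Full-size base width is 64; the **desk preset** is 8.

The desk presets are this package's own reduced problem sizes for
verification; they are not published configurations.

### Training (`mitoscope.train`)

- Classifier: SGD, momentum 0.9, batch 128, learning rate 0.01 with step
  decay ×0.1 at epochs 33 and 66 (the published recipe for a 100-epoch
  budget).
- Segmenter: Adam, batch size 1, learning rate 10⁻³. Where the source
  material is contradictory about the preferred optimizer, this package
  rules in favor of Adam for the segmenter (its configuration is also the
  one with a complete hyperparameter description); SGD remains available.
- **Checkpoint-restore early stopping:** after every epoch the validation
  loss is computed; the weights of the minimum-validation-loss epoch are
  kept and restored at the end. Patience (default 10 epochs without
  improvement) bounds the run. This mechanizes the retrospective
  "take the weights from the best epoch" procedure.
- Inputs are stored on the [0, 255] scale and divided by 255 exactly once
  in `prepare_inputs`.
- All randomness (initialization, shuffling, dropout) flows from the
  config seed; single-threaded runs are bit-reproducible.

### Metrics (`mitoscope.metrics`)

Accuracy, sensitivity, specificity, precision, F1 from a binary confusion
matrix with *mitosis* as the positive class; zero denominators report 0
with a `RuntimeWarning` and a `degenerate` flag. The Dice index is
`2|Ŷ∩Y| / (|Ŷ| + |Y|)` with the both-empty case defined as 1.0. The
factor of 2 is standard; a printed variant formula without it is bounded
by 0.5 and is kept only as an auditing option (`factor_two=False`).
Segmentation evaluation reports mean per-patch Dice on the thresholded
(0.5) mitosis channel plus pixel accuracy over both binarized channels.

## Synthetic generator: what it does and does not emulate

Emulated:

- Two nucleus classes with distinct H&E-like palettes; mitotic nuclei are
  darker and more blue-dominant, so the blue-ratio transform separates
  them from stroma by a wide margin (mean BR ≈ 130–145 for mitotic
  figures vs ≈ 23 for stroma at default settings).
- Irregular star-convex nucleus shapes (inward-dented ellipses; mitotic
  figures get stronger dents, mimicking condensed-chromatin irregularity).
- Inter-frame stain variation (global per-frame color shift), per-nucleus
  color jitter, and pixel texture noise.
- Non-overlapping placement with a minimum separation larger than two
  maximum radii, so ground-truth components are unambiguous.

Not emulated: tissue architecture (glands, ducts, fat), out-of-focus
blur, scanner compression artifacts, touching/overlapping nuclei,
apoptotic look-alikes with genuinely ambiguous morphology, and class
imbalance at realistic rates. Consequently the synthetic task is *easier*
than real mitosis detection; quality bars on it verify the pipeline's
mechanics (wiring, leakage-freedom, optimization, determinism), not
clinical performance.

## Parameter defaults

| parameter | default | rationale |
|---|---|---|
| blue-ratio constants | (100, 256) | published recipe |
| detection threshold | 30 (inclusive) | published recipe; inclusive chosen and documented |
| opening radius | 1 (disk) | published recipe |
| connectivity | 8 | published recipe |
| classification patch | 71×71×3 | published recipe |
| segmentation patch | 128×128×4 | published recipe |
| rotation angles | 0/45/90/180° | published recipe |
| match tolerance | 12 px | ≈ one nuclear radius at the synthetic scale |
| classifier SGD | lr 0.01, momentum 0.9, batch 128, decay ×0.1 @ 33/66 | published recipe |
| segmenter Adam | lr 1e-3, batch 1 | published recipe (see optimizer ruling above) |
| early-stop patience | 10 | package choice; bounds desk runs without biasing selection |
| scene palette (mitotic / non-mitotic / stroma) | (60,40,110) / (110,80,160) / (230,150,200) | chosen a priori for H&E-like separability; never adjusted after observing detector output |

## Open questions and rulings

- **Optimizer contradiction** → Adam for the segmenter, SGD for the
  classifier (each branch keeps the recipe that is completely specified
  for it).
- **Threshold comparison** → `BR ≥ T` (inclusive).
- **Stain target** → one global target per run.
- **Split scheme** → stratified with largest-remainder apportionment
  (assumed; not stated in the source recipe).
- **Segmentation accuracy** → pixel-wise over both binarized channels.
- **Dice** → factor-2 form; the un-doubled variant exists only for audit.

## Limitations

- The NumPy engine is single-threaded-deterministic but slow; full-size
  (multiplier 1.0 / base width 64) training is out of CPU reach. All
  quantitative verification uses the desk presets.
- 45° rotation resamples bilinearly, so rotated patches are not exact
  pixel permutations; tests therefore assert bit-exactness only for
  right-angle rotations.
- `lab2rgb` clips out-of-gamut pixels silently; statistics transfer onto
  extreme targets degrades gracefully but is only moment-exact in
  low-clipping regimes.
- The synthetic generator's difficulty is tunable but its easy default
  regime means near-perfect scores; it validates machinery, not clinical
  claims.
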