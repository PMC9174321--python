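# Methods

`hccmil` re-implements, as a reusable toolkit, a weakly supervised pipeline
for predicting recurrence risk from H&E histology slides: tiles are cut from
a slide, color-normalized, augmented with a soft nuclei-segmentation heatmap
as a fourth channel, scored individually by a lightweight convolutional
network, and pooled into a single slide-level risk score by a signed
generalized mean. A censored-survival evaluation stack (Kaplan–Meier,
log-rank, Cox, time-dependent ROC/accuracy, continuous NRI) quantifies how
well the resulting risk groups predict recurrence-free survival. Because no
clinical slides ship with the package, a synthetic-data module generates
nuclei-bearing tiles with ground-truth masks, labelled slide bags, and
proportional-hazards survival cohorts, so every stage is trainable and
testable end to end.

## The multiple-instance model

A slide is a *bag* of tiles carrying one binary outcome label; no tile-level
label exists. Each four-channel tile (R, G, B, nuclei heatmap) receives a
raw score `s_i` from the backbone. Bag aggregation is a signed p-norm,

    S = sign(T) |T|^(1/p),   T = Σ_i sign(s_i) |s_i|^p,   p = 3 by default,

which for non-negative scores is the plain `(Σ s_i^p)^(1/p)` of a
generalized mean without `1/n` normalization; an optional power-mean variant
divides `T` by the number of tiles. The exponent interpolates between the
sum (p = 1) and the maximum (p → ∞), keeping extreme tiles influential while
still averaging — the property that makes the pooling tolerant of tiles
whose content conflicts with the slide label. `S` is squashed by a sigmoid
into an activated score `a ∈ (0, 1)`; the slide is called high-risk when
`a > t` with `t = 0.4457` (ties go to the low-score class).

Training minimizes a cross-entropy on a piecewise-linear probability
transform of the activated score,

    p = ((t − a)/t + 1)·0.5        if a ≤ t
    p = (1 − (a − t)/(1 − t))·0.5  if a > t

(continuous, strictly decreasing, p(0) = 1, p(t) = 0.5, p(1) = 0), plus an
L2 penalty `α Σ w²` over all trainable weights with `α = 0.02`:

    L = −(1/N) Σ [y log p + (1 − y) log(1 − p)] + α Σ w².

Probabilities are clipped to `[1e−7, 1 − 1e−7]` before the logs. **Label
orientation:** since the transform maps high activated scores to low `p`,
the loss drives bags with `y = 1` toward low activated scores; throughout
the package `y = 1` means good outcome / low risk, and the reported risk
score of a slide is its activated score. Optimization is Adam with the
published schedule — initial learning rate 1e−4, halved every 10 epochs,
one bag per optimization step.

### Backbone

The per-tile scorer is a MobileNetV2-style network: a strided stem
convolution, inverted-residual bottleneck blocks (1×1 expand → 3×3 depthwise
→ 1×1 project, residual when shapes allow), global average pooling and a
single-unit linear head. The `standard` variant follows the published
MobileNetV2 plan at width 1.0 with a 4-channel stem (≈2.2 M parameters);
the `tiny` variant (3 stages, width ≈0.25) exists for CPU-scale training.

Two deliberate departures from the textbook topology:

- **GroupNorm instead of BatchNorm.** With one bag per step, batch
  statistics are computed across the tiles of a single bag, which couples
  the instances of the bag and diverges from inference-time running
  statistics; in experiments this inverted the learned score orientation
  between training and evaluation. GroupNorm is per-sample, identical in
  both modes, and standard practice at batch size 1.
- **Pooled-input head features.** Per-sample normalization discards each
  tile's absolute intensity levels, yet the absolute heatmap level (nuclei
  abundance) and mean stain tones are informative. The head therefore
  receives the four globally pooled input channels concatenated with the
  trunk features.

No pretraining is used: the 4-channel first layer breaks 3-channel
pretrained weights, so all parameters start from seeded Kaiming
initialization.

## Nuclei segmentation

A U-net (double 3×3 convolutions with GroupNorm and ReLU per level, 2×2
max-pooling down, nearest-neighbour upsampling with skip concatenation up,
per-pixel sigmoid) is trained with pure Dice loss

    L_dice = 1 − 2 (Σ p y + ε) / (Σ p + Σ y + ε),   ε = 1e−8.

An all-empty scene (Σp = Σy = 0) returns 0 by an explicit guard — the
printed ratio would give −1 there, and empty-vs-empty is perfect agreement.
Predictions stay soft everywhere downstream: the heatmap intentionally
carries graded information (cytoplasm, cell shape) beyond a binary nucleus
call. Defaults are depth 3 / 8 base channels for CPU runs (depth 4 / 16 is
the intended full-scale setting), Adam at 1e−3, horizontal/vertical flip
augmentation. Validation Dice is computed on soft predictions. GroupNorm is
load-bearing here: plain conv stacks under pure Dice loss repeatedly
collapsed into the empty-prediction attractor (sigmoid saturation at p ≈ 0
kills the gradient), while normalized blocks descend smoothly.

## Tiling and stain normalization

Tiles are cut on a regular grid (default stride = tile size, i.e.
non-overlapping); a tile is kept when at least 25 % of its pixels are
tissue, a pixel counting as tissue when its mean RGB is below 220. The
canonical geometry is 512 px at 0.25 µm/px resized bilinearly to 224 px
(mpp rescales to ≈0.571). Both thresholds are configuration knobs, since no
published filter rule exists to match.

Color normalization follows the structure-preserving stain-separation
approach: optical density `OD = −log10((I+1)/256)` is factorized over
tissue pixels into two non-negative unit-norm stain vectors (hematoxylin
first — the row with the larger normalized red-OD component, since
hematoxylin absorbs red/green) and sparse non-negative concentrations, via
L1-penalized NMF (sparsity weight 0.1 by default). Three estimator details
matter for reproducibility:

- The factorization input is a frequency-preserving 6 000-row resample of
  the *unique* pixel values, so the estimate depends only on the pixel
  distribution: duplicating a tile set, or tile size itself, cannot change
  the profile.
- The OD matrix is pre-scaled to unit median row norm before fitting,
  making the recovered vectors invariant to a global concentration scale.
- The NMF solution identifies the stain plane well but leaves a
  penalty-dependent tilt of a few degrees on the vectors; a deterministic
  extreme-ray refinement (0.2/99.8 angle percentiles around the circular
  mean direction within the plane) pins the cone edges, bringing recovery
  error on painted two-stain images under one degree.

Normalization re-expresses per-pixel concentrations (pseudoinverse least
squares, clipped at zero) under the reference basis after matching per-stain
99th-percentile concentration scales. White pixels have zero OD, hence zero
concentration, and remain white. The packaged reference profile is estimated
at run time from a synthetic Beer–Lambert-consistent reference tile painted
from the classic H&E OD vectors with seeded gamma concentrations — a pure
function of a fixed seed, so no image file ships.

## Survival evaluation

Kaplan–Meier estimation, log-rank tests and Cox proportional-hazards fits
(Efron tie handling, Wald intervals) are delegated to lifelines behind this
package's interfaces. Time-dependent discrimination uses the
cumulative-cases / dynamic-controls definition at horizon τ with
inverse-probability-of-censoring weights from the KM estimate of the
censoring distribution: cases observed at `T ≤ τ` weigh `1/G(T−)`, controls
with `T > τ` weigh `1/G(τ)`. AUC is the trapezoid over the weighted ROC
staircase (lexicographic ordering over tied FPR values makes it equal the
tie-corrected rank-sum statistic when no censoring precedes τ). The "best"
operating point maximizes the Youden index `Se + Sp − 1` (ties toward the
smallest cutoff); accuracy weights Se and Sp by the KM-estimated event
prevalence at τ, which is the censoring-consistent analogue of naïve
accuracy. Note that for a completely uninformative marker the accuracy *at
the Youden point* is not pinned at `max(π, 1−π)`: on a diagonal ROC the
Youden argmax is noise-driven, so only the one-sided bound (no better than
the majority rule) holds.

Category-free NRI at horizon τ is
`[P(up|event) − P(down|event)] + [P(down|non-event) − P(up|non-event)]`
with the same IPCW weighting and a seeded percentile bootstrap CI (1 000
resamples by default). No multiple-testing correction is applied anywhere.

## Synthetic data

The generator encodes the four histological axes that separate risk groups
in this application: nuclear size (atypia), nuclear darkness
(hyperchromasia), fibrous stroma, and immune-cell density. Nuclei are
rotated ellipses over an eosin-like textured background (additive Gaussian
noise, σ = 6); stroma is low-frequency oriented sinusoidal banding blended
into signal tiles with probability 0.6. Signal tiles draw large
(5–9 px major axis at 64 px tiles), eccentric (axis ratio 0.45–0.75), dark
(chromasia 170–240/255) nuclei and are depleted of immune cells; non-signal
tiles draw small round pale nuclei plus Poisson-distributed immune dots
(mean 4 per 64 px tile). The binary mask is 1 exactly on nucleus interiors,
immune cells included. A high-risk slide carries `ceil(signal_fraction ×
n_tiles)` signal tiles (default fraction 0.5, deliberately far from 1 so
that label-conflicting tiles exercise the MIL pooling); low-risk slides
carry none. Every tile records whether it is a signal tile, enabling
enrichment oracles for tile ranking.

Survival cohorts follow a Weibull proportional-hazards model
`S(t|x) = exp(−(t/scale)^shape · e^{β'x})` (shape 1.5, scale 24 months by
default) with a binary marker and an ordered stage factor; censoring is
uniform on `(0, c_max)` with `c_max` solved by bisection so the expected
censoring fraction hits the target (an unreachable target raises a
calibration error). The true linear predictor is recorded per subject.

What the generator does *not* emulate: photorealistic H&E texture, scanner
artifacts, stain variability across a cohort, spatial correlation between
tiles of a slide, and competing risks. Passing benchmarks on these
synthetics therefore demonstrates that the training loop, aggregation,
transform and evaluation machinery are correct and that the pipeline can
discover planted morphology — not that the classifier reaches any
particular clinical performance.

## Problem sizes and numerical choices

CPU-scale defaults keep every benchmark tractable on a single core: the
segmentation benchmark trains on 200 pairs of 64 px tiles for 10 epochs
(held-out soft Dice ≈ 0.88); the MIL benchmark trains the tiny backbone on
120 bags of 16 × 64 px tiles for 20 epochs (held-out bag accuracy 1.0 on 40
bags, chance-level under a null with no planted signal); the end-to-end
pipeline smoke configuration uses 20 slides of 8 × 32 px tiles. The
networks run on an in-package NumPy reverse-mode autodiff engine
(`hccmil._nn`) with shift-and-add convolutions (one BLAS tensordot per
kernel offset), verified against finite differences in the test suite; all
arithmetic is float32. The signed-root gradient is clamped at `|T| ≥ 1e−8`
to avoid the singularity at zero aggregate. Seeds flow from a single master
seed through `numpy.random.SeedSequence` spawning, and inference is
strictly deterministic (no dropout, per-sample normalization only).

## Known limitations

- The NumPy engine trains small networks in minutes but is not suited to
  ImageNet-scale backbones or 224 px × thousands-of-tiles cohorts.
- Per-pixel concentrations use clipped least squares rather than full
  non-negative least squares; for strongly overlapping stains an NNLS
  refinement would be more faithful.
- Repeat normalization to the same reference is stable to about one
  intensity unit, the floor set by 8-bit quantization and re-estimation.
- Cox fitting inherits lifelines' convergence criteria; degenerate designs
  (separation, constant covariates) raise rather than warn.
- The survival stack has no competing-risks or time-varying-covariate
  support; NRI confidence intervals are percentile bootstrap only.
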