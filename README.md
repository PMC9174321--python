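# hccmil

Weakly supervised recurrence-risk prediction from H&E histology slides,
rebuilt as a reusable, fully synthetic-testable toolkit.

Whole-slide images are far too large to classify directly, and outcome
labels exist per patient, not per image region. `hccmil` addresses this
with multiple-instance learning (MIL): a slide is a *bag* of tiles with a
single binary outcome label; a lightweight convolutional backbone
(MobileNetV2-style, 4 input channels — RGB plus a soft nuclei-segmentation
heatmap) scores each tile, and a signed generalized mean pools the scores,

    S = sign(T) |T|^(1/p),  T = Σᵢ sᵢᵖ,  p = 3,

keeping extreme tiles influential while averaging. `sigmoid(S)` is the
slide's risk score, thresholded at t = 0.4457. Training minimizes a
cross-entropy on a piecewise-linear probability transform of the activated
score with L2 regularization (α = 0.02), Adam at 1e-4 halving every 10
epochs, one bag per step. The nuclei heatmap comes from a U-net trained
with Dice loss (ε = 1e-8) and is deliberately left soft. Around the
classifier sit the standard pipeline stages (grid tiling with background
filtering, Vahadane-style sparse-NMF stain normalization) and the
censored-survival statistics used to validate risk groups: Kaplan-Meier,
log-rank, Cox PH, time-dependent ROC/accuracy at the best Youden index
(IPCW, cumulative/dynamic), and censoring-adjusted category-free NRI with
bootstrap CIs.

The package is aimed at computational-pathology researchers who want to
train or evaluate this family of pipelines end to end without access to
clinical cohorts: a first-class synthetic module generates nuclei tiles
with ground-truth masks (atypia, hyperchromasia, stroma, immune density as
controllable axes), labelled slide bags, and Weibull proportional-hazards
survival cohorts. The neural networks run on a compact NumPy autodiff
engine bundled with the package, so everything trains on one CPU core in
minutes.

## Worked example

Train the MIL classifier on 120 synthetic slide bags (16 tiles of 64 px,
half of the tiles in a high-risk slide carrying the high-risk morphology)
and score 40 held-out bags:

```python
from hccmil.mil import MILConfig, train_mil, predict_slide
from hccmil.simulate import SlideSimConfig, generate_cohort_bags

cfg = SlideSimConfig(n_tiles=16, tile_size=64, signal_fraction=0.5, seed=11)
train_bags = generate_cohort_bags(60, cfg, seed=100)
test_bags  = generate_cohort_bags(20, cfg, seed=200)

handle = train_mil(train_bags, MILConfig(epochs=20, seed=0))
sc = predict_slide(handle, test_bags[0])
print(f"{sc.slide_id}: risk score {sc.activated:.3f} -> "
      f"{'high' if sc.predicted_class else 'low'} risk")
acc = sum(predict_slide(handle, b).predicted_class == (1 - b.label)
          for b in test_bags) / len(test_bags)
print(f"held-out bag accuracy: {acc:.2f}")
```

```
slide-high-0000: risk score 0.622 -> high risk
held-out bag accuracy: 1.00
```

The risk score is the sigmoid-activated aggregate; scores above 0.4457
classify a slide as high risk (bag labels use y = 1 for good outcome, so a
correct prediction is `predicted_class == 1 - label`). On this synthetic
cohort the planted morphology is fully recoverable, hence accuracy 1.00;
with `signal_fraction=0` the same training stays at chance.

Evaluating a risk marker against recurrence-free survival:

```python
from hccmil.simulate import SurvivalSimConfig, generate_survival_cohort
from hccmil.survival import TimeGrid, cox_fit, stratify_and_tabulate
import math

coh = generate_survival_cohort(SurvivalSimConfig(
    n_subjects=500, log_hazard_ratios={"marker": math.log(2)}, seed=7))
print(cox_fit(coh, ["marker"]).round(3))
table = stratify_and_tabulate(coh, ["marker"], TimeGrid((12.0, 24.0)),
                              n_bootstrap=200, seed=0)
print(table[["marker", "tau", "accuracy", "auc"]].round(3))
```

```
              hr  ci_low  ci_high    p   coef
covariate
marker     2.129   1.708    2.653  0.0  0.755
   marker   tau  accuracy    auc
0  marker  12.0     0.604  0.611
1  marker  24.0     0.635  0.660
```

The Cox fit recovers the simulated hazard ratio of 2; the per-horizon table
is the machine-readable analogue of a time-dependent accuracy/AUC results
table (a single binary marker with HR 2 yields modest discrimination, as
expected).

A CLI mirrors the library (`hccmil simulate|tile|normalize|train-seg|
segment|train-mil|predict|rank-tiles|evaluate|run`); `hccmil run --seed 1
--out runs/demo` executes the whole synthetic pipeline and writes
predictions, per-horizon metric tables and a run manifest.

## Layout

- `hccmil.simulate` — synthetic tiles/masks, slide bags, survival cohorts
- `hccmil.tiles` — grid tiling, background filtering, resizing
- `hccmil.stain` — OD conversion, sparse-NMF stain estimation, normalization
- `hccmil.segmentation` — Dice loss, U-net, training, heatmap prediction
- `hccmil.mil` — 4-channel assembly, backbone, aggregation, transform,
  loss, training loop, slide prediction, tile ranking
- `hccmil.survival` — KM, log-rank, Cox, time-dependent ROC/accuracy, NRI
- `hccmil.config` / `hccmil.pipeline` / `hccmil.cli` — YAML config,
  end-to-end runner with manifests, umbrella CLI
- `hccmil._nn` — the NumPy reverse-mode autodiff engine behind both networks

See `docs/methods.md` for the model details, parameter meanings, estimator
choices and known limitations.
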