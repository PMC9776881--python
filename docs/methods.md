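# Methods

`histofuzz` classifies RGB histopathology tiles into viable tumor (VT),
non-viable/necrotic tumor (NVT), and non-tumor (NT) through a five-stage
pipeline: CLAHE contrast enhancement, a depthwise-separable CNN feature
extractor trained with Adam, a linear feature projection, a first-order
Sugeno ANFIS classifier, and honey-badger optimization (HBO) of the fuzzy
membership functions. This note records the models, the defaults and why,
the numerical choices, and what the synthetic fixtures can and cannot show.

## Honey badger optimization

HBO minimizes an objective over a box by simulating a population of
badgers that alternate two moves around the current best solution
("prey"): a *digging* move, scaled by a smell intensity
`Int = r2 · SS / (4π d²)` where `SS` is the squared distance to the
circular-successor neighbor and `d` the distance to the prey, and a
*honey* move, a guided step `prey + Fg·r7·φ·d_vec`. The density factor
`φ = Cc·exp(−iter/iter_max)` decays exploration over time; `Fg = ±1` flips
the search direction with probability ½.

Choices the update rules do not themselves fix:

- **Phase choice** — an independent fair coin per badger per iteration;
  the two phases are described without any schedule.
- **Acceptance** — greedy: a candidate replaces a badger only when it
  improves that badger's fitness, and the prey is the running global best.
  This makes the prey-fitness history non-increasing by construction.
- **Vector quantities** — the intensity uses squared Euclidean norms;
  inside the position updates `d` is used as the raw displacement vector
  `prey − Y_j`, keeping the update vector-valued.
- **Neighbor of the last badger** — wraps around to the first (circular
  indexing), since no other total order is defined.
- **Singularities** — a badger sitting exactly on the prey would divide by
  zero in the intensity; the denominator carries an additive `1e-12`.
- **Bounds** — candidates are clipped to the box; iteration indexing for φ
  is 1-based so φ never equals `Cc` exactly.
- **Reproducibility** — one seeded generator per run, drawn in a fixed
  documented order (per badger: phase coin; digging: `r2 r3 r4 r5 r6`;
  honey: `r3 r7`), so runs are bit-reproducible and the whole iteration is
  testable against a straight-line transcription of the update formulas.

On the 5-D sphere over `[−10,10]⁵` with 30 badgers and 500 iterations the
median final fitness across 20 seeds is far below 1e-2 (the acceptance
script recomputes this).

## CLAHE

Classical tile-based construction: the image is divided into a
`grid_rows × grid_cols` partition; each tile's histogram is clipped at
`clip_limit × tile_pixels / n_bins` (the clip limit is expressed relative
to the uniform bin height so configurations transfer across tile sizes),
with the excess redistributed uniformly and iterated to a fixed point
(residual < 1e-3 counts) because a single pass can re-violate the clip.
Tile lookup tables are min-max scaled CDFs; each pixel output is the
bilinear blend of the four nearest tile tables with nearest-tile fallback
in the border band. Single-intensity tiles map identically, which keeps
constant images exact fixed points. RGB tiles are converted to YUV and
only luminance is equalized — equalizing channels independently shifts
stain hue. The lookup is applied as a delta on the unquantized intensity
so identity mappings are exact rather than accurate to half a gray level.
CLAHE is not idempotent and no test asserts it is.

Defaults (8×8 grid, clip 2.0, 256 bins, luminance-only) are conventional
values; none are prescribed by the classification task itself.

## CNN feature extractor

MobileNetV2-style: a 3×3 stem convolution, inverted residual bottlenecks
(1×1 expansion with ReLU, 3×3 depthwise convolution, linear 1×1
projection, skip when shape-preserving), global average pooling, a ReLU
FC layer whose activations are the extracted features, dropout, and a
linear softmax head. Depthwise separability cuts a k×k convolution's
parameters from `k²·Cin·Cout` to `k²·Cin + Cin·Cout`.

Two presets exist. `desk` (the default study scale) takes 64×64 tiles
through an 8-filter stem, a 2×2 max-pool, and 4 bottlenecks to a 16-dim
feature vector — trainable in well under a minute per 10 epochs on one
CPU. `full_scale` mirrors the full architecture (32-filter stem, 19
bottlenecks, 224×224 input); it is constructible and runnable but not
intended for CPU training, and no test trains it.

Everything is numpy: forwards by strided sliding windows, backwards by the
transposed window scheme, verified against nested-loop oracles and finite
differences. Adam is implemented from scratch with bias-correction
exponents `t+1` (`t` starting at 0), so the first step from a zero state
has magnitude `lr·|g|/(|g|+ε)`. The standard `√v̂` denominator is the
default; `literal_eq6=True` selects the variant without the square root,
kept for comparison because both forms circulate.

Training defaults at desk scale are learning rate 2e-3, dropout 0.25,
batch size 32, 30 epochs, chosen because Adam at 1e-2 reliably collapses
the 16-unit feature head of so small a network to dead ReLUs (loss pinned
at ln 3). Larger settings remain plain config. The loss is softmax
cross-entropy; training is deterministic under a fixed seed.

## ANFIS classifier

First-order Sugeno system over a full grid partition: Gaussian membership
functions `exp(−(x−c)²/2σ²)` (a smooth two-parameter family, convenient
for metaheuristic search), product rule strengths, normalization (with a
uniform fallback when the total mass underflows, so far-out-of-range test
points yield finite scores instead of NaN), linear consequents
`p·x₁+…+r`, and a weighted sum. Multi-class output keeps one consequent
set per class sharing the antecedents, with argmax decisions and
one-vs-rest scores for AUC.

Training is hybrid: HBO tunes only the antecedent centers and widths; for
each candidate the consequents are solved in closed form by least squares.
The classification fitness is the mean misclassification over 5 stratified
CV folds (seed-controlled), so the tuner targets generalization. Because
the grid partition has `m^d` rules, CNN features are first reduced to
`d = 4` inputs by a standardized PCA projection fit on training data (with
a deterministic sign convention on the components).

Search box: centers range over each input's observed `[min, max]`; widths
over `[0.25, 1.5]` multiples of each input's standard deviation. The
width floor is deliberately above tiny values: widths below ~0.25 std
yield near-crisp rules whose LSE designs are ill-conditioned and whose
fitness landscape is littered with spiky local minima; with the narrower
box the regression-recovery experiment succeeds across all tested seeds.

**Identifiability caveat.** With two Gaussian MFs per input the normalized
firing strengths depend on each input only through the log-ratio of the
two memberships — a quadratic with three coefficients determined by four
parameters. There is therefore an exact one-parameter family per input
(e.g. shrinking both centers toward their midpoint while narrowing the
widths) along which every firing strength, and hence every fitted model
output, is unchanged. Fitting data — noiseless or not — cannot pin the
centers themselves, only the gauge-invariant combinations; the recovery
experiment documents this: held-out RMSE goes below 0.05 while the center
estimates sit elsewhere on the ridge. With three or more MFs per input
the parameter count matches the coefficient count and the ambiguity
generically disappears.

## Synthetic tiles

The generator emulates a three-class osteosarcoma tile set, including a
preset with the benchmark's class imbalance (345 VT / 263 NVT / 536 NT =
1144). Class signal is deliberately carried by several channels — nucleus
density and size (soft-edged random ellipses), stain color, background
brightness, low-frequency texture — so both the CNN and the ANFIS stages
have learnable structure. Tiles are contrast-compressed toward mid-gray
(per-class factors 0.40–0.55) to exercise CLAHE, then finished with
Gaussian noise. Tiles are 64×64 by default (desk scale, not the source
material's native resolution). The generator is byte-deterministic under
its seed, and tests verify that the emitted class statistics separate by
more than 3 pooled standard errors, i.e. the generator realizes its own
parameters.

What the fixtures do *not* show: real H&E variability (stain batch
effects, tissue architecture, artifacts), so passing tests demonstrate
pipeline correctness and learnability, not clinical performance. In
particular, on these fixtures CLAHE is not beneficial to accuracy — the
class-dependent contrast level is itself a cue and the CNN is
contrast-robust — so no test asserts a CLAHE accuracy gain; on real
stains the enhancement serves visualization and robustness goals the
fixtures cannot emulate.

## Evaluation

Stratified splits draw `round(f·n_k)` training tiles per class (half away
from zero, both sides kept non-empty), deterministic under seed. Metrics
follow the one-vs-rest convention per class: binary accuracy `(TP+TN)/N`
(which is why per-class accuracy differs from overall accuracy),
precision, recall, F1, Matthews correlation (0 when a marginal is empty),
and AUC on per-sample min-max normalized scores. The "average" row is the
unweighted macro mean; classes absent from the test set are excluded from
it with a warning. A definitional oracle recomputes every metric from the
confusion matrix in the tests.

The pipeline fans one master seed out to stage seeds via a
splitmix64-style hash of the stage name, so stages can be rerun
independently and the report file is byte-identical across reruns.

## Problem sizes used

Default verification runs use 300 synthetic tiles (100 per class, 70/30
stratified split), the desk CNN, HBO with 15 badgers × 40 iterations for
MF tuning, and 20 seeds × 500 iterations for the sphere benchmark; the
regression-recovery and permutation-null experiments use 200-sample
feature sets. These sizes were chosen so a complete verification pass
runs comfortably on a single CPU while every stage still has enough data
to reach its expected behavior.
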