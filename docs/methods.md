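# Methods

## The optimization problem

The object being optimized is a transfer-learning training configuration:
which loss to minimize, which optimizer and batch size to train with, how
much dropout to apply before the softmax head, what percentage of backbone
layers to leave trainable, which per-image intensity scaler to use, and —
optionally — a stochastic data-augmentation policy (rotation, shifts, shear,
zoom, flips, brightness). All of it is encoded as one vector in `[0,1]^15`:

| idx | hyperparameter   | kind            | range / categories |
|-----|------------------|-----------------|--------------------|
| 1   | loss             | categorical (6) | categorical crossentropy, categorical hinge, KL divergence, Poisson, squared hinge, hinge |
| 2   | batch size       | stepped integer | 4–48 step 4 |
| 3   | dropout          | continuous      | [0, 0.6] |
| 4   | trainable-layer %| stepped integer | 1–100 step 1 |
| 5   | optimizer        | categorical (11)| Adam, NAdam, AdaGrad, AdaDelta, AdaMax, RMSProp, SGD, Ftrl, SGD Nesterov, RMSProp Centered, Adam AMSGrad |
| 6   | input scaler     | categorical (4) | Normalize, Standard, MinMax, MaxAbs |
| 7   | use augmentation | boolean         | yes / no |
| 8   | rotation         | stepped integer | 0–45° step 1 |
| 9–12| shifts/shear/zoom| continuous      | [0, 0.25] |
| 13–14| flips           | boolean         | yes / no |
| 15  | brightness range | interval        | [0.5, 2.0] |

Elements 8–15 are conditional on element 7; when augmentation is off the
effective dimension is 7, but the population always keeps 15 stored elements
so the optimizer never resizes mid-run.

Decoding is the linear rule `value = lower + v (upper − lower)` plus a
kind-specific discretisation, each chosen for determinism and full range
coverage:

* **stepped**: snap to the nearest grid point, ties toward the larger one;
* **categorical**: equal-width partition of `[0,1]` into K cells, last cell
  clamped so `v = 1` is valid;
* **boolean**: threshold at 0.5, upper-inclusive;
* **interval** (brightness): the decoded value is the interval *center* `c`;
  the emitted range is `[c(1−w), c(1+w)] ∩ [0.5, 2.0]` with half-width
  fraction `w = 0.05` by default. No published rule fixes the interval
  width, so it is an explicit, configurable choice.

Element 4 is read as the percentage of *trailing* backbone layers left
trainable (the rest frozen). The opposite reading — a freezing ratio — is
equally defensible from the source material, so the direction is a
documented switch (`trailing_trainable=False`). The stock range starts at
1%; a fully frozen backbone (0%) requires the explicit
`allow_zero_learn_ratio` space override.

The space serializes to and from a flat YAML document so ranges and category
lists can be edited without code changes.

## The optimizer

MRFO with population size `N_max = 10` and `T_max = 10` iterations by
default. One iteration scores every member, then runs the update sweep:
sort members by score descending (stable sort; ties keep member order),
extract the best, and per member draw `rand < 0.5` to pick cyclone vs chain
foraging. Cyclone exploration (anchor = fresh uniform random vector) is
taken when the phase draw exceeds `t/T_max`, exploitation (anchor =
incumbent best) otherwise; the first-ranked member references the anchor
itself, later members reference the already-updated previous member (the
sweep is in-place). Everyone is re-scored with greedy best tracking, then
somersaulted around the best and re-scored again. The best score therefore
never decreases, within or across iterations.

The weight coefficients are not pinned down in the describing text beyond
"weight coefficients"; this implementation uses the original MRFO
definitions `α = 2r√|ln r|` and `β = 2 e^{r₁(T_max−t+1)/T_max} sin(2πr₁)`,
with somersault factor `S = 2`; all three are configurable. The somersault
draws are treated as two independent uniforms `r₂, r₃`.

Numerical choices: solutions are clipped element-wise to `[0,1]` after every
move (decoding requires unit-interval inputs; no other boundary policy is
described); a member whose fitness evaluation raises keeps a `-inf` sentinel
score and the run continues with a logged warning; randomness derives from a
single master seed via one independent generator per
(iteration, member, sweep), so results are reproducible bit-for-bit and
independent of evaluation order. The draw order inside a member update is
fixed: branch draw, phase draw, reference vector (exploration only), then
`r`/`r₁`.

Each iteration costs ≈3 fitness evaluations per member (initial scoring plus
the two re-scoring passes). Because the update math operates on continuous
vectors whose decoded configuration often does not change, the
transfer-learning fitness memoizes scores keyed by the *decoded*
configuration; for a deterministic fitness this changes no result, it only
avoids retraining duplicates.

## The training objective

`TransferFitness` builds backbone → dropout → dense softmax head, trains it
for `epochs = 5` (default) at the decoded batch size with the decoded loss
and optimizer, and returns classification accuracy in `[0,1]`. The score is
computed on the held-out validation split by default. Scoring on the whole
dataset (train+val+test) is available behind `eval_split="whole"` because
some published workflows evaluate that way, but it leaks training data into
model selection and is deliberately not the default.

The training stack is implemented directly in numpy: feed-forward layers
with explicit backprop, the six losses computed on softmax outputs with
gradients propagated through the softmax analytically, and the eleven
optimizers as their standard update rules. Step sizes default to
desk-scale values (e.g. Adam 0.02, SGD 0.05, AdaDelta 1.0) — larger than
deep-learning library defaults on purpose, since the head is a small convex
problem trained for very few epochs. AdaDelta in particular warms up slowly
and can stay near chance after a single epoch; that is a property of the
update rule, not a defect.

Backbones come from a provider registry (`register_backbone(name, provider)`
with `provider(seed) -> Backbone`). The shipped `tiny-cnn` provider is a
pooled-feature network (8×8 block-average pool → dense 32 → dense 16, ReLU)
whose seeded random weights are a synthetic stand-in for pretrained
weights; it is sized so one evaluation takes milliseconds. Layer freezing
partitions the provider's ordered layer list exactly
(`ceil(ratio/100 · L)` trailing layers trainable). Full-size architecture
names can be registered by the user when a deep-learning backend is
available; nothing in the package or its tests downloads weights.

## Preprocessing

* **Resize**: bicubic to 128×128, RGB; grayscale replicated across
  channels (no other rule is given for single-channel input).
* **Scalers**: statistics are per image, not per dataset — the defining
  formulas are written on a single image and per-image application needs no
  global pass. Constant images make Standard and MinMax undefined; callers
  choose between an explicit degenerate-image error and a zero image.
* **Balancing**: every class is up-sampled to the majority count by drawing
  existing members with replacement and perturbing them with the *default*
  policy (rotation 30°, 20% shifts/shear/zoom, brightness [0.8, 1.2], both
  flips) — balancing happens before optimization, so it cannot use the
  solution-encoded policy. Originals are never removed. Balancing precedes
  the split by default (matching the published post-balancing totals of
  10,608 and 1,311 images); callers who want to avoid augmented
  near-duplicates crossing the split can balance the training portion only.
* **Split**: two-stage at 85/15 — test carved off first
  (`round_half_up(0.15 n)`), then validation off the remaining pool at the
  same fraction; stratified by class, seeded, with an unstratified fallback
  (and warning) when a class is too small. Rounding is half-up at each
  stage; only the ratio itself is prescribed.

## Metrics

Micro aggregation for multiclass confusion counts (per-class one-vs-rest
2×2 tables summed before any ratio): this choice exactly reproduces the
published three-class sensitivity and specificity values from the published
counts. Zero-denominator metrics are reported as undefined (`None`), never
silently 0. Values are kept at full precision internally; percent
formatting rounds half-up to two decimals at presentation only (97.7152% →
97.72%). Dice and F1 are both reported even though they are identical on
hard counts, because soft/probability-based variants of either are common
in the wild and the pair acts as an internal consistency check. AUC, IoU,
cosine similarity and the regression-error metrics are not implemented: no
count-based computing procedure exists for them, so they cannot be
validated against printed counts.

## Synthetic data

The generator renders class-distinct images: oriented sinusoidal stripes
(orientation and frequency are functions of the class index) plus a
class-dependent intensity offset in the top-left quadrant, plus Gaussian
pixel noise (default SD 10 on a 0–255 scale). Deliberately low-frequency
and high-contrast: a threshold on quadrant mean intensity, fit on half the
data, classifies the other half at ≥95% accuracy, which certifies the data
is learnable and keeps one-epoch end-to-end tests meaningful. Desk-scale
defaults for tests are 2 classes × 30 images at 32×32; pipeline defaults
generate at 128×128.

What passing tests show — and what they do not: the synthetic set
exercises every code path (decoding, training, augmentation, balancing,
splitting, scoring) and the optimizer demonstrably recovers known optima of
analytic objectives, but synthetic stripes say nothing about accuracy on
real histopathology or ultrasound data, whose class boundaries are not
linearly separable from one summary statistic. Reproducing published
benchmark accuracies requires the real Kaggle datasets, full-size
pretrained backbones and GPU-scale training, all outside this package's
test envelope. The published confusion-count tables are instead used as
fixtures: the metric suite recomputes their derived percentages exactly.

## Known limitations

* The numpy trainer is a faithful but small-scale objective; it does not
  implement convolutional fine-tuning of deep pretrained stacks.
* Augmentation uses bilinear warps; results differ at the interpolation
  level from other image libraries.
* The brightness-interval half-width and the optimizer step sizes are
  package choices (documented above), not externally prescribed values.
* Fitness evaluations are sequential; the design guarantees results are
  independent of evaluation order, but no parallel evaluator is provided.
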