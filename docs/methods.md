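# Methods

## Problem and data model

The package targets binary classification of gait recordings from people
with a unilateral vestibular deficit (vestibular schwannoma, the "patient"
class) versus healthy controls. A recording session yields, per subject and
walking task, six synchronized IMU streams (wrist, left/right ankle, waist,
upper back, head), each with six channels in a fixed order: anterior-
posterior, mediolateral and vertical linear acceleration, then pitch, roll
and yaw angular velocity. Trials are stored as self-describing delimited
text files (key:value header + six named columns, 17 significant digits so
float64 round-trips exactly) plus a cohort manifest. Accelerations are in
m/s², angular velocities in deg/s; units cancel under normalization but are
declared in the header. Recordings still in a sensor-local frame carry
`frame: local` and are rotated channel-triad-wise by user-supplied
orthonormal matrices (determinant +1 within 1e-6); rotation matrices are
accepted as inputs, never estimated.

## Gait-cycle segmentation

Cycles are defined as half-open sample intervals `[peak_i, peak_{i+1})`
between successive dominant positive peaks of the right-ankle pitch angular
velocity — the standard swing-phase event of a shank-mounted gyroscope. The
detector applies an optional moving average (default 0.05 s) to a working
copy of the pitch channel, thresholds peak prominence at a fraction
(default 0.3) of the signal's robust range (95th − 5th percentile), enforces
a minimum inter-peak distance, and then discards (never merges) cycles
outside a physiologic duration window (defaults 0.6–2.0 s). Incomplete
leading/trailing cycles are dropped. The stored cycle data are raw: only the
detector's working copy is smoothed, and no filtering beyond the final
down-sampling is applied.

Boundaries detected on the right ankle are applied verbatim to all six
placements of the same subject × task, which requires equal trial lengths
(hardware-synchronized or pre-aligned streams are assumed; a mismatch raises
an alignment error rather than being silently resampled). Each sliced
segment is resampled to 6 × 512 by piecewise-linear interpolation on a
closed endpoint grid — positions linearly spaced from the first to the last
original sample — so endpoints are preserved exactly, affine rows are
reproduced exactly, and a length-512 input is the identity. Cubic
interpolation is available and is used for the unsegmented activity-window
path.

Open design point: whether the original clinical pipeline segmented on
peaks, zero crossings or heel-strike events is not specified by our sources;
the dominant-peak convention implemented here is a documented stand-in with
all detector parameters configurable.

## Normalization

Per fold, per channel: `x → (x − min) / (max − min)` with the extrema taken
over every value of every *training* cycle. Training data map onto [0, 1]
exactly; held-out data may fall outside and are never clipped (clipping
would erase discriminative extremes). Degenerate channels (max = min) are
flagged and divided by 1. Per-channel ranges are the default because
accelerometer and gyroscope magnitudes differ by orders of magnitude; a
single global range is available via `mode="global"`.

## Classifier

Six parallel branches, one per input channel, with no weight sharing; each
branch is four blocks of `Conv1d(kernel 3, padding 1, stride 1) → ReLU →
BatchNorm1d → MaxPool1d(2, 2)`, taking the time axis 512 → 256 → 128 → 64 →
32. Branch outputs are flattened and concatenated (default width
6 × 64 × 32 = 12 288) and passed through two `Linear → ReLU → BatchNorm1d →
Dropout(0.5)` blocks to a single-unit affine layer and a logistic output.
Probability ≥ 0.5 predicts the patient class; the tie at exactly the
threshold counts as positive (a deterministic, documented convention). The
default filter counts (8/16/32/64) and dense widths (128/64) are
configuration, not fixed truths; both are fully adjustable via `ModelSpec`.

The network is implemented in numpy inside the package (`vestgait.nn`):
im2col convolutions with hand-written backpropagation, batch normalization
(biased batch statistics for normalization, running statistics with
momentum 0.1 for evaluation, ε = 1e-5), inverted dropout, He-normal
initialization seeded from `ModelSpec.seed`, and float32 arithmetic
throughout. The six branches are evaluated as stacked grouped operations
(one block-diagonal weight tensor per layer) purely for speed; the map is
exactly six independent convolutions, and the branch-independence property
(perturbing channel *j* changes only branch *j*'s features) is asserted in
the tests. Evaluation mode is deterministic and batch-size invariant because
dropout is inactive and batch-norm uses running statistics.

## Training

Binary cross-entropy on logits, Adam with the customary moments (0.9,
0.999, ε = 1e-8), 100 epochs, batch 64, initial learning rate 0.1 with a
step scheduler multiplying by 0.1 after every 25 epochs (epochs 1/26/51/76
run at 0.1/0.01/0.001/0.0001). No early stopping anywhere — fixed epoch
counts only. Shuffling is uniform per epoch under the config seed with no
class balancing; a trailing batch of one sample is folded into the previous
batch because batch normalization needs at least two values. A learning
rate of 0.1 is unusually high for Adam; it is implemented as stated, and an
optional global gradient-norm cap (off by default) is exposed for
small-fixture stability. Given a seed, data and config, a run is exactly
reproducible (pure numpy, all randomness via explicit generators).

## Transfer learning

`pretrain` fits the model on a source dataset and reports a cross-validated
source accuracy: grouped subject-level folds for segmented pathological
sources, stratified sample-level folds for the unsegmented activity-window
source (whose 3 s × 100 Hz windows are resampled to 512 points with cubic
interpolation; activity-window pretraining uses learning rate 0.001). The
checkpoint itself is trained on the full source. `finetune` restores a
checkpoint, freezes the convolutional stage — weights, biases, batch-norm
affine parameters *and* running statistics, with the branches run in eval
mode — and updates only the dense stage for 20 epochs. Freezing the
statistics along with the parameters is a deliberate choice so the frozen
stage is bit-identical before and after fine-tuning, which the tests assert
exactly. Checkpoints are single `.npz` archives holding the spec, all
parameters and buffers, the normalization parameters, and metadata, and are
version-stamped.

## Evaluation protocol

Paired leave-one-out cross-validation at the subject level: each group is
sorted by subject id and paired by rank (the pairing rule does not affect
which subjects are tested, only fold composition; it makes folds
deterministic). Each fold holds out one control and one patient, fits
normalization on the training cycles only, trains a fresh model (fold *f*
derives seeds as `seed + f`), and scores each held-out subject as the
fraction of their cycles classified with their true label — all cycles
retained, no per-subject capping. Group means are arithmetic means of
per-subject accuracies; the overall mean is the mean of the two group means
exactly. With unequal group sizes the leftovers of the larger group get
singleton folds plus a warning. A runtime assertion enforces that train and
test subject sets never intersect. F1 (2TP / (2TP + FP + FN)) is computed on
pooled cycle-level counts by default (a subject-averaged alternative was
considered; pooled counts are the documented choice), and flagged undefined
when the denominator is zero. Accuracy is evaluated in exact rational
arithmetic before the final float conversion; report tables round to 4
decimals for display.

## Synthetic cohort generator

Each subject draws a stride frequency (mean 1 Hz, SD 0.05 Hz) and a global
amplitude factor (1 + N(0, 0.1)); each cycle's duration is multiplied by a
lognormal jitter (σ = 0.02, mean-corrected so expected period is preserved;
the lognormal keeps periods positive — the true distributional shape of
inter-cycle variability is unknown and this is a stand-in). Channels are
sums of up to `n_harmonics` (default 3) sinusoids of the continuous stride
phase with a fixed deterministic phase table, scaled by base amplitudes
(acc 1.5–3 m/s², gyro 50–120 deg/s) and corrupted by white noise with SD
equal to 5% of the channel's base amplitude. The right-ankle pitch channel
is special-cased to a dominant first harmonic (peak at phase 0.25) with
small higher harmonics, guaranteeing exactly one dominant positive peak per
stride so segmentation is well posed.

The patient class multiplies selected channel amplitudes by
`1 + w · effect`: by default head pitch/roll are reduced (w = −1, emulating
restricted head motion), mediolateral trunk acceleration at waist and back
is increased (w = +1), and every placement carries a mild mediolateral
effect (w = +0.4) so each sensor has some signal. A
`group_variability_effect` multiplier scales the patient class's cycle
jitter. Age and sex are generated but carry no effect — the target cohorts
are age-matched, so the null fixture is too.

What the generator does **not** emulate: biomechanical coupling between
segments, asymmetry between affected/unaffected sides, non-stationarity
within a trial, task-dependent kinematic changes, or realistic sensor error
models (bias, drift, quantization). Passing tests therefore demonstrate
that the pipeline recovers planted amplitude/variability differences under
subject heterogeneity and noise — not clinical-grade performance.

A second generator emulates an unsegmented activity-recognition source: 3 s
single-sensor windows at 100 Hz in two classes distinguished by base
movement frequency (defaults 1.8 vs 3.0 Hz walking/running-like), with
random initial phase and 10% noise.

## Packaged study conditions

The property studies (`vestgait.studies`) run on cohorts of 8 subjects per
group with 8 s trials (~7 cycles per subject) and use a proportionally
scaled-down classifier (filters 4/8/16/32, dense 64/32 — same topology)
trained for 12 epochs of Adam at learning rate 0.01, batch 24. These are the
package's chosen problem sizes for small-cohort studies; the full-scale
defaults remain the published recipe. The amplitude-effect ladder is
none/weak/medium/strong = 0/0.10/0.25/0.50.

* **Chance study** — 10 seeds of LOOCV on zero-effect cohorts; the mean is
  compared to a 95% binomial band around 0.5 with one Bernoulli trial per
  held-out subject per seed (under the null a subject tends to be
  classified wholesale, so the subject — not the cycle — is the effective
  unit).
* **Effect ladder** — 3 seeds per rung at the head placement (which carries
  the strongest default effect); accuracy should be non-decreasing along
  the ladder within a small seed-averaging tolerance (0.03).
* **Ablation study** — subject-fraction ablation (25/50/75%, 5 iterations,
  iteration *i* seeded `seed + i`) on the fixture's best-performing sensor.
  The published design ablated the best sensor of its cohort; under the
  default effect map that is the head placement here. Sample-fraction
  ablation never drops a subject below one cycle, so per-subject accuracy
  stays defined.
* **Segmentation oracle** — with jitter, noise and all random effects
  zeroed, a 10 s trial at 1 stride/s has exactly 10 pitch peaks, so 9
  interior cycles must be detected for every subject, with identical
  counts at all six placements.
* **Freeze audit** — pretrain on activity windows, fine-tune on a strong
  cohort, and report the maximum absolute change over all convolutional-
  stage tensors (must be exactly 0).

## Numerical and degenerate-input choices

* Exact rational accuracy arithmetic; rounding only at display time.
* Constant segmentation signal ⇒ zero robust range ⇒ empty boundary list
  (not an error); subjects with zero cycles are flagged and excluded from
  accuracy means rather than scored 0.
* Degenerate normalization channels divide by 1 (flagged).
* Resampling requires at least 2 samples; batch norm at least 2 values.
* Checkpoint loading validates a format version and parameter shapes.

## Known limitations

* The numpy engine targets clarity and reproducibility over throughput; the
  full-scale recipe (100 epochs, 64-subject cohorts) is CPU-minutes per
  fold, so large sweeps should use the scaled-down spec or patience.
* Only conv stride 1 and pool kernel = stride are implemented — exactly the
  published topology.
* The synthetic generator's group effects are amplitude-based; phase- or
  waveform-shape effects are not modelled, so sensors differ in effect size
  only through the configured weights.
* LOOCV retrains one model per fold per placement; there is no warm
  starting across folds (by design, to keep folds independent).
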