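# Methods

`shuttlesense` classifies badminton activity from a 6-axis inertial sensor
mounted on the racket grip (tri-axial accelerometer in g, tri-axial
gyroscope in dps, nominally 100 Hz).  Nine classes are distinguished:
seven strokes — clear, dab, drive, short serve, lob, net drop, smash —
plus displacement (running) and rest.  This note records the models, the
conventions and the design decisions, and what the synthetic experiments
do and do not demonstrate.

## Signal conditioning and framing

Incoming streams are truncated to the sensors' physical ranges (±16 g,
±2000 dps) and may be decimated to 50, 25 or 12.5 Hz by plain
sample-dropping (keep indices 0, k, 2k, …).  No anti-alias filter is
applied: the classifiers learn raw signal patterns, and filtering would
alter the magnitudes they are meant to exploit.

Each modality is divided by one global constant — by default its
full-scale range, so inputs land in [−1, 1].  Per-frame or per-sample
normalisation is deliberately avoided: absolute magnitude carries class
information (a smash is more vigorous than a net drop), and only a global
scaling keeps magnitudes comparable across frames.

The stream is then cut into non-overlapping frames of fixed duration;
frame length is `L = round(frame_size_s * fs_hz)` samples (1.08 s at
25 Hz → 27 samples), the trailing partial window is dropped, and each
frame is labelled with the modal per-sample ground-truth label, ties
broken by earliest occurrence in the window (deterministic and
order-stable).  A 663,954-sample session at 100 Hz therefore yields
exactly 6639 one-second frames.

## Classifiers

Both architectures consume one raw scaled frame (L × C) and emit a
9-way softmax; hard predictions are the per-row argmax.

**CNN.** The frame is treated as a single-plane image: Conv(16 filters,
3×3, ReLU) → batch normalisation → dropout 10% → Conv(32, 3×3, ReLU) →
dropout 20% → flatten → dense(64, ReLU, L2 on weights and bias) →
dense(K, softmax).  Convolutions are valid (no padding) with unit
stride, so an 80×6 input produces 78×4×16 → 76×2×32 → 4864 → 64 → 9 and
316,809 trainable parameters.  The parameter total counts batch
normalisation as four vectors per channel (scale, shift, running mean,
running variance) — the convention under which the closed-form count
matches an enumeration of the realised model's tensors.  For
accelerometer-only input (C = 3) the second 3×3 valid convolution would
underflow the channel axis (3 → 1 → impossible); the second kernel
narrows to 3×1 in that case.

**DNN.** A convolution-free variant for low-cost deployments: dense
layers of width 1024 → 512 → 256 → 128 → 32 applied independently at
every timestep (20% dropout after each), flattened to L·32, then the
softmax layer.

The networks are implemented directly in NumPy (im2col convolutions,
analytic backward passes, Adam); the backward passes are verified against
finite differences in the test suite, and training is bit-reproducible
under a fixed seed.  Training defaults: Adam, learning rate 1e-3, batch
32, 50 epochs, 10% validation split, L2 coefficient 1e-4 on the dense
bottleneck — all overridable through `TrainConfig` or the estimator
parameters.  The synthetic studies below use 30 epochs and no validation
split.

## Multi-frame-size ensemble

Stroke durations span roughly 0.68 s (short serve) to 1.6 s (clear), so
no single frame size suits every class: short frames resolve boundaries
and short strokes, long frames capture the temporal structure of long
strokes.  The ensemble trains one classifier per frame size over the grid
0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6 s and fuses their outputs.

**Alignment.** Each model's per-frame softmax is broadcast to every
sample its frame covers, giving per-sample probability vectors on a
common grid.  The grid spans `T = max_m (n_frames_m · L_m)` samples; a
model whose complete frames end before T carries its last distribution
forward.

**Fusion.** Given per-(model, class) weights `w[m, i] ≥ 0`, two pooling
rules are provided.  The *weighted-certainty* rule scores class i at
position t as `max_m w[m, i] · p[m, t, i]` — the class some model asserts
with the highest weighted confidence.  The *averaging* rule replaces the
max with the mean over models.  The estimator defaults to averaging:
trained softmax outputs saturate near one-hot, so the max rule
degenerates into "whichever model is most overconfident wins" and, in our
experiments, scores below every individual bank member, while averaging
lets confident long-frame models resolve classes that short-frame models
see ambiguously and lets crisp short-frame votes fix boundaries.  Ties
break to the lowest class index; decisions are invariant to positive
rescaling of the weight matrix under both rules.

**Weights.** Uniform weights give the plain ensemble.  The
duration-matched strategy up-weights each class on the models whose frame
size is nearest the class's best frame size (defaults: clear 1.60, dab
1.08, drive 1.08, short serve 0.68, lob 1.28, net drop 1.20, smash
0.72 s; rest and displacement neutral) through a Gaussian kernel
`w[m, i] = 1 + β · exp(−(size_m − best_i)² / 2σ²)` with β = 1,
σ = 0.3 s.  The functional form is this package's choice — the principle
is only that classes should count most on duration-matched models — and
hand-specified weight matrices are accepted (CSV: rows = frame sizes,
columns = classes).

**Transition smoothing.** Misclassifications concentrate at activity
transitions, where fused confidence dips.  With threshold τ, positions
whose winning score falls below τ inherit the label of the nearest
confident position (earlier side on ties); τ = 0 disables smoothing and
is the default.

## Evaluation

Confusion matrices use rows = truth, columns = prediction.  Per-class
precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = 2PR/(P+R); classes with
a zero denominator are reported as 0 and flagged, so support-weighted
averages stay defined on sparse data.  Two accuracy readings are
exposed:

* **per-sample** — every sample on the alignment grid counts; boundary
  placement is charged to the classifier.  A model trained at frame size
  L cannot express label changes inside a frame, so per-sample accuracy
  of long-frame models is structurally capped; per-sample accuracies are
  comparable across models only because all are measured on the same
  grid.
* **per-event** — each maximal ground-truth segment counts once and is
  predicted by the modal fused label inside it.  This is the
  stroke-sequence reading (which activities were played, in order) and is
  the headline metric for the ensemble studies.

Fine classes can be merged into supersets before scoring: overhand
(clear, dab, net drop, smash) vs underhand (drive, short serve, lob), or
clear+smash into one overhead-power category.  Merging never decreases
accuracy — correct predictions stay correct and within-superset
confusions become correct — which the suite checks on random sequences.

## Synthetic data

No public dataset accompanies this problem setting, so the generator
produces recordings with the statistical structure the pipeline needs to
be testable end to end.

Each stroke is a train of motion-primitive pulses: Gaussian-windowed
sinusoids of fixed width (sd 0.08 s) spread over the stroke duration,
per-channel carrier frequency/phase and amplitude.  Class identity lives
in the pulse count, amplitude progression and total span.  Confusable
strokes share carriers, as real strokes share sub-movements: clear /
smash / drive share the overhead-power carrier (clear and smash also have
near-identical angular rates; the drive carries ~¼ of their gyro
amplitude, making it the accelerometer-similar, gyroscope-distinct
partner of the clear), and short serve / net drop share a soft
low-amplitude carrier.  A window much shorter than a stroke therefore
sees one pulse that looks alike across its group — which is exactly why
per-class best frame sizes exist and a multi-frame-size ensemble has
something to contribute.

Scenario generation concatenates strokes (counts per class default to a
realistic test session: 30–34 each), repositioning pauses of 1.0–2.5 s
labelled rest, and multi-second gait-like displacement bouts; white noise
is added (sd 0.05 g on accelerometer channels and 125× that on gyro
channels, comparable floors after full-scale scaling).  Every stroke
instance draws its own multiplicative vigour factor (sd 0.10) — no player
repeats a stroke identically — and its duration from a normal with sd 5%
of nominal.  An optional impact spike (1–3 samples on the accelerometer
y axis at ~60% of the burst) emulates shuttle contact; its height is set
to dominate the envelope's own sample-to-sample slope so that a
first-difference detector finds it.  A y-axis inversion transform is
provided for left-handed augmentation.

The two-subject split draws independent per-class amplitude and duration
factors (uniform ±jitter, default 10%) for subjects A and B.  Subject A's
training recording prepends drill blocks — back-to-back repetitions of
the same stroke with no idle time between them — to a varied scenario
with three times the configured counts (training sessions are several
times longer than a test scenario); subject B contributes a varied
scenario only, so every evaluation is strictly cross-subject.  A fixed
seed determines the output completely.

What the generator does **not** model: biomechanics (waveforms are
synthetic primitives, not measured kinematics), sensor-position effects
(wrist vs upper arm vs grip), drift, temperature, or realistic noise
spectra.  Passing tests therefore demonstrate that the pipeline recovers
class structure of the kind described — duration-coded, locally
ambiguous, subject-perturbed — not performance on real play.

## Study problem sizes

The end-to-end studies (in `shuttlesense.experiments`) run at sizes
chosen to keep a full pass in minutes on one CPU core: 10 strokes per
class in the test scenario, 10 drill repetitions, 30 epochs; the
ensemble and channel-ablation studies run at 25 Hz (the rate the
sampling-frequency trade-off favours), cross-subject recovery at 100 Hz
with 0.8 s frames.  The ensemble study compares the duration-weighted
averaged fusion against the best single bank member on per-event
accuracy over five seeds; the ablation study compares drive/clear pair
accuracy with and without the gyroscope channels at 1.2 s frames.

## Known limitations

* The max-rule fusion is sensitive to calibration; no temperature or
  calibration step is applied to the softmax outputs.
* Accelerometer-only operation changes the CNN's second kernel (3×1), so
  accel-only and full models have different parameter counts.
* Long-frame models' per-sample output cannot represent sub-frame label
  changes; per-sample metrics should be interpreted with the alignment
  granularity in mind.
* The impact-peak detector is a standalone analysis tool; its output is
  not fed back into classification.
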