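# Methods

`rteeg` re-implements, end to end, an affective-EEG analysis for
reminiscence-therapy conversations: older adults talk about old
photographs for one minute per trial while 8 channels of EEG are
recorded at 250 Hz, rate each conversation on pleasure, arousal and
stress, and a recurrent classifier is trained to recognize the resulting
positive/negative emotional state from the raw (filtered) signal. The
original recordings are not publicly deposited, so every stage runs on a
synthetic cohort whose statistical structure matches the study design;
the package's tests are therefore statements about the *pipeline* —
its arithmetic, its protocol, and its ability to recover a known injected
effect — not about real brains.

## Emotion labeling

Each trial's self-assessment is three integers: pleasure and arousal in
[−4, 4], stress in [1, 7]. Two labelings are implemented:

* **VA quadrants** — sign tests on (pleasure, arousal): (+,+) happy,
  (−,+) frightened, (−,−) boredom, (+,−) relaxed; a zero on either axis
  is `on_axis` and not distinguishable. In this population nearly all
  mass falls in the first quadrant and on the axes, which is why the
  binary scheme below replaces it.
* **PS rule** (used for classification) — *positive* iff pleasure > 0
  **and** stress ≤ 1; *negative* iff pleasure < 0 **or** stress > 2;
  anything else *excluded*. "Stress ≤ 1" is read on the integer scale as
  stress = 1, the scale minimum. Exhaustive enumeration of the
  9 × 9 × 7 = 567 rating cells gives 36 positive, 477 negative and 54
  excluded cells; the test suite re-derives this with an independent
  brute-force classifier.

With the default class mix (126/396, 69/396, 201/396) a stratified
396-trial cohort (11 subjects × 36 conversations) contains exactly 126
positive, 69 negative and 201 excluded trials, so 195 trials survive to
the modeling stage.

## Synthetic signal model

Each channel of a trial is the sum of four components, amplitudes in µV
RMS (defaults in parentheses):

* **1/f background** (5 µV, exponent 1): Gaussian noise spectrally
  shaped as f^(−β/2) above 1 Hz.
* **Band oscillations**: narrowband Gaussian noise in theta 4–8 Hz
  (4 µV), alpha 8–13 Hz (6 µV), beta 13–30 Hz (2.5 µV). The values give
  a realistic resting-adult spectrum with a prominent but not dominant
  alpha peak; total channel RMS lands near 22 µV.
* **Mains interference**: 60 Hz sinusoid (2 µV, random phase per
  channel) — the 60 Hz (Kansai) grid frequency.
* **Baseline drift**: band-limited noise below 0.3 Hz (20 µV),
  emulating slow electrode/skin potential wander.

The learnable class difference is a **lateralized alpha-power effect**,
chosen because the channels reported as most discriminative form lateral
pairs near the ears (F7/F8, T7/T8). For a positive trial the log-ratio
of alpha power on (F7, T7) versus (F8, T8) is +δ/2, for a negative trial
−δ/2, so the between-class difference of that log-ratio is the config
knob `effect_size` (δ, default 1.0, dimensionless). Excluded trials get
a half-strength effect with random laterality. Per-channel log-gain
jitter (SD 0.05) and a per-subject overall amplitude factor
(log-normal, SD 0.1) add trial- and subject-level variability. δ = 0
makes the classes identical by construction, which grounds the null
calibration tests. A Welch-periodogram oracle in the test suite recovers
δ within ±20% at δ = 1 and each band's RMS within 10%.

What the generator does **not** emulate: eye-blink/EMG artifact
morphology, volume-conduction correlation structure between channels,
non-stationarity within a trial, and any genuine neural correlate of
emotion. A high recovery accuracy on synthetic data therefore
demonstrates that the pipeline can extract a lateralized band-power
signal at realistic SNR — not that real conversations are classifiable.

## Preprocessing

Fixed order per trial: Butterworth band-pass 1–45 Hz, then Chebyshev-I
high-pass detrend at 0.5 Hz. Both are applied per channel as
second-order sections, forward–backward (zero phase): the analysis is
offline, and phase distortion would shift features across segment
boundaries. Causal application is available via `FilterSpec.zero_phase`.

Design values: band-pass order 6 — the lowest even order whose
effective (squared, zero-phase) response is ≥ 40 dB down at 60 Hz, which
is what lets the pipeline skip a separate mains notch; high-pass order
4, passband ripple 0.1 dB — small enough that the doubled ripple of
zero-phase application costs under ~5% of white-noise variance, with
0.5 Hz preserving the delta content the 1 Hz band edge already admits.
Amplitude assertions in the tests exclude 1 s of edge transient (2 s for
narrowband attenuation measurements, the decay time of the 1 Hz edge's
impulse response); the data itself is never trimmed.

## Dataset geometry

A 60-s trial at 250 Hz is 15,000 samples per channel and is cut into 20
contiguous, non-overlapping 3-s segments of 750 samples; concatenation
reconstructs the trial exactly, and any other length is an error rather
than a silent truncation. Assembly drops excluded trials, one-hot
encodes labels as (positive, negative), and selects a named channel
subset in canonical order: `full` (F3, F4, F7, F8, T7, T8, P3, P4),
`eyewear` (F7, F8, T7, T8) or `headband` (F3, F4, F7, F8). The on-disk
container is one HDF5 file (`data`, `labels`, `trial_ids`, montage/fs
attributes).

## Models

Both classifiers are three-layer recurrent stacks with (64, 32, 16)
units, dropout 0.2 after layers 1 and 2, and a 2-way softmax head under
categorical cross-entropy; the bidirectional variant runs each layer in
both time directions and concatenates the passes (doubling the width
seen downstream). Layers 1..n−1 return sequences; layer n returns its
final state. Gates use sigmoid, cell input/output tanh; kernels are
Glorot-uniform, recurrent kernels orthogonal, forget-gate bias 1.
Recurrent (within-cell) dropout is not implemented — dropout is plain
inter-layer. The engine is NumPy with full backpropagation through
time, verified against central finite differences; parameter layout
follows the usual convention so each LSTM layer holds 4((d + u + 1)u)
weights and the closed-form `count_parameters` matches every
constructed model.

## Training protocol

* **Instance granularity**: one 3-s segment (timesteps × channels)
  inheriting its trial's label. Folds are cut at the *trial* level so
  all 20 segments of a trial share a fold — this reproduces the printed
  split sizes (195 trials → validation 49, training 146) while
  preventing segment leakage. Trial-level majority-vote accuracy (ties
  toward positive) is reported alongside segment accuracy.
* **Cross-validation**: 4 random near-equal folds (unstratified by
  default, matching "randomly divided"; stratification by class is a
  flag). A leakage assertion runs on every fold.
* **Early stopping**: monitor validation loss, min_delta 0, patience 2,
  no weight restoration. T_i is the number of epochs fold i ran.
* **Epoch selection, two phases**: phase 1 early-stops each fold to get
  T1..T4; the selected epoch is max(T_i); phase 2 retrains each fold
  from scratch for exactly that many epochs, and the reported accuracy
  is the mean of phase-2 fold validation accuracies. Phase-1
  (early-stopped) accuracies are also retained, since which of the two
  the original protocol reports is ambiguous.
* **Standardization**: per-channel z-scoring with training-fold
  statistics (configurable off); raw µV magnitudes destabilize recurrent
  training.
* **Grid**: optimizers {SGD (plain), RMSprop, Adam} × learning rates
  {0.01, 0.001, 0.0001}, batch size 10 (20 for 4-channel sets). A cell
  is flagged "–" and its accuracy suppressed when its mean final
  validation loss exceeds 1 or it hits 100% validation accuracy within
  ≤ 5 epochs ("very few" fixed at 5, configurable).
* **Determinism**: one master seed drives fold shuffling, weight init,
  dropout masks and batch order through spawned child seeds; rerunning
  with the same seed reproduces every field of the result exactly.

## Reduced profiles and problem sizes

Full-scale training (195 trials × 20 segments × 750 timesteps,
(64, 32, 16) units) is expensive on a single CPU in NumPy, so the
package defines scaled-down profiles for validation and routine runs,
chosen once as the package's own desk-scale conditions:

* **Reduced** (default for `run_acceptance` and the recovery checks):
  60 trials (30/30 stratified positive/negative), segments decimated
  750 → 94 timesteps with `scipy.signal.decimate` (anti-aliased; factor
  8 keeps Nyquist at 15.6 Hz, above the 13 Hz upper alpha edge so the
  injected effect survives), two-layer Bi-LSTM (16, 8), batch 10, Adam
  1e-3, ≤ 10 epochs, fourfold CV. One such run takes a few minutes.
* **Micro** (determinism and protocol-property tests): 12 trials,
  decimation 9, (8, 4) units, 3 epochs — seconds per run.

Decimation factors above 9 would alias away the alpha band and destroy
the class signal; the profiles deliberately stay below that.

At the pinned seed the reduced profile recovers a strong injected effect
(δ = 1.5) at mean segment accuracy ≈ 0.97 (the acceptance threshold is
0.85), and at δ = 0 accuracy stays within the 95% binomial interval of
the majority baseline, computed with the trial count as the effective
sample size since the 20 segments of a trial are correlated. Accuracy is monotone in δ over {0, 0.5, 1.0,
1.5} in the protocol tests.

## Known limitations

* The synthetic effect is a single stationary band-power asymmetry; real
  affective EEG is weaker, non-stationary and subject-specific.
* Evaluation is subject-dependent (trials of one subject may appear in
  both training and validation), matching the study design;
  leave-subject-out generalization is out of scope.
* The NumPy engine trains small recurrent stacks adequately but is not a
  general deep-learning substrate (no GPU, no recurrent dropout, no
  gradient clipping).
* ICA artifact removal, re-referencing and bad-channel handling are
  deliberately absent from the cleaning stage.
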