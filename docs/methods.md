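# Methods

This note records the models, conventions and numerical choices behind
`somnaug`, and what the synthetic experiments do and do not demonstrate.

## Sleep-architecture summaries

Three quantities are derived from the in-bed clock times: time in bed
(TIB = end − start), sleep latency (SL = onset − start) and total sleep
time defined as **TST = TIB − SL**.  Wake after sleep onset is carried
as an annotation input and deliberately not subtracted from TST; this
matches the convention of the clinical summary table the module
reproduces, not the stricter polysomnographic TST definition.  Clock
arithmetic is at one-second resolution with a single midnight wrap
(end < start ⇒ +24 h) and output rounded to two decimals; TST is
computed from the rounded TIB and SL so the identity TIB = SL + TST is
exact after rounding.  Latency ≥ 20 min is flagged "prolonged".

## Synthetic EEG cohorts

Each subject's trace is the sum of five independent band-limited
Gaussian noise processes: white noise filtered with the same order-4
zero-phase Butterworth design the analysis chain uses, one filter per
band (delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–45 Hz),
each rescaled so its realized mean-square power equals the class target
exactly.  Default targets (µV²): delta 40, theta 12, beta 6, gamma 1.5
for both classes; alpha 4.0 (healthy) vs 6.4 (insomnia).

The alpha elevation is the planted class effect.  Its size was
calibrated once so that, after preprocessing and layer-1 augmentation,
the addition-set rows of the feature table separate the classes in
measured alpha band power by about two pooled within-class standard
deviations (realized Cohen's d ≈ 2.3 at the default 12-subject, 90 s,
three-segment conditions).  The calibration is stated at the level the
classifiers actually see because augmentation both dilutes the raw
subject-level separation (scaled-alpha rows) and adds spread.

Within a class, subjects differ only in their noise realizations — the
generator plants no per-subject power variability.  Consequently the
synthetic cohorts do **not** emulate inter-subject physiological
variability, age/medication effects, artifacts (unless configured),
non-stationarity across the night, or sleep-stage structure.  Passing
the end-to-end test shows the pipeline recovers a planted band-power
effect through both augmentation layers; it is not evidence about
clinical recordings.  Optional powerline (50 Hz) and baseline-drift
sinusoids can be mixed in for denoising tests; they are off by default.

Metadata: sleep start ~ U(21:30, 23:30), TIB ~ U(6 h, 9 h), sleep
latency U(25, 120) min for insomnia and U(1, 15) min for healthy
subjects, WASO wider for insomnia — values chosen to straddle the
20-minute latency criterion with margin on both sides.

Determinism: every subject's signal is drawn from
`SeedSequence([seed, group, subject_index])`, so cohorts are bit-identical
for a fixed spec and independent of generation order.

## Preprocessing

* Denoising: db8 wavelet, 5 levels, universal threshold
  σ·√(2 ln n) with σ from the MAD of the finest detail level, soft
  shrinkage of detail coefficients only.  A zero threshold (noiseless
  input) short-circuits to the identity.
* Bandpass: order-4 Butterworth 0.5–45 Hz applied forward–backward
  (zero phase), symmetric padding.  Note the two-pass magnitude already
  droops near the edges (|H|² ≈ 0.94 at 30 Hz, 0.80 at 35 Hz), which
  bounds how literally "filter idempotence" can hold for broadband
  content.
* Band decomposition at fs = 512 Hz: 7-level db8 DWT; delta = A7+D7
  (0–4 Hz), theta = D6 (4–8), alpha = D5 (8–16), beta = D4 (16–32),
  gamma = D3 (32–64); D1–D2 (> 64 Hz) are kept as a residual so bands +
  residual reproduce the input exactly (linearity of the inverse
  transform).  The clinical 12/30 Hz edges cannot fall on dyadic
  boundaries; the nearest dyadic assignment is used and the prior
  bandpass suppresses out-of-band content.  Other rates require an
  explicit band/level map.
* Segmentation: aligned non-overlapping 30 s epochs, trailing partial
  epoch dropped.  30 s follows the standard sleep-epoch convention; the
  segment length used by augmentation is otherwise a free parameter.

## MCSA (layer-1 augmentation)

For every (subject, band, segment) the sweep emits four signals:
MCSA-1 addition (band-segment × scale factor), MCSA-2 addition
(band-segment + white Gaussian noise), and each of those convolved with
the subject's filtered raw trace.  Choices:

* Scale factor default 1.5 — amplification only; attenuation is
  excluded by design to avoid information loss.
* Noise is parameterized as SNR in dB relative to the targeted
  band-segment's own power (default 10 dB), which keeps the
  perturbation proportionate across bands of very different amplitude;
  SNR ≥ 120 dB is treated as noiseless.  Noise draws are seeded per
  (seed, subject, band, segment), so single augmented signals are
  reproducible in isolation.
* Convolution uses "same"-aligned linear (FFT) convolution truncated to
  the source length and rescaled to the input's power — full
  convolution of two long traces would explode in amplitude and length.
* The count law 4·S·B·G is the package's loop definition.  It follows
  the minimal reading of the augmentation scheme; the originating
  study's total signal count is not decomposable into any stated loop
  structure, so no attempt is made to reproduce it.

Labels are inherited from the source subject, and all untouched
band-segments are preserved bit-close (≤ 1e-9 relative), which the test
suite checks exhaustively.

## Features

Nine features per band on the full-length band reconstruction (the
decomposition is recomputed per augmented signal):

* Sample entropy: −ln(A/B), Chebyshev distance, tolerance r = 0.2 of the
  population SD, m = 2, self-matches excluded, A and B over the same
  n − m template positions.  Degenerate cases (no matches) return the
  finite cap ln(B_max(B_max−1)) so the feature table never holds
  non-finite values.  Because SampEn is O(n²), it is evaluated on a
  uniformly strided subsequence of at most 1024 points; all other
  features use every sample.
* Spectral entropy: Shannon entropy of the Welch PSD (nperseg ≤ 1024)
  normalized by log₂ of the bin count → [0, 1]; scale-invariant.
* Shannon entropy: 256 equal-width amplitude bins over the observed
  range, in bits; invariant to affine amplitude maps; defined 0 for
  constant input.
* Log-energy entropy: Σ log(x² + ε), ε = 1e-12.
* Band power: mean square.  Moments: mean, population SD, skewness,
  excess kurtosis (Gaussian → 0); skewness/kurtosis defined 0 at zero
  variance.

## Conditional tabular GAN (layer-2 augmentation)

Mode-specific normalization fits each continuous column with a Bayesian
Gaussian mixture (≤ 10 modes, `weight_concentration_prior = 1e-3`,
1000 EM iterations, 3 restarts, fitted on ≤ 1000 subsampled values;
modes under weight 0.005 pruned, SD floor 1e-6).  A value is encoded as
α = (v − μ_k)/(4 σ_k) with a one-hot mode indicator, mode k chosen by
responsibility argmax — deterministic and exactly invertible, so
encode∘decode is the identity.

Generator: 128-dim latent ⊕ condition vector → two 256-wide hidden
layers with batch normalization and ReLU → linear output activated
per slot (tanh for α, gumbel-softmax τ = 0.2 for mode/category
one-hots).  Discriminator: packed groups of 10 rows (pac = 10), two
256-wide hidden layers with LeakyReLU(0.2) and dropout 0.5.  Both are
plain numpy with hand-written backprop and Adam (lr 2e-4, β = 0.5/0.9,
weight decay 1e-6).  Training-by-sampling: each batch row draws a
(column, category) condition by log-frequency and a matching real row;
the generator loss adds a cross-entropy term tying its categorical
output to the condition.  The adversarial loss is the non-saturating
cross-entropy GAN loss; a gradient-penalty critic would need
second-order autodiff and is intentionally not used.

Sampling decodes the categorical value **from the condition vector that
generated the row**: conditional sampling is therefore 100% compliant
by construction, and unconditional sampling reproduces the empirical
class frequencies used to draw conditions.  Defaults: 2000 epochs,
batch 500, 10,000 sampled rows.  Short training (≈ 300 epochs) learns
marginals but not the class-conditional structure of the 45-column
table; the pipeline therefore runs the full 2000 epochs by default.

`validate_synthetic` reports per-column mean/SD differences and the
Frobenius norm of the correlation-matrix difference; the default pass
thresholds (|Δmean| ≤ 0.5 σ_real per column, Frobenius ≤ 5) are
package choices, and at the default end-to-end conditions the
correlation check does not pass (norm ≈ 8 over a 45×45 matrix) — the
run artifacts report this honestly.

## Classification and evaluation

Five models, all seeded with `random_state = 22`: decision tree
(entropy, depth ≤ 10), bagging of 100 entropy trees, gradient boosting
(100 estimators, lr 0.1), random forest (100 estimators), and a
stacking classifier over {bagged trees, random forest, decision tree}
with a gradient-boosting meta-learner.  Insomnia is the positive class;
reported metrics are accuracy, sensitivity (= recall), specificity,
precision, F1, trapezoidal ROC AUC from predicted probabilities, and
CER ≡ 1 − accuracy.

Evaluation protocols: stratified 75/25 holdout; stratified 5-fold CV;
and 6-fold subject-wise CV in which subjects are dealt into folds one
insomnia + one healthy per fold (12 subjects → 6 two-class test folds,
so every metric stays defined).  GAN-generated rows carry no subject
and join every training fold but are never tested on — the
subject-leakage guarantee applies to all subject-attributed rows.  Note
this mirrors the originating protocol, in which the GAN has seen the
augmented rows of all subjects; it is a weaker guarantee than training
the GAN per fold.

## Problem sizes

The default study conditions are 12 subjects (6 + 6) × 90 s at 512 Hz,
30 s epochs (G = 3), giving 720 layer-1 signals + 12 real, a 2000-epoch
GAN and 10,000 synthetic rows (~10,700 training rows).  These sizes were
chosen as the smallest cohort at which all three evaluation protocols
are meaningful; at these conditions the random forest reaches holdout
accuracy ≈ 0.95, AUC ≈ 0.99, CER ≈ 0.05 and subject-wise CV ≈ 0.97
(recomputed by `scripts/acceptance.py`).  Unit tests run on 2–4-subject,
30–60 s cohorts and toy GAN tables.

## Known limitations

* EDF support covers the 16-bit single-data-record-rate subset used
  here (no EDF+ annotations, no per-channel rates); non-integer-second
  signals are stored in a single record, where fs is recoverable only
  to the 8-character header precision.
* The GAN is CPU-bound numpy; wall-clock scales linearly with epochs ×
  batch and is minutes, not seconds, at the default table width.
* Subject-wise CV with a shared, cohort-trained GAN leaks distributional
  information about test subjects (see above).
* The dyadic alpha band (8–16 Hz) absorbs part of the 12–16 Hz beta
  content; class contrasts planted in generator bands are attenuated,
  not removed, by this mismatch.
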