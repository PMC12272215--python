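# Methods

This note documents the models and procedures implemented in `eegage`,
the assumptions behind them, and the design choices made where several
reasonable options existed.

## Problem setting

The package predicts chronological age from short, noisy, 4-channel
EEG recorded by a consumer headband (TP9, Fp1, Fp2, TP10 referenced to
Fpz, 256 Hz) during either an eyes-closed meditation exercise or
overnight sleep. Age prediction serves as a proxy task: the residual
between predicted and chronological age (the brain-age delta
Δ = ŷ − y) is a candidate biomarker of brain aging. With only four
frontal/temporal channels, the usable signal is spectral and
spatio-spectral structure, not source topography.

## Preprocessing

Fixed order: crop → interpolate → band-pass → notch bank → window →
peak-to-peak rejection → resample.

* **Crop (meditation only).** The first 60 s are discarded (signal
  quality settles) and at most the following 480 s kept. Sleep
  recordings are used whole. Recordings of ≤ 61 s are skipped with a
  warning rather than failing a batch.
* **Missing samples.** Wireless dropouts appear as NaN runs affecting
  all channels. Interior gaps are linearly interpolated from the
  surrounding valid samples; leading/trailing gaps take the nearest
  valid value, avoiding extrapolation. A fully missing channel is an
  error.
* **Filters.** All filters are windowed-sinc (Hamming) linear-phase
  FIR kernels of odd length applied by centred convolution — exactly
  zero-phase. Transition bandwidths follow the common M/EEG rule:
  min(max(0.25·f_low, 0.1 Hz), f_low) at the low edge, 25 % at the
  high edge; kernel length ≈ 3.3 / transition-bandwidth. The band-pass
  is 0.1–49 Hz. Notches are realized as one multiband band-stop kernel
  with 1 Hz-wide stop bands centred at 16, 21.3, 32, 42.7 Hz
  (hardware-specific peaks) and 50, 60 Hz (power-line). Measured
  behaviour: ≥ 59 dB attenuation at 21.3 Hz, < 0.1 dB at 10 Hz.
* **Windows.** Non-overlapping, contiguous: 10 s for meditation
  (short recordings need many windows for covariance estimation), 30 s
  for sleep, aligned one-to-one with hypnogram epochs so windows never
  straddle a stage boundary. The trailing remainder is dropped.
* **Rejection.** A window is rejected if peak-to-peak amplitude on
  *any* channel exceeds 250 µV (the strictest reading; threshold
  configurable). Rejection runs after all filtering — the criterion is
  evaluated on the signal the model will actually see.
* **Resampling.** Polyphase down-sampling to 128 Hz after windowing;
  each window keeps exactly length × 128 samples. The 49 Hz band edge
  is below the new Nyquist, so no passband content is lost.

## Filterbank covariance features

Nine bands: low (0.1–1), δ (1–4), θ (4–8), α_low (8–10), α_mid
(10–12), α_high (12–15), β_low (15–26), β_mid (26–35), β_high
(35–49 Hz). Band filtering reuses the windowed-sinc design with the
kernel capped at one window length; at the lowest band the ideal
transition would need more context than a 10 s window contains, so the
low band is realized at a coarser spectral resolution — an inherent
limit of short windows, not of the implementation.

Per window and band, the spatial covariance is estimated with Oracle
Approximating Shrinkage (OAS): `(1−ρ)S + ρ(tr S/C)I` with the
closed-form weight ρ, guaranteeing well-conditioned SPD matrices even
with C = 4 and short windows. The per-recording covariance is the
Euclidean mean over retained windows of per-window OAS estimates
(matching the filterbank benchmark convention this pipeline follows;
pooling samples before OAS is the documented alternative). The
cross-spectral covariance stacks the nine narrow-band signals
channel-wise (channels within band, bands in filterbank order) into a
36-row signal per window before the same estimation.

### Vectorization

* **Log-diagonal (spectral).** `ν = ∥_k log diag Σ^(k)`: channel-wise
  log-powers, 36 coordinates for meditation.
* **Bures–Wasserstein tangent space (spectro-spatial /
  cross-spectro-spatial).** Covariances are embedded at the
  Bures–Wasserstein barycenter of the *training* covariances. With
  Y, Ȳ the symmetric square roots of Σ and Σ̄, the orthogonal
  alignment `Q* = argmin_Q ‖YQ − Ȳ‖_F` gives an aligned difference
  whose Frobenius norm is exactly the Bures–Wasserstein distance
  d(Σ, Σ̄). That difference is not symmetric; it lies in the
  *horizontal space* `{SȲ : S symmetric}` of the square-root
  submersion, a subspace of dimension C(C+1)/2. The embedding
  therefore returns the coordinates of the aligned difference in an
  orthonormal basis of this subspace (obtained from the Gram square
  root of the basis {E_a Ȳ}, cached per reference point). This keeps
  the printed feature counts (10 per 4×4 matrix, 666 for the 36×36
  cross-spectral matrix) while making the embedding an exact local
  isometry: ‖ν‖₂ = d(Σ, Σ̄). The naive alternative — symmetrize the
  aligned difference and take its weighted upper triangle — was
  rejected because the discarded skew part is first-order in Σ − Σ̄
  and leaves a persistent ~5 % norm error.
* **Barycenter.** Fixed-point iteration
  `M ← M^{−1/2} [mean_i (M^{1/2} Σ_i M^{1/2})^{1/2}]² M^{−1/2}`,
  initialized at the Euclidean mean, tolerance 1e-8 on the Frobenius
  residual, at most 100 iterations; non-convergence raises an error
  carrying the last iterate. Agreement with brute-force minimisation
  of the summed squared distances is tested to 1e-4.

### Sleep-stage conditioning

For sleep, covariances are estimated separately per stage (W, N1, N2,
N3, R) from that stage's retained windows, and the per-stage feature
vectors are concatenated in fixed stage order (×5 feature counts:
180 / 450 / 3330). A stage observed in fewer than 3 retained windows
is treated as unobserved: its block is NaN at assembly, imputed with
training-set column means at the dataset level, and the recording is
flagged. Tangent references are fitted on training recordings pooled
across stages — one reference per band — keeping the embedding
comparable across stages; hypnograms are an input (ground truth from
the generator or user-supplied), not predicted.

## Regression and evaluation

Features are z-scored with training-fold means/SDs (zero-variance
columns pass through with a warning). Ridge regression with an
unpenalized intercept is fitted on the scaled features; the penalty α
is chosen from 100 log-uniform values in [1e-5, 1e10] by closed-form
generalized leave-one-out: centring the design makes the intercept
column orthogonal to the features, so the hat matrix is
`H = 11ᵀ/n + U diag(s²/(s²+α)) Uᵀ` from one SVD and the exact LOO
residual of row i is `(yᵢ − ŷᵢ)/(1 − Hᵢᵢ)` — no refitting loop. The
identity is verified against explicit n-refit leave-one-out to 1e-8.
The "validation" role is entirely played by this inner LOO; no third
partition is held out.

Evaluation: subject-grouped Monte-Carlo (shuffle-split)
cross-validation, 100 splits, 10 % of subjects held out. Subjects are
split atomically — all sessions of a subject fall on one side — and
the scaler, tangent references, imputation means, and ridge weights
are refitted inside each training fold, so no statistic ever sees a
test subject. Scores are R² and MAE pooled over the test rows of each
split (not per-subject averages), against a dummy predictor emitting
the training median age. A master seed drives the splitter; identical
seeds reproduce identical scores bit-for-bit.

## Interpretation

* **Grouped permutation importance.** Coordinates are grouped by
  frequency band (meditation) or band × stage (sleep). Per repetition
  (default 100), a group's coordinates are jointly row-shuffled across
  the held-out rows of a fitted CV split and ΔR² = R²(intact) −
  R²(permuted) is recorded; one fitted model per split is reused and
  results are averaged over splits, then normalized by the largest
  group-wise mean so the top group reads 1. The table reports both the
  spread across repetitions (per split) and across splits (aggregate),
  labeled.
* **Longitudinal summaries.** Dates are ISO-8601, handled as days
  since the subject's first session. Per subject: the OLS slope of Δ
  per day and the within-subject SD of Δ across sessions.
  `trait_state_ratio` compares the mean within-subject SD against the
  cross-subject SD of a cross-sectional cohort; a ratio < 1 indicates
  stable trait-like information on top of session-to-session state.
  No anonymization jitter is applied to analysis values.

## The synthetic-data generator

The generator emulates the *signal families the pipeline feeds on*,
with planted age effects whose direction matches the aging literature:

* 1/f^β background (β = 1) mixed across channels through a fixed
  matrix, so spatial covariance is informative; baseline RMS ~14 µV.
* An alpha oscillator (narrow-band noise, ~1 Hz bandwidth) present
  throughout meditation and in W epochs of sleep. Its peak frequency
  is 10.5 Hz at age 20 and decreases by 0.03 Hz/year; its power drifts
  by +0.8 %/year.
* Sigma-band activity (13.5 Hz centre) in N2 epochs (−1 %/year) and
  delta waves (2 Hz centre) in N3 epochs (−1.2 %/year, the declining
  slow-wave power of aging).
* All-channel NaN dropout runs (mean ~0.1 s, default 0.2 % of
  samples) and Poisson-count artifact bursts (~0.5 s, 500–1200 µV,
  3–8 Hz) that survive the band-pass and trigger the 250 µV rejection.
* Hypnograms from a first-order Markov chain over (W, N1, N2, N3, R)
  at 30 s resolution, started at W, with deep sleep typically reached
  before REM; the documented transition matrix's stationary
  distribution is the long-run stage mix. Age does not alter the
  chain — stage-architecture trends are out of the generator's scope;
  the age signal lives in the spectral content.

What makes the task realistically hard rather than trivially easy:
each subject carries a stable alpha-peak offset (SD 0.7 Hz,
age-independent — individual alpha frequency varies widely at any
age), and oscillator and background powers fluctuate log-normally at
the subject level (SD 0.15) and session level (SD 0.30). These values
were calibrated once so that the default 300-subject meditation cohort
(9-minute raw sessions → 8 minutes after cropping) puts the spectral
model's cross-validated R² in the 0.3–0.5 regime reported for
real-world consumer-EEG cohorts, and then frozen; the test suite
verifies on that exact cohort that the model beats the dummy baseline
by at least 0.2 R² while the dummy itself explains nothing.
Default desk-scale durations are 540 s (meditation) and 2400 s
(sleep "nights" with the full stage repertoire); both are
configurable up to realistic lengths.

What the generator does **not** emulate: sleep microstructure events
(K-complexes, arousals, spindle morphology), age-dependent sleep
architecture, non-stationary drift within a session, electrode
artifacts with realistic spatial signatures, or any neurofeedback
dynamics. Passing tests therefore demonstrate that the pipeline
recovers planted covariance-level age structure under dropouts,
artifacts, and subject/session noise — not that it would achieve the
same accuracy on real recordings.

Sex is generated for realism but unused by the pipeline. Everything is
driven by one integer seed through spawned per-subject/per-session
seed sequences; identical (config, seed) pairs are bit-identical.

## File formats

Recordings interchange as EDF (16-bit, physical unit µV, channel
labels TP9/Fp1/Fp2/TP10, 1 s records); the digital minimum is reserved
as the missing-sample sentinel so dropout masks survive a round trip
(restored to NaN on read). Values are clipped to ±2000 µV minus a
guard band; the quantization step is ~0.06 µV. Hypnograms are
two-column CSVs (epoch_index, stage); cohort metadata one CSV row per
session; feature tables CSV with a JSON sidecar; run configuration
round-trips through YAML.

## Numerical choices and degenerate inputs

* Matrix square roots via eigendecomposition with eigenvalues floored
  at 1e-15; OAS guarantees SPD inputs in practice.
* The Nelder-Mead brute-force check of the barycenter and the explicit
  LOO refits exist only in tests, independent of the library paths
  they verify.
* Constant features pass the scaler unscaled (warning); constant
  targets make R² undefined (error); an empty retained-window set is
  an error at covariance estimation and a skip at the cohort level.
* R² and MAE are implemented directly from their definitions and
  cross-checked against scikit-learn in tests.

## Known limitations

* The low band (0.1–1 Hz) is estimated from 10 s windows at coarser
  spectral resolution than its nominal edges suggest.
* Missing-stage imputation with training means biases those blocks
  toward the cohort centre; recordings with few observed stages are
  flagged but not excluded.
* The generator's effect sizes are calibrated to a plausible accuracy
  regime, not fitted to any real dataset; absolute R²/MAE values on
  synthetic cohorts are not comparable to real-data results.
* Longitudinal model evaluation retrains on the cross-sectional cohort
  and predicts repeat sessions; no per-subject adaptation is applied.
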