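# Methods

This note documents the models, algorithms and numerical choices behind
`binauralgap`, in the spirit of the methods documentation shipped with
simulation-and-inference packages.

## The task being modelled

A listener hears two 2000 ms intervals of Gaussian noise over headphones. In
the *reference* interval the two ears receive the same waveform; in the
*target* interval the temporal middle of the right-ear waveform is replaced by
an independent noise segment, producing an instantaneous change in interaural
correlation (CIC, a "binaural gap"). An interaural delay (ID) is imposed on
the right channel. Detecting the CIC requires the auditory system to hold the
fine structure of the leading ear's signal long enough to correlate it with
the delayed ear — so the longest ID at which the CIC is still detectable
measures the persistence of transient auditory storage. The package simulates
this experiment end to end and fits the models used to analyse it.

## Stimulus synthesis

* Gaussian noise at 48 kHz (default), 2000 ms intervals, scaled to a digital
  RMS level in dBFS (default −20 dBFS; absolute SPL calibration is hardware
  and out of scope).
* Narrowband conditions are 1/3-octave bands at 200, 400, 800, 1600 or
  3200 Hz: band edges CF·2^(∓1/6), realized with a zero-phase (forward–
  backward) Butterworth SOS bandpass. **Filter order 8** with **250 ms guard
  samples** generated on each side and cropped after filtering. The guard is
  load-bearing: the narrow filter rings for tens of milliseconds, and without
  cropping, start-up transients leak broadband energy; measured over 200
  seeds, the in-band power fraction at CF = 200 Hz then stays ≥ 0.958
  (band-limit contract: ≥ 95% of power inside the band, stopband one octave
  beyond the edges attenuated ≥ 40 dB).
* CIC: the middle `cic_duration_ms` (default 200 ms) of the right channel is
  replaced by a mixture of the original segment `h1` and an independent
  segment `h2`. Two mixing rules are available:
  - `"printed"` (default): `h2` is pre-scaled to RMS `(1−α)·RMS(h1)`, under
    which the mixing identity `α·h1 + h2 + (1−α−|h2|/|h1|)·h1` reduces to the
    amplitude-linear mixer `α·h1 + (1−α)·ĥ2`;
  - `"power"`: the power-preserving mixer `α·h1 + √(1−α²)·ĥ2`.
  The two agree exactly at the operating points α ∈ {0, 1} used throughout
  (a fully uncorrelated segment, or no change); they differ only in the power
  of intermediate mixtures, which no analysis here depends on.
* The ID is an integer-sample shift (round-half-up; 20.8 µs resolution at
  48 kHz, far below millisecond-scale thresholds), with zero-padding keeping
  the channels equal length. All windows are 0-based half-open sample
  intervals in undelayed (left-channel) coordinates.

## Interaural coherence

The interaural correlation at candidate delay T is the normalized
cross-correlation of the left channel and the right channel shifted back by
T, with the normalization energies taken over the same overlap, so |ρ| ≤ 1
holds exactly by Cauchy–Schwarz. The coherence ϑ is the maximum of ρ over a
lag grid (default: one-sample steps over [0, 20] ms; ties break toward the
smallest lag). For a pair whose right channel is a delayed copy, ϑ = 1
exactly at the introduced delay; replacing a fraction f of the signal with
independent noise lowers ρ at that lag to ≈ 1 − f (0.90 for 200 ms of
2000 ms). No peripheral auditory model (filterbank, compression) is applied:
the metric is waveform-level by design.

## Adaptive staircase

A transformed up–down track: after 3 consecutive correct 2AFC responses the
ID *increases* (the task measures the longest tolerable delay, so correct
runs make the task harder), after one error it decreases. With per-trial
probability p of a correct response, an increase occurs with probability p³
and a decrease with p²(1−p) + p(1−p) + (1−p) = 1 − p³; the track therefore
converges where p³ = ½, i.e. p = 0.5^(1/3) ≈ 0.794.

Defaults (classic transformed up–down practice; the step schedule is a
package choice): geometric steps, factor 2 until the 2nd reversal and √2
thereafter, with a 0.1 ms floor on the step size; 12 reversals end the track
and the threshold is the arithmetic mean ID of the last 8 reversals; session
estimates are averaged across sessions (default 3). An arithmetic
(additive-step) variant is available. Monte-Carlo check: with a logistic
observer whose 79.4% point is 6 ms, the mean estimate over 200 tracks is
≈ 6.4–6.6 ms — within one final (√2) step of the target, with the small
upward bias expected from arithmetic averaging of geometric reversals.

## The simulated listener

The duration threshold follows the linear threshold model

    T_μi = T_λ + T_β·ρ(T_δ) + T_γi + N(0, σ),

a fixed intercept, a slope on the interaural correlation, a participant
random intercept, and Gaussian error. The model specifies only the
threshold; to drive trial-by-trial behaviour the package anchors a logistic
psychometric function in log-ID at that threshold:
P(correct) = 0.5 + (0.5 − λ/2)·F(ID), with F logistic (slope 8 by default)
and F calibrated so P(T_μi) = 0.794 exactly. The lapse rate λ (default 0.02)
sets the ceiling; λ = 1 yields chance everywhere.

A stimulus-driven decision rule is also provided: evidence per interval is a
decision-weighted sum over CIC-sized analysis windows of the coherence
deficit 1 − ϑ_k, with the lag search confined to the observer's memory span
(default: its threshold) — delays beyond the span cannot be compensated, so
both intervals look equally decorrelated and performance falls to chance.
The weighted-sum form mirrors the multiple-observation decision variable
β = Σ ξ_k x_k; the choice of the coherence deficit as the observation x_k
is the minimal assumption consistent with the coherence machinery. This
waveform route is mechanistic and not calibrated to the 79.4% anchor; bulk
simulations use the calibrated psychometric route.

## The synthetic population

The generator emulates the study's structure — n = 14 participants, five
narrowband conditions plus wideband — with latent thresholds

    t_ij = profile(CF_j) + γ_i + d_ij + N(0, σ),
    T_i  = Σ_j ω̄_j t_ij + N(0, σ),

where γ_i ~ N(0, 1.0 ms) is the participant intercept, d_ij ~ N(0, 1.5 ms)
a stable participant-by-band deviation, σ = 0.5 ms measurement error, the
frequency profile (9.0, 8.0, 6.5, 4.5, 3.0) ms declines monotonically from
200 Hz to 3.2 kHz, and the simplex weights ω̄ = (0.35, 0.30, 0.20, 0.10,
0.05) tie the wideband threshold to the narrowband ones with low-frequency
dominance. The band deviation term matters: with only a shared intercept,
every narrowband column would correlate with the wideband vector almost
identically; band-specific individual variance is what lets the
narrowband/wideband correlation decline with CF over a realistic range
(≈ 0.64 at 200 Hz down to ≈ 0.41 at 3.2 kHz in the end-to-end simulation,
averaged over 100 studies).

Non-positive draws are resampled (with logging) or rejected under a
strictness flag. `generate_matrix` draws the matrix directly from this
distribution; `simulate_study` is the heavyweight path that runs the full
3-down/1-up track per participant × condition × session against the
psychometric observer and assembles the matrix from staircase estimates.
Profile values and variance components are the package's calibration of the
qualitative structure (ordering and correlation ranges), not assertions of
unpublished magnitudes.

What the generator does *not* emulate: learning or fatigue across sessions,
attention lapses correlated over trials, non-Gaussian individual
differences, or any peripheral hearing differences between listeners —
passing recovery tests here shows the estimators work under the stated
model, not that the model captures every feature of real listeners.

## Fitting

* **Band weights.** `BandWeightModel` minimizes Σ_i (Σ_j ω_j t_ij − T_i)²
  subject to Σ ω_j = 1, ω_j ≥ 0 — a convex QP solved with SLSQP from the
  uniform start (deterministic; verified in tests against an exhaustive
  0.01-resolution simplex grid search for m ≤ 3 and against random feasible
  points). Strict positivity (ω_j ≥ ε) is available by flag; the
  non-negativity reading of the constraint follows constrained
  least-squares practice. Rank-deficient designs get a logged warning and a
  tiny ridge (1e−9 of the design scale) as a minimum-norm tie-break. One
  global weight vector is estimated; per-participant weights would be
  unidentifiable with one wideband value per row. Reported diagnostics:
  residuals, R², active constraints, and T′ = mean_i Σ_j ω̄_j t_ij, the
  model-implied mean wideband longest delay.
* **Threshold model.** `InterauralThresholdModel` fits the random-intercept
  model by REML via `statsmodels` MixedLM and reports T̂_λ, T̂_β with
  standard errors, the residual SD σ̂, the participant SD, and per-
  participant BLUPs. At least two participants and two distinct ρ values are
  required (the slope is otherwise unidentifiable).
* **Descriptives.** Per-CF Pearson correlations between narrowband columns
  and the wideband vector (zero-variance columns flagged, r = NaN), and a
  monotone curve for group-mean longest ID versus CF — linear in log₂(CF) by
  default, with a bounded four-parameter logistic decay as the alternative;
  which family produced any particular published goodness-of-fit is not
  knowable from summary values, so the family is an explicit argument.

## Problem sizes and seeds

The shipped verification runs use: 200 staircase tracks for convergence,
~10,000 staircase decisions for the run-probability check, 100 seeds for the
CIC coherence average, 100 seeds for weight recovery (σ = 0.1 ms, the
"small measurement noise" regime in which the weights are well identified:
the estimation error per weakly identified direction scales as
σ_T/√(n·(band_sd² + σ²))), one 14 × 6 × 3 table for threshold-model
recovery, and 100–200 end-to-end simulated studies for the ordering
descriptives. All randomness flows from explicit integer seeds through
`numpy` seed sequences; the pipeline derives per-stage child seeds keyed by
stage name so adding a stage never perturbs earlier stages' streams.

## Known limitations

* The correlation metric is waveform-level; no claims about physiological
  mechanisms (phase-locking, delay lines) are made or testable here.
* The printed-form mixer does not preserve power for intermediate α; use the
  power-preserving switch if intermediate correlations are ever needed.
* Staircase estimates carry a small positive bias (arithmetic mean of
  geometric reversal levels) that is inherited by downstream group means.
* The equality-constrained solver relies on SLSQP convergence; for the
  problem sizes here (m ≤ 5) this has been exact to tolerance in every
  tested instance, but pathological scaling (columns differing by orders of
  magnitude) is untested.
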