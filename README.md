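# binauralgap

Simulation and analysis of **binaural-gap detection under interaural delay** —
a computational account of how long the auditory system can hold ("transiently
store") the fine structure of a noise waveform.

## The scientific problem

Listeners can detect an *instantaneous change in correlation* (CIC): a short
segment of interaurally uncorrelated noise inserted into otherwise identical
left/right noise. Detection survives even when the right-ear signal is delayed
relative to the left by several milliseconds, which implies that the fine
structure of the leading signal is held in a transient store long enough to be
correlated with the lagging one. The longest interaural delay (ID) at which
the CIC remains detectable therefore measures the persistence of that store —
per frequency band, since low-frequency fine structure is stored longer than
high-frequency fine structure.

`binauralgap` is for auditory psychophysicists and modellers who want to
simulate this paradigm, benchmark its estimators, or analyse threshold tables
from it. It provides:

* **Stimuli** — 48 kHz Gaussian noise pairs, wideband or 1/3-octave bands at
  0.2/0.4/0.8/1.6/3.2 kHz, with a CIC in the temporal middle and an
  integer-sample interaural delay; stereo WAV + JSON sidecar output.
* **Coherence** — the interaural correlation ρ(T) over candidate delays and
  its maximum ϑ = max_T ρ(T).
* **Staircase** — the adaptive two-interval 2AFC, 3-down/1-up track, which
  converges at the delay where P(correct) = 0.5^(1/3) ≈ 0.794 (an increase
  needs a run of three correct responses, probability p³; a decrease has
  probability p²(1−p) + p(1−p) + (1−p)).
* **Observers** — simulated listeners with thresholds from the linear model
  T_μi = T_λ + T_β·ρ(T_δ) + T_γi + N(0, σ), turned into trial-by-trial
  behaviour by a logistic psychometric function anchored at the 79.4% point,
  plus a full synthetic-study generator (14 participants × 6 conditions).
* **Fits** — statsmodels-style model/results classes:
  `BandWeightModel` solves the simplex-constrained least squares
  Σ_j ω̄_j·t̄_ij = T_i (Σ ω̄_j = 1, ω̄_j ≥ 0) relating narrowband to wideband
  longest delays; `InterauralThresholdModel` fits the mixed threshold model
  by REML; plus per-CF narrowband/wideband correlations and the group-mean
  longest-ID-versus-CF curve.

## Worked example

Simulate a full study (14 participants, 5 narrowband bands + wideband, three
3-down/1-up sessions per condition), then fit the band weights:

```python
from binauralgap import (PopulationSpec, StaircaseConfig, simulate_study,
                         fit_weights, correlate_bands, fit_cf_curve)

matrix = simulate_study(PopulationSpec(), StaircaseConfig(), seed=1, sessions=3)
print(fit_weights(matrix).summary())
```

```
Band-weight fit (simplex-constrained least squares)
----------------------------------------------------
  omega[ 200.0] =  0.3691
  omega[ 400.0] =  0.2601
  omega[ 800.0] =  0.2679
  omega[1600.0] =  0.1029
  omega[3200.0] =  0.0000  (at bound)
  sum(omega)    = 1.000000
  R^2           = 0.7203
  T' (mean wideband longest delay) = 8.334 ms
  weights pinned at the bound: (4,)
```

The fitted weights estimate how much each narrowband condition contributes to
the wideband longest delay: here the two lowest bands carry ~63% of the
weight (the generating weights are 0.35, 0.30, 0.20, 0.10, 0.05), and the
3.2 kHz weight is pinned at the non-negativity bound. T′ is the model-implied
mean wideband longest delay across participants. Descriptives follow the same
pattern:

```python
r = correlate_bands(matrix).r        # per-CF correlation with wideband
r2 = fit_cf_curve(matrix).r_squared  # group-mean longest ID vs log2(CF)
```

which for this seed gives r = (0.75, 0.49, 0.14, 0.62, 0.12) — noisy at
n = 14, but declining with CF on average over many studies — and a
log-linear CF-curve R² of 0.989.

The same steps are available from a shell:

```bash
binauralgap stimgen --band nb --cf 800 --id-ms 4 --cic-ms 200 --seed 7 --out pair.wav
binauralgap coherence --in pair.wav --max-lag-ms 20
binauralgap simulate --n 14 --sessions 3 --seed 1 --out matrix.csv
binauralgap fit --in matrix.csv --out report.json
binauralgap run --out-dir run1 --seed 1     # full pipeline with manifest
```

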