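"""Simulated listeners and synthetic participant data.

The listener is parameterized by a duration threshold for detecting the change
in correlation (CIC): T_mu = T_lambda + T_beta * rho(T_delta) + T_gamma_i +
N(0, sigma), a linear threshold model with a fixed intercept, a slope on the
interaural correlation, a participant random intercept, and Gaussian error.  A
logistic psychometric function in log-delay, anchored so that the per-trial
probability of a correct 2AFC response equals 0.5**(1/3) (the 3-down/1-up
convergence level) at T_mu, turns the threshold into trial-by-trial behaviour.

The population generator emulates the study's structure: 14 participants, five
1/3-octave narrowband conditions (0.2-3.2 kHz) plus wideband, with the
longest detectable delay declining monotonically with center frequency and the
wideband value tied to the narrowband values through simplex weights
(sum_j t_ij * omega_j = T_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import coherence_scan
from .staircase import (
    CONVERGENCE_P,
    StaircaseConfig,
    estimate_threshold,
    run_track,
)
from .stimulus import BandSpec, BinauralStimulus, NARROWBAND_CENTER_FREQUENCIES

__all__ = [
    "ObserverModel",
    "PopulationSpec",
    "ThresholdMatrix",
    "DEFAULT_FREQUENCY_PROFILE",
    "DEFAULT_TRUE_WEIGHTS",
    "respond",
    "generate_matrix",
    "simulate_study",
    "generate_threshold_observations",
]

logger = logging.getLogger(__name__)

#: Expected longest detectable delay (ms) per narrowband center frequency.
#: Monotone non-increasing in CF: low-frequency fine structure is stored longer.
DEFAULT_FREQUENCY_PROFILE = {
    200.0: 9.0,
    400.0: 8.0,
    800.0: 6.5,
    1600.0: 4.5,
    3200.0: 3.0,
}

#: Simplex weights tying the wideband longest delay to the narrowband ones;
#: low-frequency bands dominate.
DEFAULT_TRUE_WEIGHTS = (0.35, 0.30, 0.20, 0.10, 0.05)


@dataclass
class ObserverModel:
    """A parametric simulated listener.

    ``T_lambda_ms`` (fixed intercept), ``T_beta_ms`` (slope on the interaural
    correlation), ``gamma_ms`` (this participant's random intercept) and
    ``sigma_ms`` (error SD) define the duration threshold.  For
    condition-driven simulation, ``condition_thresholds`` maps a band label
    (e.g. ``"nb800"``, ``"wb"``) directly to a threshold in ms and takes
    precedence.  ``decision_weights`` are the weights xi_k of the evidence sum
    beta = sum_k xi_k x_k over analysis sub-windows in the stimulus-driven
    decision rule (uniform by default).
    """

    T_lambda_ms: float = 8.0
    T_beta_ms: float = 0.0
    gamma_ms: float = 0.0
    sigma_ms: float = 0.0
    psychometric_slope: float = 8.0
    lapse_rate: float = 0.02
    target_level: float = CONVERGENCE_P
    decision_weights: tuple[float, ...] | None = None
    internal_noise: float = 0.0
    condition_thresholds: dict[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_ms < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse rate must lie in [0, 1]")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric slope must be positive")
        if not 0.5 < self.target_level < 1.0:
            raise ValueError("target level must lie in (0.5, 1)")
        if self.decision_weights is not None and not np.all(
            np.isfinite(self.decision_weights)
        ):
            raise ValueError("decision weights must be finite")

    # -- threshold model -------------------------------------------------

    def mean_threshold(self, rho: float = 1.0) -> float:
        """Deterministic part of the threshold model at interaural correlation rho."""
        return self.T_lambda_ms + self.T_beta_ms * rho + self.gamma_ms

    def draw_threshold(self, rho: float = 1.0, rng: np.random.Generator | None = None) -> float:
        """One noisy threshold draw (e.g. a session-level realization)."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        return self.mean_threshold(rho) + rng.normal(0.0, self.sigma_ms)

    def threshold_for(self, condition: BandSpec | str, rho: float = 1.0) -> float:
        """Threshold for a named condition, or the model value at ``rho``."""
        label = condition if isinstance(condition, str) else condition.label
        if self.condition_thresholds is not None and label in self.condition_thresholds:
            return self.condition_thresholds[label]
        return self.mean_threshold(rho)

    # -- psychometric function -------------------------------------------

    def p_correct(self, id_ms: float, threshold_ms: float) -> float:
        """2AFC probability of a correct response at a given interaural delay.

        A logistic in log-delay falling from near-certainty toward the 0.5
        chance floor, anchored so that ``p_correct(threshold) == target_level``
        (0.794 by default, the 3-down/1-up convergence point).
        """
        ceiling = 1.0 - self.lapse_rate / 2.0
        span = ceiling - 0.5
        if span <= 0:
            return 0.5
        f_at_threshold = (self.target_level - 0.5) / span
        if not 0.0 < f_at_threshold < 1.0:
            raise ValueError(
                "target level unreachable given the lapse rate "
                f"(ceiling {ceiling:.3f} < target {self.target_level:.3f})"
            )
        if threshold_ms <= 0:
            return 0.5 + span * 0.5  # degenerate threshold: flat mid-performance
        if id_ms <= 0:
            return ceiling
        s = self.psychometric_slope
        # midpoint such that F(threshold) = f_at_threshold for F = 1/(1+(id/mid)^s)
        mid = threshold_ms * (1.0 / f_at_threshold - 1.0) ** (-1.0 / s)
        f = 1.0 / (1.0 + (id_ms / mid) ** s)
        return 0.5 + span * f

    # -- stimulus-driven decision ----------------------------------------

    def respond(
        self,
        interval_1: BinauralStimulus,
        interval_2: BinauralStimulus,
        rng: np.random.Generator | None = None,
        memory_span_ms: float | None = None,
        lag_step_ms: float = 0.25,
    ) -> int:
        """Pick the interval judged to contain the CIC (1 or 2).

        Evidence per interval is the decision-weighted sum over analysis
        sub-windows of the coherence deficit 1 - theta_k, where theta_k is the
        windowed maximum interaural correlation over compensating lags within
        the observer's memory span (default: this condition's threshold).
        Delays beyond the span cannot be compensated, so both intervals then
        look equally decorrelated and performance falls to chance.  Internal
        Gaussian noise and a lapse probability corrupt the decision.
        """
        if rng is None:
            rng = np.random.default_rng(self.seed)
        flags = (interval_1.contains_cic, interval_2.contains_cic)
        if sum(flags) != 1:
            raise ValueError("exactly one interval must contain the CIC")
        if rng.random() < self.lapse_rate:
            return int(rng.integers(1, 3))
        if memory_span_ms is None:
            memory_span_ms = self.threshold_for(interval_1.band)
        evidence = [
            self._evidence(iv, memory_span_ms, lag_step_ms) + rng.normal(0.0, self.internal_noise)
            if self.internal_noise > 0
            else self._evidence(iv, memory_span_ms, lag_step_ms)
            for iv in (interval_1, interval_2)
        ]
        if evidence[0] == evidence[1]:
            return int(rng.integers(1, 3))
        return 1 if evidence[0] > evidence[1] else 2

    def _evidence(self, stim: BinauralStimulus, span_ms: float, lag_step_ms: float) -> float:
        fs = stim.sample_rate_hz
        win = max(stim.config.cic_n_samples, 1)
        n = stim.n_samples
        lags = np.arange(0.0, max(span_ms, lag_step_ms) + 1e-9, lag_step_ms)
        deficits = []
        for start in range(0, n - win + 1, win):
            seg = (stim.left[start : start + win + int(span_ms * fs / 1000) ],
                   stim.right[start : start + win + int(span_ms * fs / 1000)], fs)
            curve = coherence_scan(seg, lag_grid_ms=lags)
            deficits.append(1.0 - curve.theta)
        deficits = np.asarray(deficits)
        if self.decision_weights is None:
            w = np.full(deficits.shape, 1.0 / max(len(deficits), 1))
        else:
            w = np.asarray(self.decision_weights, dtype=float)
            if w.shape != deficits.shape:
                raise ValueError(
                    f"decision_weights length {w.size} does not match "
                    f"{deficits.size} analysis windows"
                )
        return float(np.dot(w, deficits))


def respond(observer: ObserverModel, interval_1, interval_2, **kwargs) -> int:
    """Functional alias for :meth:`ObserverModel.respond`."""
    return observer.respond(interval_1, interval_2, **kwargs)


@dataclass
class PopulationSpec:
    """Structure of the simulated participant population.

    ``gamma_sd_ms`` is the between-participant SD of the random intercept;
    ``band_sd_ms`` the SD of stable participant-by-band deviations (the source
    of band-specific individual differences that make the narrowband/wideband
    correlations differ across center frequencies); ``sigma_ms`` the
    measurement-error SD.  ``true_weights`` tie the wideband longest delay to
    the narrowband ones on the simplex.
    """

    n_participants: int = 14
    gamma_sd_ms: float = 1.0
    band_sd_ms: float = 1.5
    sigma_ms: float = 0.5
    condition_cfs: tuple[float, ...] = NARROWBAND_CENTER_FREQUENCIES
    frequency_profile: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_PROFILE)
    )
    true_weights: tuple[float, ...] = DEFAULT_TRUE_WEIGHTS
    resample_nonpositive: bool = True
    max_resample: int = 1000

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least two participants")
        w = np.asarray(self.true_weights, dtype=float)
        if w.size != len(self.condition_cfs):
            raise ValueError("true_weights must have one entry per narrowband condition")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("true_weights must be non-negative and sum to 1")
        for sd in (self.gamma_sd_ms, self.band_sd_ms, self.sigma_ms):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        missing = [cf for cf in self.condition_cfs if cf not in self.frequency_profile]
        if missing:
            raise ValueError(f"frequency_profile lacks entries for CFs {missing}")

    @property
    def profile_vector(self) -> np.ndarray:
        return np.asarray([self.frequency_profile[cf] for cf in self.condition_cfs])


@dataclass
class ThresholdMatrix:
    """Participants x conditions table of longest detectable delays (ms)."""

    t_ij: np.ndarray  # (n participants, m narrowband CFs)
    T_i: np.ndarray  # (n,) wideband values
    cf_labels: tuple[float, ...]

    def __post_init__(self) -> None:
        self.t_ij = np.asarray(self.t_ij, dtype=float)
        self.T_i = np.asarray(self.T_i, dtype=float)
        if self.t_ij.ndim != 2:
            raise ValueError("t_ij must be 2-D (participants x conditions)")
        if self.t_ij.shape[1] != len(self.cf_labels):
            raise ValueError("column count must match cf_labels")
        if self.t_ij.shape[0] != self.T_i.shape[0]:
            raise ValueError("row count must match the wideband vector length")

    @property
    def n(self) -> int:
        return self.t_ij.shape[0]

    @property
    def m(self) -> int:
        return self.t_ij.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long format: participant, cf_or_wb, longest_id_ms."""
        rows = []
        for i in range(self.n):
            for j, cf in enumerate(self.cf_labels):
                rows.append((i, f"{cf:g}", self.t_ij[i, j]))
            rows.append((i, "wb", self.T_i[i]))
        return pd.DataFrame(rows, columns=["participant", "cf_or_wb", "longest_id_ms"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThresholdMatrix":
        wide = df.pivot(index="participant", columns="cf_or_wb", values="longest_id_ms")
        if "wb" not in wide.columns:
            raise ValueError("expected a 'wb' (wideband) column")
        cfs = sorted(float(c) for c in wide.columns if c != "wb")
        t = wide[[f"{cf:g}" for cf in cfs]].to_numpy(dtype=float)
        return cls(t_ij=t, T_i=wide["wb"].to_numpy(dtype=float), cf_labels=tuple(cfs))

    @classmethod
    def from_csv(cls, path) -> "ThresholdMatrix":
        return cls.from_frame(pd.read_csv(path))


def _draw_positive(
    draw, rng: np.random.Generator, max_resample: int, strict: bool, what: str
) -> np.ndarray:
    """Draw an array, redrawing non-positive entries (or raising when strict)."""
    x = draw(rng)
    bad = x <= 0
    tries = 0
    while np.any(bad):
        if strict:
            raise ValueError(f"non-positive generated {what}")
        if tries >= max_resample:
            raise RuntimeError(f"could not draw positive {what} after {max_resample} tries")
        logger.info("resampling %d non-positive %s value(s)", int(bad.sum()), what)
        x = np.where(bad, draw(rng), x)
        bad = x <= 0
        tries += 1
    return x


def generate_matrix(pop: PopulationSpec, seed: int | None = None) -> ThresholdMatrix:
    """Draw a synthetic threshold matrix directly from the population model.

    ``t_ij = profile(CF_j) + gamma_i + d_ij + N(0, sigma)`` with participant
    intercepts ``gamma_i ~ N(0, gamma_sd)`` and stable participant-by-band
    deviations ``d_ij ~ N(0, band_sd)``; the wideband value is the simplex-
    weighted combination of the observed narrowband values plus measurement
    error: ``T_i = sum_j omega_j t_ij + N(0, sigma)``.  This is the fast,
    distributional shortcut; :func:`simulate_study` is the full end-to-end path.
    """
    rng = np.random.default_rng(seed)
    n, m = pop.n_participants, len(pop.condition_cfs)
    gamma = rng.normal(0.0, pop.gamma_sd_ms, size=n)
    base = pop.profile_vector[None, :] + gamma[:, None]

    def draw_t(r):
        # band deviation and measurement error are redrawn together so that a
        # non-positive draw can actually be resampled away
        return (
            base
            + r.normal(0.0, pop.band_sd_ms, size=(n, m))
            + r.normal(0.0, pop.sigma_ms, size=(n, m))
        )

    t = _draw_positive(draw_t, rng, pop.max_resample, not pop.resample_nonpositive, "threshold")
    w = np.asarray(pop.true_weights)

    def draw_T(r):
        return t @ w + r.normal(0.0, pop.sigma_ms, size=n)

    T = _draw_positive(
        draw_T, rng, pop.max_resample, not pop.resample_nonpositive, "wideband threshold"
    )
    return ThresholdMatrix(t_ij=t, T_i=T, cf_labels=tuple(pop.condition_cfs))


def simulate_study(
    pop: PopulationSpec,
    staircase_config: StaircaseConfig | None = None,
    seed: int | None = None,
    sessions: int = 3,
    mode: str = "psychometric",
    stimulus_config=None,
    psychometric_slope: float = 8.0,
    lapse_rate: float = 0.02,
) -> ThresholdMatrix:
    """Run the full adaptive-track study for every participant and condition.

    Each participant carries latent band thresholds ``theta_ij = profile_j +
    gamma_i + d_ij`` and a latent wideband threshold ``Theta_i = sum_j omega_j
    theta_ij``; every session draws a noisy realization (SD ``sigma_ms``) and
    runs a 3-down/1-up track against a logistic observer anchored at it.  The
    matrix entry is the across-session mean of the track threshold estimates.
    """
    if staircase_config is None:
        staircase_config = StaircaseConfig()
    rng = np.random.default_rng(seed)
    n, m = pop.n_participants, len(pop.condition_cfs)
    gamma = rng.normal(0.0, pop.gamma_sd_ms, size=n)
    d = rng.normal(0.0, pop.band_sd_ms, size=(n, m))
    theta = pop.profile_vector[None, :] + gamma[:, None] + d
    theta = np.clip(theta, 0.2, None)  # latent thresholds stay physically positive
    w = np.asarray(pop.true_weights)
    Theta_wb = theta @ w

    conditions = [BandSpec.narrowband(cf) for cf in pop.condition_cfs] + [BandSpec.wideband()]
    latent = np.column_stack([theta, Theta_wb])

    out = np.empty((n, m + 1))
    for i in range(n):
        for c, cond in enumerate(conditions):
            tracks = []
            for _ in range(sessions):
                thr = max(latent[i, c] + rng.normal(0.0, pop.sigma_ms), 0.2)
                obs = ObserverModel(
                    psychometric_slope=psychometric_slope,
                    lapse_rate=lapse_rate,
                )
                tracks.append(
                    run_track(
                        obs,
                        cond,
                        staircase_config,
                        rng=rng,
                        mode=mode,
                        stimulus_config=stimulus_config,
                        threshold_ms=thr,
                    )
                )
            est = estimate_threshold(tracks, staircase_config)
            out[i, c] = est.t_bar_iai_ms
    return ThresholdMatrix(
        t_ij=out[:, :m], T_i=out[:, m], cf_labels=tuple(pop.condition_cfs)
    )


def generate_threshold_observations(
    n_participants: int = 14,
    rho_levels: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 0.9, 1.0),
    sessions: int = 3,
    T_lambda_ms: float = 8.0,
    T_beta_ms: float = -4.0,
    gamma_sd_ms: float = 1.0,
    sigma_ms: float = 0.2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long table of duration thresholds under the linear threshold model.

    One row per participant x interaural-correlation level x session, with
    ``threshold_ms = T_lambda + T_beta * rho + gamma_i + N(0, sigma)``.  Used
    for parameter-recovery studies of the mixed threshold model.
    """
    rng = np.random.default_rng(seed)
    gamma = rng.normal(0.0, gamma_sd_ms, size=n_participants)
    rows = []
    for i in range(n_participants):
        for rho in rho_levels:
            for s in range(sessions):
                thr = T_lambda_ms + T_beta_ms * rho + gamma[i] + rng.normal(0.0, sigma_ms)
                rows.append((i, rho, s, thr))
    return pd.DataFrame(rows, columns=["participant", "rho", "session", "threshold_ms"])
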