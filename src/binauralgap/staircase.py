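"""Transformed up-down (3-down/1-up) adaptive track for the longest detectable delay.

The task is a two-interval, two-alternative forced choice: one interval contains
the change in correlation (CIC), and the listener reports which.  Because the
measured quantity is the LONGEST interaural delay at which the CIC remains
detectable, three consecutive correct responses make the task harder by
*increasing* the delay, and a single error decreases it.  The track therefore
converges on the delay at which the per-trial probability of a correct response
is 0.5**(1/3) ~= 0.794: an increase requires a run of three correct responses
(probability p**3), a decrease follows any shorter run
(p^2(1-p) + p(1-p) + (1-p) = 1 - p**3), and the two balance when p**3 = 1/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimulus import BandSpec, StimulusConfig, build_interval

__all__ = [
    "StaircaseConfig",
    "StaircaseTrack",
    "TrialRecord",
    "ThresholdEstimate",
    "StaircaseError",
    "InsufficientReversalsError",
    "CONVERGENCE_P",
    "step",
    "run_track",
    "estimate_threshold",
    "track_to_frame",
    "write_trial_log",
]

logger = logging.getLogger(__name__)

#: Per-trial probability of a correct response at the 3-down/1-up convergence point.
CONVERGENCE_P = 0.5 ** (1.0 / 3.0)


class StaircaseError(RuntimeError):
    """Raised on invalid staircase operations (e.g. stepping a finished track)."""


class InsufficientReversalsError(ValueError):
    """Raised when a track has fewer reversals than the threshold rule needs."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Rule and schedule of one adaptive track.

    The step schedule shrinks as reversals accumulate: entry ``k`` of the
    schedule applies after ``k * reversals_per_step`` reversals, with the last
    entry persisting.  In geometric mode entries are multiplicative factors
    (> 1); in arithmetic mode they are millisecond increments.  ``min_step_ms``
    keeps the effective geometric step from collapsing at very small delays.
    """

    n_down: int = 3
    n_up: int = 1
    initial_id_ms: float = 4.0
    step_mode: str = "geometric"
    step_schedule: tuple[float, ...] = (2.0, math.sqrt(2.0))
    reversals_per_step: int = 2
    min_step_ms: float = 0.1
    n_reversals_total: int = 12
    n_reversals_for_threshold: int = 8
    max_trials: int = 400
    min_id_ms: float = 0.0
    max_id_ms: float | None = None

    def __post_init__(self) -> None:
        if self.n_down < 1 or self.n_up != 1:
            raise ValueError("rule must be n-down/1-up with n >= 1")
        if self.initial_id_ms < 0:
            raise ValueError("initial delay must be >= 0")
        if self.step_mode not in ("geometric", "arithmetic"):
            raise ValueError("step_mode must be 'geometric' or 'arithmetic'")
        if not self.step_schedule:
            raise ValueError("step schedule is empty")
        if self.step_mode == "geometric" and any(f <= 1.0 for f in self.step_schedule):
            raise ValueError("geometric step factors must exceed 1")
        if self.step_mode == "arithmetic" and any(s <= 0.0 for s in self.step_schedule):
            raise ValueError("arithmetic steps must be positive")
        if any(
            b > a for a, b in zip(self.step_schedule, self.step_schedule[1:])
        ):
            raise ValueError("step schedule must be non-increasing (large to small)")
        if self.n_reversals_total < 1 or self.n_reversals_for_threshold < 1:
            raise ValueError("reversal counts must be positive")
        if self.n_reversals_for_threshold > self.n_reversals_total:
            raise ValueError("n_reversals_for_threshold cannot exceed n_reversals_total")
        if self.max_trials < 1:
            raise ValueError("max_trials must be positive")


@dataclass
class TrialRecord:
    id_ms: float
    cic_interval: int | None = None
    response_interval: int | None = None
    correct: bool = False
    reversal: bool = False


@dataclass
class StaircaseTrack:
    """Evolving state of one adaptive run."""

    current_id_ms: float
    trials: list[TrialRecord] = field(default_factory=list)
    consecutive_correct: int = 0
    reversals: list[tuple[int, float]] = field(default_factory=list)
    last_direction: int = 0
    finished: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_reversals(self) -> int:
        return len(self.reversals)


def _current_step(config: StaircaseConfig, n_reversals: int) -> float:
    idx = min(n_reversals // config.reversals_per_step, len(config.step_schedule) - 1)
    return config.step_schedule[idx]


def final_step_ms(config: StaircaseConfig, at_id_ms: float) -> float:
    """Size in ms of the smallest scheduled step, evaluated at a given delay."""
    s = config.step_schedule[-1]
    if config.step_mode == "arithmetic":
        return s
    return max(at_id_ms * (s - 1.0), config.min_step_ms)


def _move(track: StaircaseTrack, direction: int, config: StaircaseConfig) -> None:
    s = _current_step(config, track.n_reversals)
    x = track.current_id_ms
    if config.step_mode == "geometric":
        delta = max(x * (s - 1.0), config.min_step_ms) if x > 0 else config.min_step_ms
        new = x + delta if direction > 0 else x * x / (x + delta) if x > 0 else 0.0
        # geometric down-step mirrors the up-step in log space: x -> x^2/(x+delta)
        # equals x/s when delta = x*(s-1)
    else:
        new = x + s if direction > 0 else x - s
    if new < config.min_id_ms:
        logger.warning("staircase clamped at the %.3g ms floor", config.min_id_ms)
        new = config.min_id_ms
    if config.max_id_ms is not None and new > config.max_id_ms:
        new = config.max_id_ms
    track.current_id_ms = new


def step(
    track: StaircaseTrack,
    correct: bool,
    config: StaircaseConfig,
    cic_interval: int | None = None,
    response_interval: int | None = None,
) -> StaircaseTrack:
    """Record one trial outcome and apply the 3-down/1-up rule in place.

    After ``n_down`` consecutive correct responses the delay increases by the
    current step and the run counter resets; any error decreases the delay and
    resets the counter.  A reversal is recorded (at the pre-step delay) whenever
    the direction of movement flips.  The track finishes when the configured
    number of reversals or the trial budget is reached.
    """
    if track.finished:
        raise StaircaseError("cannot step a finished track")
    rec = TrialRecord(
        id_ms=track.current_id_ms,
        cic_interval=cic_interval,
        response_interval=response_interval,
        correct=bool(correct),
    )
    track.trials.append(rec)
    direction = 0
    if correct:
        track.consecutive_correct += 1
        if track.consecutive_correct >= config.n_down:
            direction = +1
            track.consecutive_correct = 0
    else:
        direction = -1
        track.consecutive_correct = 0
    if direction != 0:
        if track.last_direction != 0 and direction != track.last_direction:
            track.reversals.append((track.n_trials - 1, track.current_id_ms))
            rec.reversal = True
        _move(track, direction, config)
        track.last_direction = direction
    if track.n_reversals >= config.n_reversals_total or track.n_trials >= config.max_trials:
        track.finished = True
    return track


def run_track(
    observer,
    condition: BandSpec,
    config: StaircaseConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "psychometric",
    stimulus_config: StimulusConfig | None = None,
    threshold_ms: float | None = None,
) -> StaircaseTrack:
    """Simulate one full 2AFC adaptive track against an observer model.

    In ``"psychometric"`` mode each trial draws correctness from the observer's
    psychometric function at the current delay (the fast path used for bulk
    simulation).  In ``"waveform"`` mode fresh stimuli are synthesized for both
    intervals on every trial and the observer's stimulus-driven decision rule is
    used.  Fully reproducible given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if mode not in ("psychometric", "waveform"):
        raise ValueError("mode must be 'psychometric' or 'waveform'")
    if threshold_ms is None:
        threshold_ms = observer.threshold_for(condition)
    track = StaircaseTrack(current_id_ms=config.initial_id_ms)
    while not track.finished:
        cic_interval = int(rng.integers(1, 3))
        if mode == "psychometric":
            p = observer.p_correct(track.current_id_ms, threshold_ms)
            correct = bool(rng.random() < p)
            response = cic_interval if correct else 3 - cic_interval
        else:
            if stimulus_config is None:
                raise ValueError("waveform mode requires a stimulus_config")
            import dataclasses as _dc

            cfg = _dc.replace(stimulus_config, interaural_delay_ms=track.current_id_ms)
            seeds = rng.integers(0, 2**31 - 1, size=2)
            intervals = [
                build_interval(cfg, condition, contains_cic=(i + 1 == cic_interval), seed=int(s))
                for i, s in enumerate(seeds)
            ]
            response = observer.respond(intervals[0], intervals[1], rng=rng)
            correct = response == cic_interval
        step(track, correct, config, cic_interval=cic_interval, response_interval=response)
    return track


@dataclass
class ThresholdEstimate:
    """Longest-delay estimate: per-session values and their mean."""

    t_bar_iai_ms: float
    per_session_ms: list[float]
    sd_ms: float


def _session_threshold(track: StaircaseTrack, config: StaircaseConfig, name: str) -> float:
    k = config.n_reversals_for_threshold
    if track.n_reversals < k:
        raise InsufficientReversalsError(
            f"{name} has {track.n_reversals} reversals; {k} required"
        )
    ids = [id_ms for _, id_ms in track.reversals[-k:]]
    return float(np.mean(ids))


def estimate_threshold(
    tracks: list[StaircaseTrack], config: StaircaseConfig
) -> ThresholdEstimate:
    """Mean delay over the last scheduled reversals of each session, then over sessions."""
    if not tracks:
        raise ValueError("no tracks supplied")
    per_session = [
        _session_threshold(t, config, f"track {i}") for i, t in enumerate(tracks)
    ]
    arr = np.asarray(per_session)
    return ThresholdEstimate(
        t_bar_iai_ms=float(arr.mean()),
        per_session_ms=per_session,
        sd_ms=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


def track_to_frame(track: StaircaseTrack, session_id: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "session_id": session_id,
            "trial": np.arange(track.n_trials),
            "id_ms": [t.id_ms for t in track.trials],
            "cic_interval": [t.cic_interval for t in track.trials],
            "response": [t.response_interval for t in track.trials],
            "correct": [t.correct for t in track.trials],
            "reversal_flag": [t.reversal for t in track.trials],
        }
    )


def write_trial_log(tracks: list[StaircaseTrack], path) -> None:
    frames = [track_to_frame(t, i) for i, t in enumerate(tracks)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
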