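"""Interaural correlation and maximum-coherence metrics.

The interaural coherence of a binaural stimulus is the maximum, over candidate
compensating delays T, of the normalized cross-correlation between the left-ear
signal and the right-ear signal shifted back by T.  For a pair whose right
channel is a delayed copy of the left, the coherence is 1 exactly at the
introduced delay; substituting a fraction f of the right channel with
independent noise lowers the coherence at that lag to about 1 - f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import BinauralStimulus, ms_to_samples

__all__ = [
    "CoherenceCurve",
    "ZeroEnergyError",
    "interaural_correlation",
    "coherence_scan",
    "mean_coherence_curve",
    "coherence_to_csv",
]


class ZeroEnergyError(ValueError):
    """Raised when a correlation is requested over a zero-energy overlap."""


def _channels(stimulus) -> tuple[np.ndarray, np.ndarray, float]:
    if isinstance(stimulus, BinauralStimulus):
        return stimulus.left, stimulus.right, stimulus.sample_rate_hz
    left, right, fs = stimulus
    return np.asarray(left, dtype=float), np.asarray(right, dtype=float), float(fs)


@dataclass
class CoherenceCurve:
    """Normalized interaural correlation over a grid of candidate delays."""

    lags_ms: np.ndarray
    rho: np.ndarray
    theta: float
    argmax_lag_ms: float

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.lags_ms.shape != self.rho.shape:
            raise ValueError("lag grid and correlation values must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ms": self.lags_ms, "rho": self.rho})


def interaural_correlation(stimulus, lag_ms: float) -> float:
    """Normalized cross-correlation of left and lag-shifted right channels.

    A positive lag compensates an introduced interaural delay of the right
    channel: ``rho(lag) = corr(left[:-n], right[n:])`` with ``n`` the lag in
    samples.  The normalization energies are taken over the same overlap, so
    ``|rho| <= 1`` exactly (Cauchy-Schwarz).  Negative lags shift the other way.
    """
    left, right, fs = _channels(stimulus)
    n_total = left.shape[0]
    n = ms_to_samples(abs(lag_ms), fs)
    if n >= n_total:
        raise ValueError(f"lag {lag_ms} ms is at or beyond the waveform length")
    if lag_ms >= 0:
        a = left[: n_total - n] if n else left
        b = right[n:]
    else:
        a = left[n:]
        b = right[: n_total - n] if n else right
    ea = float(np.dot(a, a))
    eb = float(np.dot(b, b))
    if ea == 0.0 or eb == 0.0:
        raise ZeroEnergyError("correlation undefined: a channel has zero energy in the overlap")
    return float(np.dot(a, b) / np.sqrt(ea * eb))


def default_lag_grid(sample_rate_hz: float, max_lag_ms: float = 20.0) -> np.ndarray:
    """One-sample-step lag grid over [0, max_lag_ms]."""
    n_max = ms_to_samples(max_lag_ms, sample_rate_hz)
    return np.arange(n_max + 1) * (1000.0 / sample_rate_hz)


def coherence_scan(
    stimulus,
    lag_grid_ms: np.ndarray | None = None,
    max_lag_ms: float = 20.0,
) -> CoherenceCurve:
    """Evaluate the interaural correlation over a lag grid and take its maximum.

    Ties are broken toward the smallest lag (first index of the maximum on an
    ascending grid).
    """
    left, right, fs = _channels(stimulus)
    if lag_grid_ms is None:
        lag_grid_ms = default_lag_grid(fs, max_lag_ms)
    lag_grid_ms = np.asarray(lag_grid_ms, dtype=float)
    if lag_grid_ms.size == 0:
        raise ValueError("lag grid is empty")
    rho = np.array([interaural_correlation((left, right, fs), lag) for lag in lag_grid_ms])
    idx = int(np.argmax(rho))
    return CoherenceCurve(
        lags_ms=lag_grid_ms,
        rho=rho,
        theta=float(rho[idx]),
        argmax_lag_ms=float(lag_grid_ms[idx]),
    )


def mean_coherence_curve(curves: list[CoherenceCurve]) -> CoherenceCurve:
    """Average several coherence curves sharing one lag grid (per-condition view)."""
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags_ms
    for c in curves[1:]:
        if not np.array_equal(c.lags_ms, lags):
            raise ValueError("curves must share the same lag grid")
    rho = np.mean([c.rho for c in curves], axis=0)
    idx = int(np.argmax(rho))
    return CoherenceCurve(lags, rho, float(rho[idx]), float(lags[idx]))


def coherence_to_csv(curve: CoherenceCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)
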