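"""Synthesis of the binaural noise stimuli used in CIC (change-in-correlation) detection.

A trial interval is a pair of Gaussian noise waveforms presented to the left and
right ears.  In the reference interval the two ears receive identical noise (up to
an interaural delay).  In the target interval the temporal middle of the right-ear
channel is substituted with an interaurally uncorrelated segment, creating an
instantaneous change in correlation (CIC, a "binaural gap").  Narrowband
conditions restrict the noise to a 1/3-octave band around one of five standard
center frequencies; the wideband condition uses the full Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "NARROWBAND_CENTER_FREQUENCIES",
    "BandSpec",
    "StimulusConfig",
    "BinauralStimulus",
    "InvalidBandError",
    "ClippingError",
    "ms_to_samples",
    "generate_noise",
    "build_interval",
    "apply_interaural_delay",
    "write_wav",
    "read_wav",
    "write_sidecar",
]

logger = logging.getLogger(__name__)

#: The five standard narrowband center frequencies, in Hz.
NARROWBAND_CENTER_FREQUENCIES = (200.0, 400.0, 800.0, 1600.0, 3200.0)


class InvalidBandError(ValueError):
    """Raised when a band specification is unusable at the given sample rate."""


class ClippingError(ValueError):
    """Raised when waveform samples exceed full scale and normalization is off."""


#: Guard duration generated on each side of a narrowband waveform and cropped
#: after zero-phase filtering, removing filter start-up transients.
_FILTER_GUARD_MS = 250.0


def ms_to_samples(duration_ms: float, sample_rate_hz: float) -> int:
    """Convert milliseconds to a whole sample count, rounding half up.

    Round-half-up (not banker's rounding) so that e.g. 10.01 ms at 48 kHz maps to
    480 samples and 10.5 samples of delay maps to 11.
    """
    return int(np.floor(duration_ms * sample_rate_hz / 1000.0 + 0.5))


@dataclass(frozen=True)
class BandSpec:
    """Frequency-band specification of a noise stimulus.

    ``kind`` is ``"wideband"`` or ``"narrowband"``.  Narrowband stimuli carry a
    fixed relative bandwidth (default 1/3 octave), so the band edges are
    ``cf * 2**(-bw/2)`` and ``cf * 2**(+bw/2)``.
    """

    kind: str
    center_frequency_hz: float | None = None
    bandwidth_octaves: float = 1.0 / 3.0
    allow_nonstandard_cf: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("wideband", "narrowband"):
            raise InvalidBandError(f"unknown band kind {self.kind!r}")
        if self.bandwidth_octaves <= 0:
            raise InvalidBandError("bandwidth must be positive")
        if self.kind == "narrowband":
            cf = self.center_frequency_hz
            if cf is None or cf <= 0:
                raise InvalidBandError("narrowband requires a positive center frequency")
            if not self.allow_nonstandard_cf and float(cf) not in NARROWBAND_CENTER_FREQUENCIES:
                raise InvalidBandError(
                    f"center frequency {cf} Hz is not one of the standard set "
                    f"{NARROWBAND_CENTER_FREQUENCIES}; pass allow_nonstandard_cf=True "
                    "to override"
                )

    @classmethod
    def wideband(cls) -> "BandSpec":
        return cls(kind="wideband")

    @classmethod
    def narrowband(cls, center_frequency_hz: float, **kwargs) -> "BandSpec":
        return cls(kind="narrowband", center_frequency_hz=center_frequency_hz, **kwargs)

    @property
    def edges_hz(self) -> tuple[float, float] | None:
        """Lower and upper band edges in Hz (None for wideband)."""
        if self.kind == "wideband":
            return None
        cf = float(self.center_frequency_hz)
        half = self.bandwidth_octaves / 2.0
        return (cf * 2.0 ** (-half), cf * 2.0 ** (half))

    @property
    def label(self) -> str:
        if self.kind == "wideband":
            return "wb"
        return f"nb{int(round(self.center_frequency_hz))}"


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of one 2AFC interval.

    Durations are in milliseconds; ``level_dbfs`` is the digital RMS level in dB
    re full scale (absolute SPL calibration is hardware and out of scope).
    ``alpha`` is the correlation-mixing coefficient of the CIC segment: alpha=0
    gives a fully uncorrelated segment, alpha=1 degenerates to the unmodified
    interval.  ``mixer`` selects between the amplitude-linear mixing rule
    ("printed") and the power-preserving rule ("power"); the two agree at
    alpha in {0, 1}.
    """

    sample_rate_hz: float = 48000.0
    interval_duration_ms: float = 2000.0
    cic_duration_ms: float = 200.0
    interaural_delay_ms: float = 0.0
    alpha: float = 0.0
    level_dbfs: float = -20.0
    mixer: str = "printed"
    filter_order: int = 8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.interval_duration_ms <= 0:
            raise ValueError("interval duration must be positive")
        if self.cic_duration_ms < 0 or self.cic_duration_ms > self.interval_duration_ms:
            raise ValueError("cic_duration_ms must lie in [0, interval_duration_ms]")
        if self.interaural_delay_ms < 0:
            raise ValueError("interaural delay must be >= 0")
        if self.interaural_delay_ms > self.interval_duration_ms:
            raise ValueError("interaural delay exceeds the interval duration")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.mixer not in ("printed", "power"):
            raise ValueError("mixer must be 'printed' or 'power'")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")

    @property
    def n_samples(self) -> int:
        return ms_to_samples(self.interval_duration_ms, self.sample_rate_hz)

    @property
    def cic_n_samples(self) -> int:
        return ms_to_samples(self.cic_duration_ms, self.sample_rate_hz)

    @property
    def delay_n_samples(self) -> int:
        return ms_to_samples(self.interaural_delay_ms, self.sample_rate_hz)

    @property
    def target_rms(self) -> float:
        return 10.0 ** (self.level_dbfs / 20.0)


@dataclass
class BinauralStimulus:
    """A left/right waveform pair with its generating metadata.

    ``cic_window`` is the half-open ``(start, end)`` sample window of the
    substituted segment, in coordinates of the undelayed (left) channel; it is
    ``None`` when the interval contains no CIC.
    """

    left: np.ndarray
    right: np.ndarray
    config: StimulusConfig
    band: BandSpec
    cic_window: tuple[int, int] | None = None
    contains_cic: bool = False

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")

    @property
    def sample_rate_hz(self) -> float:
        return self.config.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return int(self.left.shape[0])

    def channel_rms(self) -> tuple[float, float]:
        return (
            float(np.sqrt(np.mean(self.left**2))),
            float(np.sqrt(np.mean(self.right**2))),
        )


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def _band_sos(band: BandSpec, sample_rate_hz: float, order: int) -> np.ndarray:
    lo, hi = band.edges_hz
    nyquist = sample_rate_hz / 2.0
    if hi >= nyquist:
        raise InvalidBandError(
            f"upper band edge {hi:.1f} Hz is at or above Nyquist ({nyquist:.1f} Hz)"
        )
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate_hz, output="sos")


def generate_noise(
    config: StimulusConfig,
    band: BandSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate one Gaussian noise waveform for the given band.

    Wideband noise is i.i.d. Gaussian; narrowband noise is the same noise passed
    through a zero-phase Butterworth bandpass (applied forward-backward, so the
    effective roll-off is twice the nominal order).  The result is scaled to the
    configured RMS level.  Reproducible: the same ``(config, band, seed)`` always
    yields the same waveform.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if band.kind == "narrowband":
        # generate with guard samples and crop after filtering: the narrow
        # filter rings for tens of ms and its start-up transients would
        # otherwise leak broadband energy into the kept waveform
        pad = ms_to_samples(_FILTER_GUARD_MS, config.sample_rate_hz)
        x = rng.standard_normal(config.n_samples + 2 * pad)
        sos = _band_sos(band, config.sample_rate_hz, config.filter_order)
        x = signal.sosfiltfilt(sos, x)[pad : pad + config.n_samples]
    else:
        x = rng.standard_normal(config.n_samples)
    rms = _rms(x)
    if rms == 0.0:
        raise ValueError("generated waveform has zero energy")
    return x * (config.target_rms / rms)


def _mix_cic_segment(
    h1_seg: np.ndarray, h2_seg: np.ndarray, alpha: float, mixer: str
) -> np.ndarray:
    """Replace a segment of the right channel with a partially correlated mixture.

    In "printed" mode the independent noise is pre-scaled so its RMS is
    ``(1 - alpha)`` times the RMS of the original segment, under which the mixing
    identity ``alpha*h1 + h2 + (1 - alpha - |h2|/|h1|)*h1`` reduces to the
    amplitude-linear mixer ``alpha*h1 + (1-alpha)*h2_hat``.  "power" mode uses the
    power-preserving mixer ``alpha*h1 + sqrt(1-alpha^2)*h2_hat``.
    """
    rms1 = _rms(h1_seg)
    rms2 = _rms(h2_seg)
    if rms2 == 0.0:
        raise ValueError("independent CIC noise segment has zero energy")
    if mixer == "printed":
        h2_scaled = h2_seg * ((1.0 - alpha) * rms1 / rms2)
        ratio = _rms(h2_scaled) / rms1 if rms1 > 0 else 0.0
        return alpha * h1_seg + h2_scaled + (1.0 - alpha - ratio) * h1_seg
    # power-preserving
    h2_hat = h2_seg * (rms1 / rms2)
    return alpha * h1_seg + np.sqrt(max(0.0, 1.0 - alpha**2)) * h2_hat


def build_interval(
    config: StimulusConfig,
    band: BandSpec,
    contains_cic: bool,
    seed: int | None = None,
) -> BinauralStimulus:
    """Construct one 2AFC interval.

    Without a CIC the right channel is the left channel (delayed by the
    configured interaural delay).  With a CIC, the temporal middle
    ``cic_duration_ms`` of the right channel is first substituted with an
    independent noise mixture, then the delay is applied.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h1 = generate_noise(config, band, rng=rng)
    left = h1
    right = h1.copy()
    cic_window = None
    if contains_cic:
        n = config.n_samples
        n_cic = config.cic_n_samples
        if n_cic == 0:
            raise ValueError("contains_cic=True requires cic_duration_ms > 0")
        start = (n - n_cic) // 2
        end = start + n_cic
        cic_window = (start, end)
        h2 = generate_noise(config, band, rng=rng)
        right[start:end] = _mix_cic_segment(
            h1[start:end], h2[start:end], config.alpha, config.mixer
        )
    stim = BinauralStimulus(
        left=left,
        right=right,
        config=dataclasses.replace(config, interaural_delay_ms=0.0),
        band=band,
        cic_window=cic_window,
        contains_cic=contains_cic,
    )
    if config.interaural_delay_ms > 0:
        stim = apply_interaural_delay(stim, config.interaural_delay_ms)
    else:
        stim.config = config
    return stim


def apply_interaural_delay(stimulus: BinauralStimulus, delay_ms: float) -> BinauralStimulus:
    """Delay the right channel by ``delay_ms`` relative to the left.

    The delay is realized as an integer-sample shift (round-half-up; at 48 kHz
    the quantization is ~20.8 us, far below measured longest delays).  Both
    channels are zero-padded to equal length; the CIC window stays in undelayed
    (left-channel) coordinates.
    """
    if delay_ms < 0:
        raise ValueError("delay must be >= 0")
    if delay_ms > stimulus.config.interval_duration_ms:
        raise ValueError("delay exceeds the interval duration")
    n = ms_to_samples(delay_ms, stimulus.sample_rate_hz)
    if n == 0:
        new_cfg = dataclasses.replace(
            stimulus.config,
            interaural_delay_ms=stimulus.config.interaural_delay_ms + delay_ms,
        )
        return BinauralStimulus(
            left=stimulus.left.copy(),
            right=stimulus.right.copy(),
            config=new_cfg,
            band=stimulus.band,
            cic_window=stimulus.cic_window,
            contains_cic=stimulus.contains_cic,
        )
    left = np.concatenate([stimulus.left, np.zeros(n)])
    right = np.concatenate([np.zeros(n), stimulus.right])
    new_cfg = dataclasses.replace(
        stimulus.config,
        interaural_delay_ms=stimulus.config.interaural_delay_ms + delay_ms,
    )
    return BinauralStimulus(
        left=left,
        right=right,
        config=new_cfg,
        band=stimulus.band,
        cic_window=stimulus.cic_window,
        contains_cic=stimulus.contains_cic,
    )


def write_wav(
    stimulus,
    path,
    encoding: str = "float32",
    normalize: bool = False,
) -> None:
    """Write a stereo WAV file (left ear = channel 0).

    ``stimulus`` may be a :class:`BinauralStimulus` or an ``(n, 2)`` array plus a
    config-borne sample rate.  Samples exceeding full scale raise
    :class:`ClippingError` unless ``normalize`` is set, in which case the pair is
    rescaled to a 0.99 peak.  ``encoding`` is ``"float32"`` (lossless round-trip)
    or ``"pcm16"``.
    """
    if isinstance(stimulus, BinauralStimulus):
        data = np.stack([stimulus.left, stimulus.right], axis=1)
        fs = int(round(stimulus.sample_rate_hz))
    else:
        data = np.asarray(stimulus)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError("expected a stereo (n, 2) array; mono input is not accepted")
        raise TypeError("raw arrays require a BinauralStimulus for the sample rate")
    peak = float(np.max(np.abs(data))) if data.size else 0.0
    if peak > 1.0:
        if not normalize:
            raise ClippingError(
                f"peak amplitude {peak:.3f} exceeds full scale; pass normalize=True"
            )
        data = data * (0.99 / peak)
    if encoding == "float32":
        wavfile.write(path, fs, data.astype(np.float32))
    elif encoding == "pcm16":
        scaled = np.clip(np.round(data * 32767.0), -32768, 32767).astype(np.int16)
        wavfile.write(path, fs, scaled)
    else:
        raise ValueError("encoding must be 'float32' or 'pcm16'")


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a WAV file, returning ``(sample_rate, float array in [-1, 1])``."""
    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483647.0
    else:
        data = data.astype(np.float64)
    return int(fs), data


def write_sidecar(stimulus: BinauralStimulus, path) -> None:
    """Write a JSON metadata sidecar describing the stimulus."""
    meta = {
        "config": dataclasses.asdict(stimulus.config),
        "band": dataclasses.asdict(stimulus.band),
        "cic_window": list(stimulus.cic_window) if stimulus.cic_window else None,
        "contains_cic": stimulus.contains_cic,
        "n_samples": stimulus.n_samples,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
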