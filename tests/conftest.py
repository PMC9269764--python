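import numpy as np
import pytest

from binauralgap import BandSpec, StimulusConfig


@pytest.fixture
def short_config():
    """A small, fast stimulus configuration for waveform-level tests."""
    return StimulusConfig(
        sample_rate_hz=8000.0,
        interval_duration_ms=400.0,
        cic_duration_ms=100.0,
    )


@pytest.fixture
def full_config():
    """The study-scale configuration (48 kHz, 2000 ms, 200 ms CIC)."""
    return StimulusConfig()


@pytest.fixture
def wideband():
    return BandSpec.wideband()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
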