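import sys
from datetime import datetime
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from actikit import RawRecording

START = datetime(2021, 6, 1, 0, 0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(20210601)


@pytest.fixture
def make_recording():
    """Factory: build a RawRecording from per-axis arrays (60 Hz default)."""

    def _make(y, x=None, z=None, fs=60.0):
        y = np.asarray(y, dtype=float)
        x = np.zeros_like(y) if x is None else np.asarray(x, dtype=float)
        z = np.zeros_like(y) if z is None else np.asarray(z, dtype=float)
        return RawRecording(sample_rate_hz=fs, start_time=START, x=x, y=y, z=z)

    return _make


@pytest.fixture
def sinusoid():
    """Factory: sinusoid in g at a given frequency/amplitude/duration."""

    def _make(freq_hz, amplitude_g, duration_s, fs=60.0):
        t = np.arange(int(round(duration_s * fs))) / fs
        return amplitude_g * np.sin(2 * np.pi * freq_hz * t)

    return _make
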