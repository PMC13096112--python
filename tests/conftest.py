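import numpy as np
import pytest

from stimvision import ApertureTrace, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def sinusoid_trace():
    """10 s pure sinusoid: 1.5 Hz, amplitude 0.4, offset 0.5, 60 Hz sampling."""
    t = np.arange(0, 10, 1 / 60)
    s = 0.5 + 0.4 * np.sin(2 * np.pi * 1.5 * t)
    return ApertureTrace(s, sampling_rate=60, patient_id="P01", hand="right", condition="OFF")


def make_sinusoid(freq=1.5, amp=0.4, offset=0.5, duration=10.0, fs=60.0, condition="OFF"):
    t = np.arange(0, duration, 1 / fs)
    s = offset + amp * np.sin(2 * np.pi * freq * t)
    return ApertureTrace(s, sampling_rate=fs, patient_id="P01", hand="right", condition=condition)
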