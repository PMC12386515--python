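import numpy as np
import pytest

from balancelab.signals import CoPTrace, SampledSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_signal(x, rate=100.0, channels=None, units=None):
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    channels = channels or tuple(f"ch{i}" for i in range(x.shape[1]))
    units = units or ("m",) * x.shape[1]
    return SampledSignal(x, rate=rate, channels=channels, units=units)


def sinusoid_trace(amp, freq, duration, rate, axis="ml", condition="EOWF"):
    """CoPTrace with a pure sinusoid on one axis, zeros on the other."""
    t = np.arange(int(round(duration * rate))) / rate
    wave = amp * np.sin(2 * np.pi * freq * t)
    zero = np.zeros_like(wave)
    ml, ap = (wave, zero) if axis == "ml" else (zero, wave)
    return CoPTrace(ml=ml, ap=ap, rate=rate, condition=condition)
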