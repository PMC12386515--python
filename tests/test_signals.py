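"""Preprocessing front-end: offset removal, filtering, windowing, derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balancelab.signals import (
    CoPTrace,
    InvalidSignalError,
    PipelineStageError,
    SampledSignal,
    butterworth_lowpass,
    differentiate,
    extract_central_window,
    integrate,
    preprocess_static_trial,
    remove_offset,
)
from conftest import make_signal


class TestRemoveOffset:
    @pytest.mark.parametrize(
        "data,expected",
        [([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]), ([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0])],
    )
    def test_small_cases(self, data, expected):
        out = remove_offset(make_signal(data))
        np.testing.assert_allclose(out.data[:, 0], expected, atol=1e-15)

    def test_brute_force_mean_oracle(self, rng):
        x = rng.normal(3.7, 2.0, 500)
        mean = sum(x) / len(x)  # direct summation oracle
        out = remove_offset(make_signal(x)).data[:, 0]
        np.testing.assert_allclose(out, x - mean, atol=1e-12)
        assert abs(out.mean()) < 1e-9 * out.std() + 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidSignalError):
            SampledSignal(np.array([[1.0]]), rate=100.0, channels=("x",))


class TestButterworth:
    def test_dc_gain_unity(self):
        sig = make_signal(np.full(2000, 3.25), rate=100.0)
        out = butterworth_lowpass(sig, order=4, cutoff_hz=3.5)
        np.testing.assert_allclose(out.data[:, 0], 3.25, rtol=1e-9)

    def test_passband_amplitude_preserved(self):
        rate = 100.0
        t = np.arange(0, 60, 1 / rate)
        sig = make_signal(np.sin(2 * np.pi * 0.1 * t), rate=rate)
        out = butterworth_lowpass(sig, order=4, cutoff_hz=3.5).data[:, 0]
        c = slice(int(0.1 * t.size), int(0.9 * t.size))
        assert abs(np.max(np.abs(out[c])) - 1.0) < 0.01

    def test_stopband_attenuation(self):
        rate = 1000.0
        t = np.arange(0, 10, 1 / rate)
        sig = make_signal(np.sin(2 * np.pi * 35.0 * t), rate=rate)
        out = butterworth_lowpass(sig, order=4, cutoff_hz=3.5).data[:, 0]
        c = slice(int(0.1 * t.size), int(0.9 * t.size))
        # zero-phase = squared 4th-order magnitude: (1/(1+10^8))^1 ~ 1e-8 << 1e-3
        assert np.max(np.abs(out[c])) < 1e-3

    def test_cutoff_at_nyquist_rejected(self):
        sig = make_signal(np.zeros(100), rate=100.0)
        with pytest.raises(InvalidSignalError):
            butterworth_lowpass(sig, order=4, cutoff_hz=50.0)

    def test_causal_mode_differs_but_same_length(self, rng):
        sig = make_signal(rng.normal(0, 1, 1000), rate=100.0)
        zp = butterworth_lowpass(sig, 4, 3.5, zero_phase=True)
        ca = butterworth_lowpass(sig, 4, 3.5, zero_phase=False)
        assert zp.n_samples == ca.n_samples == 1000
        assert not np.allclose(zp.data, ca.data)


class TestCentralWindow:
    @pytest.mark.parametrize(
        "dur,rate,win,start",
        [
            (90.0, 100.0, 60.0, 1500),   # samples [1500, 7500)
            (60.0, 100.0, 60.0, 0),      # identity
            (61.5, 1000.0, 60.0, 750),   # floor((L-W)/2)
        ],
    )
    def test_start_index(self, dur, rate, win, start):
        n = int(round(dur * rate))
        sig = make_signal(np.arange(n, dtype=float), rate=rate)
        out = extract_central_window(sig, win)
        assert out.n_samples == int(round(win * rate))
        assert out.data[0, 0] == start

    def test_too_short_rejected(self):
        sig = make_signal(np.zeros(100), rate=10.0)  # 10 s
        with pytest.raises(InvalidSignalError):
            extract_central_window(sig, 60.0)


class TestDifferentiate:
    def test_ramp_exact(self):
        rate, v = 100.0, 0.37
        x = v * np.arange(500) / rate
        out = differentiate(make_signal(x, rate=rate)).data[:, 0]
        np.testing.assert_allclose(out, v, rtol=1e-10)

    def test_constant_zero(self):
        out = differentiate(make_signal(np.full(100, 2.0))).data[:, 0]
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_sinusoid_truncation_bound(self):
        f, rate = 1.0, 200.0
        t = np.arange(0, 5, 1 / rate)
        out = differentiate(make_signal(np.sin(2 * np.pi * f * t), rate=rate)).data[:, 0]
        exact = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        interior = slice(1, -1)
        bound = (2 * np.pi * f) ** 3 / (6 * rate**2)
        assert np.max(np.abs(out[interior] - exact[interior])) < bound

    def test_units_divided_by_seconds(self):
        out = differentiate(make_signal(np.arange(10.0), units=("m",)))
        assert out.units == ("m/s",)

    def test_round_trip_with_integrator(self, rng):
        # differentiate(integrate(x)) ~ x for smooth band-limited input
        rate = 100.0
        t = np.arange(0, 10, 1 / rate)
        x = np.sin(2 * np.pi * 0.5 * t) + 0.3 * np.cos(2 * np.pi * 1.2 * t)
        sig = make_signal(x, rate=rate)
        back = differentiate(integrate(sig)).data[1:-1, 0]
        assert np.max(np.abs(back - x[1:-1])) < 5e-3


class TestStaticPipeline:
    def _raw(self, rng, duration=90.0, rate=100.0, offset=(0.0, 0.0)):
        t = np.arange(int(duration * rate)) / rate
        ml = 0.01 * np.sin(2 * np.pi * 0.3 * t) + 0.002 * rng.normal(size=t.size)
        ap = 0.01 * np.cos(2 * np.pi * 0.2 * t) + 0.002 * rng.normal(size=t.size)
        return make_signal(
            np.column_stack([ml + offset[0], ap + offset[1]]),
            rate=rate,
            channels=("ml", "ap"),
        )

    def test_window_and_zero_mean_invariants(self, rng):
        trace = preprocess_static_trial(self._raw(rng), window_s=60.0)
        assert trace.n_samples == 6000
        assert abs(trace.ml.mean()) < 1e-9
        assert abs(trace.ap.mean()) < 1e-9

    def test_translation_invariance(self, rng):
        raw = self._raw(rng)
        shifted = make_signal(
            raw.data + np.array([0.3, -0.2]), rate=raw.rate, channels=("ml", "ap")
        )
        a = preprocess_static_trial(raw)
        b = preprocess_static_trial(shifted)
        assert np.max(np.abs(a.ml - b.ml)) < 1e-9
        assert np.max(np.abs(a.ap - b.ap)) < 1e-9

    def test_sub_cutoff_amplitude_preserved(self):
        rate = 100.0
        t = np.arange(int(90 * rate)) / rate
        raw = make_signal(
            np.column_stack([0.01 * np.sin(2 * np.pi * 0.25 * t), np.zeros(t.size)]),
            rate=rate,
            channels=("ml", "ap"),
        )
        trace = preprocess_static_trial(raw)
        c = slice(int(0.1 * trace.n_samples), int(0.9 * trace.n_samples))
        assert abs(np.max(np.abs(trace.ml[c])) - 0.01) < 1e-4

    def test_short_input_reports_stage(self, rng):
        with pytest.raises(PipelineStageError) as err:
            preprocess_static_trial(self._raw(rng, duration=30.0), window_s=60.0)
        assert err.value.stage == "extract_central_window"

    def test_bad_condition_rejected(self, rng):
        with pytest.raises(InvalidSignalError):
            preprocess_static_trial(self._raw(rng), condition="XYZ")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    offset=st.floats(-10, 10, allow_nan=False),
    amp=st.floats(1e-4, 0.05),
    freq=st.floats(0.05, 1.0),
)
def test_pipeline_translation_invariance_property(offset, amp, freq):
    """Adding any constant to a channel changes the preprocessed output by < 1 nm."""
    rate = 50.0
    t = np.arange(int(30 * rate)) / rate
    base = np.column_stack(
        [amp * np.sin(2 * np.pi * freq * t), amp * np.cos(2 * np.pi * freq * t)]
    )
    raw = make_signal(base, rate=rate, channels=("ml", "ap"))
    shifted = make_signal(base + offset, rate=rate, channels=("ml", "ap"))
    a = preprocess_static_trial(raw, window_s=20.0)
    b = preprocess_static_trial(shifted, window_s=20.0)
    assert np.max(np.abs(a.ml - b.ml)) < 1e-9
    assert np.max(np.abs(a.ap - b.ap)) < 1e-9
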