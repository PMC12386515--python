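"""Deterministic preprocessing of raw force-plate / accelerometer recordings.

This module is the shared front-end for the center-of-pressure (CoP) and
center-of-mass (CoM) pathways: offset removal, low-pass Butterworth filtering,
extraction of the central analysis window, and finite-difference
differentiation.  The static-trial pipeline mirrors standard stabilometric
practice: each displacement channel is demeaned (the offset is the subject's
standing position, not sway), filtered with a fourth-order low-pass Butterworth
at 3.5 Hz, and the central 60 s of the record are retained for analysis.

Filtering is zero-phase by default (forward-backward application of the
designed filter), because phase distortion would bias derivative-based metrics
such as jerk; a causal single-pass mode is available behind ``zero_phase=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "InvalidSignalError",
    "PipelineStageError",
    "SampledSignal",
    "CoPTrace",
    "STANDING_CONDITIONS",
    "remove_offset",
    "butterworth_lowpass",
    "extract_central_window",
    "differentiate",
    "integrate",
    "preprocess_static_trial",
]

#: Standing conditions: eyes open/closed x wide/narrowed feet.
STANDING_CONDITIONS = ("EOWF", "ECWF", "EONF", "ECNF")


class InvalidSignalError(ValueError):
    """Raised when a signal violates an operation's preconditions."""


class PipelineStageError(InvalidSignalError):
    """A preprocessing stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _per_second(unit: str) -> str:
    """Unit string after one differentiation in time."""
    if unit.endswith("/s"):
        return unit + "^2" if not unit.endswith("/s^2") else unit[:-2] + "^3"
    return f"{unit}/s"


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Sample values, one column per channel.
    rate : float
        Sampling frequency in Hz.
    channels : tuple of str
        Ordered channel labels.
    units : tuple of str
        Per-channel unit strings (same length as ``channels``).
    """

    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    units: tuple[str, ...] = field(default=())

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        if data.ndim != 2:
            raise InvalidSignalError("data must be 1-D or 2-D (samples x channels)")
        if data.shape[0] < 2:
            raise InvalidSignalError("signal needs at least 2 samples")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise InvalidSignalError(f"rate must be positive, got {self.rate}")
        channels = tuple(self.channels)
        if len(channels) != data.shape[1]:
            raise InvalidSignalError(
                f"{len(channels)} channel labels for {data.shape[1]} columns"
            )
        units = tuple(self.units) if self.units else ("",) * len(channels)
        if len(units) != len(channels):
            raise InvalidSignalError("units must match channels")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", channels)
        object.__setattr__(self, "units", units)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Record duration in seconds (n_samples / rate)."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by (case-insensitive) label."""
        labels = [c.lower() for c in self.channels]
        try:
            return self.data[:, labels.index(name.lower())]
        except ValueError:
            raise InvalidSignalError(
                f"channel {name!r} not in {self.channels}"
            ) from None


@dataclass(frozen=True)
class CoPTrace:
    """Preprocessed zero-mean CoP displacement pair for one standing trial.

    ``ml``/``ap`` are medio-lateral and antero-posterior displacements in
    metres, demeaned over the analysis window.
    """

    ml: np.ndarray
    ap: np.ndarray
    rate: float
    condition: str = "EOWF"

    def __post_init__(self):
        ml = np.asarray(self.ml, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        if ml.shape != ap.shape or ml.ndim != 1:
            raise InvalidSignalError("ml and ap must be equal-length 1-D arrays")
        if ml.size < 2:
            raise InvalidSignalError("trace needs at least 2 samples")
        if self.rate <= 0:
            raise InvalidSignalError("rate must be positive")
        if self.condition not in STANDING_CONDITIONS:
            raise InvalidSignalError(
                f"condition must be one of {STANDING_CONDITIONS}, got {self.condition!r}"
            )
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "ap", ap)

    @property
    def n_samples(self) -> int:
        return self.ml.size

    @property
    def duration(self) -> float:
        return self.ml.size / self.rate


def remove_offset(sig: SampledSignal) -> SampledSignal:
    """Subtract each channel's own mean (the subject's standing offset)."""
    if sig.n_samples < 2:
        raise InvalidSignalError("offset removal needs at least 2 samples")
    return replace(sig, data=sig.data - sig.data.mean(axis=0, keepdims=True))


def butterworth_lowpass(
    sig: SampledSignal,
    order: int = 4,
    cutoff_hz: float = 3.5,
    zero_phase: bool = True,
) -> SampledSignal:
    """Low-pass Butterworth filter, zero-phase by default.

    Zero-phase mode applies the designed filter forward and backward
    (``scipy.signal.filtfilt`` with its default odd-reflection padding of
    ``3 * (max(len(a), len(b)) - 1)`` samples), so the effective magnitude
    response is the square of the designed one.  ``zero_phase=False`` gives a
    single causal pass.

    Raises
    ------
    InvalidSignalError
        If ``cutoff_hz`` is not inside (0, rate/2) or ``order < 1``.
    """
    nyquist = sig.rate / 2.0
    if not 0.0 < cutoff_hz < nyquist:
        raise InvalidSignalError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz"
        )
    if order < 1:
        raise InvalidSignalError("filter order must be >= 1")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sig.rate, output="sos")
    if zero_phase:
        b, a = sps.butter(order, cutoff_hz, btype="low", fs=sig.rate)
        out = sps.filtfilt(b, a, sig.data, axis=0)
    else:
        out = sps.sosfilt(sos, sig.data, axis=0)
    return replace(sig, data=out)


def extract_central_window(sig: SampledSignal, duration_s: float) -> SampledSignal:
    """Extract ``duration_s`` seconds from the middle of the record.

    The window has ``round(duration_s * rate)`` samples starting at index
    ``floor((L - W) / 2)``.
    """
    n_win = int(round(duration_s * sig.rate))
    if n_win < 2:
        raise InvalidSignalError("window too short")
    if n_win > sig.n_samples:
        raise InvalidSignalError(
            f"signal of {sig.duration:.3f} s is shorter than the "
            f"{duration_s} s analysis window"
        )
    start = (sig.n_samples - n_win) // 2
    return replace(sig, data=sig.data[start : start + n_win])


def differentiate(sig: SampledSignal) -> SampledSignal:
    """Time derivative by central differences (one-sided at the endpoints).

    Exact for linear signals; output keeps the input length and rate, with
    per-channel units divided by seconds.
    """
    if sig.n_samples < 3:
        raise InvalidSignalError("differentiation needs at least 3 samples")
    out = np.gradient(sig.data, 1.0 / sig.rate, axis=0, edge_order=1)
    return replace(sig, data=out, units=tuple(_per_second(u) for u in sig.units))


def integrate(sig: SampledSignal) -> SampledSignal:
    """Cumulative trapezoidal integral from t=0 (test oracle counterpart of
    :func:`differentiate`)."""
    dt = 1.0 / sig.rate
    out = np.concatenate(
        [
            np.zeros((1, sig.data.shape[1])),
            np.cumsum((sig.data[1:] + sig.data[:-1]) / 2.0 * dt, axis=0),
        ]
    )
    return replace(sig, data=out, units=tuple(f"{u}*s" for u in sig.units))


def preprocess_static_trial(
    raw: SampledSignal,
    condition: str = "EOWF",
    window_s: float = 60.0,
    cutoff_hz: float = 3.5,
    order: int = 4,
    zero_phase: bool = True,
) -> CoPTrace:
    """Full static-trial pipeline: demean, filter, central window.

    Follows the acquisition-order convention: the offset is removed over the
    whole record, the record is filtered, and only then is the central
    ``window_s`` segment retained — so filter edge transients fall outside the
    analysis window.  The retained window is demeaned once more so the trace
    is exactly zero-mean (the windowed segment of a globally demeaned record
    is not).

    Stage failures are re-raised as :class:`PipelineStageError` with the stage
    name attached.
    """

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except InvalidSignalError as exc:
            raise PipelineStageError(name, str(exc)) from exc

    demeaned = _stage("remove_offset", remove_offset, raw)
    filtered = _stage(
        "butterworth_lowpass",
        butterworth_lowpass,
        demeaned,
        order=order,
        cutoff_hz=cutoff_hz,
        zero_phase=zero_phase,
    )
    windowed = _stage("extract_central_window", extract_central_window, filtered, window_s)
    final = _stage("remove_offset", remove_offset, windowed)
    return CoPTrace(
        ml=final.channel("ml"),
        ap=final.channel("ap"),
        rate=final.rate,
        condition=condition,
    )
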