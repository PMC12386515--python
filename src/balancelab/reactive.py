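"""Reactive-balance features from treadmill-perturbation trials.

A perturbation trial exposes the subject to three brief belt accelerations
(6 m/s² up to 0.4 m/s) while the preprocessed antero-posterior (AP) CoP
component is recorded.  For each perturbation five features are extracted and
then averaged across the three repetitions:

* ``range_p`` — AP CoP range (max - min) during the active perturbation;
* ``range_r`` — AP CoP range during the subsequent recovery phase;
* ``peak``    — peak absolute baseline-referenced AP excursion;
* ``ttp``     — time from perturbation onset to that peak;
* ``tor``     — time from the end of the active phase until the CoP re-enters
  the baseline band (baseline mean ± max(k·SD, floor)) and dwells there.

The active phase ends when the belt-speed channel drops back below threshold;
with CoP-only input a configured fixed active duration is used (default 1.5 s:
the 0.4 m/s plateau reached at 6 m/s² plus a plateau estimate).  Recovery is
declared at re-entry into the baseline band with a minimum dwell (default 1 s);
band multiplier, floor and dwell are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signals import InvalidSignalError

__all__ = [
    "SegmentationError",
    "ReactiveConfig",
    "PerturbationFeatures",
    "PerturbationTrial",
    "detect_onsets",
    "perturbation_features",
    "average_perturbations",
    "analyze_perturbation_trial",
]


class SegmentationError(InvalidSignalError):
    """Onset segmentation found an unexpected number of perturbations."""


@dataclass(frozen=True)
class ReactiveConfig:
    """Tunable thresholds of the reactive-feature extraction.

    Attributes
    ----------
    belt_threshold : m/s, belt counts as moving above this speed.
    cop_rate_threshold : m/s, |d(AP)/dt| onset threshold in CoP-only mode.
    refractory_s : minimum spacing between detected onsets.
    baseline_s : length of the pre-onset baseline segment.
    active_duration_s : active-phase length when no belt channel is present.
    band_multiplier : recovery band half-width in baseline SDs.
    band_floor_m : absolute lower bound on the band half-width (quiet
        baselines would otherwise shrink the band to ~0).
    dwell_s : time the CoP must stay inside the band to count as recovered.
    rate_smooth_s : moving-average window applied to |d(AP)/dt| before
        thresholding in CoP-only onset detection.
    """

    belt_threshold: float = 0.01
    cop_rate_threshold: float = 0.05
    refractory_s: float = 5.0
    baseline_s: float = 2.0
    active_duration_s: float = 1.5
    band_multiplier: float = 2.0
    band_floor_m: float = 1e-3
    dwell_s: float = 1.0
    rate_smooth_s: float = 0.1

    def __post_init__(self):
        for name in (
            "belt_threshold",
            "cop_rate_threshold",
            "refractory_s",
            "baseline_s",
            "active_duration_s",
            "band_multiplier",
            "band_floor_m",
            "dwell_s",
            "rate_smooth_s",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSignalError(f"{name} must be positive")


@dataclass(frozen=True)
class PerturbationFeatures:
    """Recovery features for one (or averaged) perturbation.

    ``range_r`` and ``tor`` are ``None`` when no recovery was observed before
    the next perturbation (recorded, never fabricated).  ``n`` counts the
    perturbations contributing to an averaged record.
    """

    range_p: float
    range_r: Optional[float]
    peak: float
    ttp: float
    tor: Optional[float]
    n: int = 1


@dataclass(frozen=True)
class PerturbationTrial:
    """Preprocessed AP CoP for one perturbation trial.

    ``belt_speed`` is the optional commanded belt-speed channel (m/s, same
    rate); ``onsets`` are known perturbation sample indices when available.
    """

    cop_ap: np.ndarray
    rate: float
    belt_speed: Optional[np.ndarray] = None
    onsets: Optional[tuple[int, ...]] = None
    expected_perturbations: int = 3

    def __post_init__(self):
        ap = np.asarray(self.cop_ap, dtype=float)
        if ap.ndim != 1 or ap.size < 2:
            raise InvalidSignalError("cop_ap must be a 1-D array of >= 2 samples")
        if self.rate <= 0:
            raise InvalidSignalError("rate must be positive")
        object.__setattr__(self, "cop_ap", ap)
        if self.belt_speed is not None:
            bs = np.asarray(self.belt_speed, dtype=float)
            if bs.shape != ap.shape:
                raise InvalidSignalError("belt_speed must match cop_ap length")
            object.__setattr__(self, "belt_speed", bs)
        if self.onsets is not None:
            onsets = tuple(int(i) for i in self.onsets)
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise InvalidSignalError("onsets must be strictly increasing")
            object.__setattr__(self, "onsets", onsets)


def _epoch_starts(mask: np.ndarray) -> np.ndarray:
    """First index of each contiguous True epoch."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx
    starts = idx[np.concatenate([[True], np.diff(idx) > 1])]
    return starts


def detect_onsets(
    trial: PerturbationTrial, config: ReactiveConfig = ReactiveConfig()
) -> tuple[int, ...]:
    """Locate perturbation onsets.

    Belt-speed mode: the first sample of each contiguous epoch with speed
    above ``belt_threshold``.  CoP-only mode: upward crossings of
    ``|d(AP)/dt|`` above ``cop_rate_threshold``, separated by at least the
    refractory period.  Exactly ``trial.expected_perturbations`` onsets must
    be found, otherwise a :class:`SegmentationError` lists the candidates.
    """
    expected = trial.expected_perturbations
    if trial.belt_speed is not None:
        starts = _epoch_starts(trial.belt_speed > config.belt_threshold)
        candidates = list(starts)
    else:
        rate_sig = np.abs(np.gradient(trial.cop_ap, 1.0 / trial.rate))
        # centered moving average suppresses sample-scale derivative noise
        # without shifting the crossing
        k = max(int(round(config.rate_smooth_s * trial.rate)), 1)
        rate_sig = np.convolve(rate_sig, np.ones(k) / k, mode="same")
        above = rate_sig > config.cop_rate_threshold
        crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        refractory = int(round(config.refractory_s * trial.rate))
        candidates = []
        for c in crossings:
            if not candidates or c - candidates[-1] >= refractory:
                candidates.append(int(c))
    if len(candidates) != expected:
        raise SegmentationError(
            f"expected {expected} perturbation onsets, found {len(candidates)}: "
            f"{[int(c) for c in candidates]}"
        )
    return tuple(int(c) for c in candidates)


def _active_end(
    trial: PerturbationTrial, onset: int, bound: int, config: ReactiveConfig
) -> int:
    """Sample index one past the active perturbation phase."""
    if trial.belt_speed is not None:
        moving = trial.belt_speed[onset:bound] > config.belt_threshold
        stopped = np.flatnonzero(~moving)
        # belt may still be below threshold exactly at the onset sample
        stopped = stopped[stopped > 0]
        if stopped.size:
            return onset + int(stopped[0])
        return bound
    return min(onset + int(round(config.active_duration_s * trial.rate)), bound)


def perturbation_features(
    trial: PerturbationTrial,
    onset: int,
    bound: Optional[int] = None,
    config: ReactiveConfig = ReactiveConfig(),
) -> PerturbationFeatures:
    """Extract the five features for one perturbation.

    ``bound`` is the next onset (or trial end).  A pre-onset baseline of
    ``config.baseline_s`` seconds must exist.  All features are baseline
    referenced, hence invariant to a constant AP offset.
    """
    ap = trial.cop_ap
    n = ap.size
    bound = n if bound is None else int(bound)
    if not 0 <= onset < bound <= n:
        raise InvalidSignalError(f"onset {onset} / bound {bound} out of range")
    n_base = int(round(config.baseline_s * trial.rate))
    if onset < n_base:
        raise InvalidSignalError(
            f"need {config.baseline_s} s of pre-onset baseline ({n_base} samples), "
            f"onset at sample {onset}"
        )
    baseline = ap[onset - n_base : onset]
    base_mean = float(baseline.mean())
    band = max(config.band_multiplier * float(baseline.std(ddof=0)), config.band_floor_m)

    active_end = _active_end(trial, onset, bound, config)
    active = ap[onset:active_end]
    range_p = float(active.max() - active.min()) if active.size else 0.0

    response = np.abs(ap[onset:bound] - base_mean)
    peak_idx = int(np.argmax(response))
    peak = float(response[peak_idx])
    ttp = peak_idx / trial.rate

    # recovery: first re-entry into the band that lasts >= dwell_s
    inside = response[active_end - onset :] <= band
    dwell_n = max(int(round(config.dwell_s * trial.rate)), 1)
    rec_rel: Optional[int] = None
    starts = _epoch_starts(inside)
    for s in starts:
        run_end = s
        while run_end < inside.size and inside[run_end]:
            run_end += 1
        if run_end - s >= dwell_n or run_end == inside.size and inside[s:].all():
            rec_rel = int(s)
            break
    if rec_rel is None:
        return PerturbationFeatures(
            range_p=range_p, range_r=None, peak=peak, ttp=ttp, tor=None
        )
    tor = rec_rel / trial.rate
    rec_abs = active_end + rec_rel
    recovery = ap[active_end : rec_abs + 1]
    range_r = float(recovery.max() - recovery.min()) if recovery.size else 0.0
    return PerturbationFeatures(
        range_p=range_p, range_r=range_r, peak=peak, ttp=ttp, tor=tor
    )


def average_perturbations(
    features: Sequence[PerturbationFeatures],
) -> PerturbationFeatures:
    """Element-wise mean over non-missing feature entries.

    ``range_r``/``tor`` entries flagged missing are excluded field-wise; the
    averaged record's ``n`` is the number of contributing perturbations.
    Raises if the list is empty.
    """
    if not features:
        raise InvalidSignalError("no perturbation features to average")

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return PerturbationFeatures(
        range_p=float(np.mean([f.range_p for f in features])),
        range_r=_mean([f.range_r for f in features]),
        peak=float(np.mean([f.peak for f in features])),
        ttp=float(np.mean([f.ttp for f in features])),
        tor=_mean([f.tor for f in features]),
        n=len(features),
    )


def analyze_perturbation_trial(
    trial: PerturbationTrial, config: ReactiveConfig = ReactiveConfig()
) -> tuple[list[PerturbationFeatures], PerturbationFeatures]:
    """Segment a trial and return (per-perturbation features, their average)."""
    onsets = trial.onsets if trial.onsets is not None else detect_onsets(trial, config)
    bounds = list(onsets[1:]) + [trial.cop_ap.size]
    per = [
        perturbation_features(trial, o, b, config) for o, b in zip(onsets, bounds)
    ]
    return per, average_perturbations(per)
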