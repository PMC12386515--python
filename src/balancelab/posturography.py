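"""Static stabilometric metrics from a preprocessed CoP trace.

Five metrics summarize a quiet-standing trial:

* sway path length — total distance travelled by the CoP point,
  ``sum_n sqrt((AP_{n+1}-AP_n)^2 + (ML_{n+1}-ML_n)^2)`` (metres);
* 95% confidence-ellipse area — ``pi * chi2_{2,0.95} * sqrt(lmax * lmin)``
  with ``lmax, lmin`` the eigenvalues of the 2x2 ML/AP displacement
  covariance, reported in mm²;
* mean velocity per axis — mean absolute first derivative of the ML and AP
  displacement (m/s);
* jerk metric — time integral over the window of the squared jerk magnitude
  (third derivative of displacement), units m²/s⁵; lower values indicate
  smoother postural corrections.

On the ellipse: the sqrt convention is the standard one (only
``sqrt(lmax*lmin)`` has units of area).  A literal mode multiplying the raw
eigenvalue product, as some posturography reports print the equation, is
selectable with ``mode="literal"``; it is evaluated on mm-scaled
displacements so its magnitude matches such reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .signals import CoPTrace, InvalidSignalError, SampledSignal, differentiate

__all__ = [
    "StabilometricSummary",
    "chi2_critical",
    "sway_path_length",
    "confidence_ellipse_area",
    "mean_velocity",
    "jerk_metric",
    "summarize_static_trial",
]

#: Column order of the tidy per-trial output.
METRIC_COLUMNS = ("sway_path_length", "area_ce", "vel_ap", "vel_ml", "jerk")

M2_TO_MM2 = 1e6


def chi2_critical(coverage: float = 0.95, df: int = 2) -> float:
    """Chi-squared quantile used in the confidence-ellipse area
    (``chi2_{2,0.95} ~= 5.991``)."""
    if not 0.0 < coverage < 1.0:
        raise InvalidSignalError("coverage must lie in (0, 1)")
    return float(spstats.chi2.ppf(coverage, df))


@dataclass(frozen=True)
class StabilometricSummary:
    """The five static-balance metrics for one trial/condition."""

    condition: str
    sway_path_length: float  # m
    area_ce: float  # mm^2
    vel_ap: float  # m/s
    vel_ml: float  # m/s
    jerk: float  # m^2/s^5

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def _as_signal(trace: CoPTrace) -> SampledSignal:
    return SampledSignal(
        data=np.column_stack([trace.ml, trace.ap]),
        rate=trace.rate,
        channels=("ml", "ap"),
        units=("m", "m"),
    )


def sway_path_length(trace: CoPTrace) -> float:
    """Sum of Euclidean CoP step lengths over the window (metres)."""
    if trace.n_samples < 2:
        raise InvalidSignalError("sway path needs at least 2 samples")
    steps = np.hypot(np.diff(trace.ap), np.diff(trace.ml))
    return float(steps.sum())


def confidence_ellipse_area(
    trace: CoPTrace, coverage: float = 0.95, mode: str = "sqrt"
) -> float:
    """Area of the ellipse covering ``coverage`` of CoP samples (mm²).

    ``mode="sqrt"`` (default): ``pi * chi2 * sqrt(lmax * lmin)`` on the
    metre-scale covariance, converted to mm².  ``mode="literal"``:
    ``pi * chi2 * lmax * lmin`` on mm-scale displacements (the equation as
    sometimes printed, without the square root).  Collinear data give 0.
    """
    if trace.n_samples < 3:
        raise InvalidSignalError("ellipse area needs at least 3 samples")
    if mode not in ("sqrt", "literal"):
        raise InvalidSignalError(f"unknown ellipse mode {mode!r}")
    crit = chi2_critical(coverage)
    if mode == "literal":
        cov = np.cov(trace.ml * 1e3, trace.ap * 1e3)
    else:
        cov = np.cov(trace.ml, trace.ap)
    if not np.all(np.isfinite(cov)):
        raise InvalidSignalError("non-finite displacement covariance")
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)  # tiny negatives from rounding
    if mode == "literal":
        return float(np.pi * crit * lam[0] * lam[1])
    return float(np.pi * crit * np.sqrt(lam[0] * lam[1]) * M2_TO_MM2)


def mean_velocity(trace: CoPTrace, axis: str) -> float:
    """Mean absolute CoP velocity along one axis (m/s).

    The absolute-value convention is used: the signed mean derivative is
    forced to ~0 by offset removal and carries no information.
    """
    axis = axis.lower()
    if axis not in ("ml", "ap"):
        raise InvalidSignalError("axis must be 'ml' or 'ap'")
    vel = differentiate(_as_signal(trace)).channel(axis)
    return float(np.mean(np.abs(vel)))


def jerk_metric(trace: CoPTrace) -> float:
    """Window time-integral of squared jerk magnitude (m²/s⁵).

    Jerk is the third time derivative of displacement; the metric is
    ``integral (jerk_ML^2 + jerk_AP^2) dt`` over the analysis window.
    """
    if trace.n_samples < 5:
        raise InvalidSignalError("jerk metric needs at least 5 samples")
    d = _as_signal(trace)
    for _ in range(3):
        d = differentiate(d)
    sq = d.data[:, 0] ** 2 + d.data[:, 1] ** 2
    return float(np.trapezoid(sq, dx=1.0 / trace.rate))


def summarize_static_trial(
    trace: CoPTrace, coverage: float = 0.95, ellipse_mode: str = "sqrt"
) -> StabilometricSummary:
    """All five metrics on the same window, condition tag carried through."""
    return StabilometricSummary(
        condition=trace.condition,
        sway_path_length=sway_path_length(trace),
        area_ce=confidence_ellipse_area(trace, coverage, ellipse_mode),
        vel_ap=mean_velocity(trace, "ap"),
        vel_ml=mean_velocity(trace, "ml"),
        jerk=jerk_metric(trace),
    )
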