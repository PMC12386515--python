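"""Stride-level gait summaries from treadmill walking trials.

Inputs are sagittal joint-angle curves (ankle, knee, hip; degrees), joint
power curves (W/kg), heel-strike (HS) / toe-off (TO) events per side, and
optional foot AP/ML positions for spatio-temporal parameters.  Events are
consumed as input — on an instrumented treadmill they come from the force
plates — so no event detection is attempted here.

Per-stride quantities (left heel strikes define the reference cycle):

* ROM per joint: max - min of the angle within the stride;
* stride time: ipsilateral HS-to-HS interval; stance: HS to TO; swing: TO to
  next HS;
* step length: AP distance between contralateral foot placements at heel
  strike plus the belt displacement over the step interval (treadmill
  convention); step width: ML distance between placements; walking speed:
  the belt speed;
* peak power per joint: per-stride maximum of the power curve.

Each parameter is summarized by its mean and its standard deviation across
strides; the SD is the gait-pattern variability measure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .signals import InvalidSignalError, SampledSignal, butterworth_lowpass

__all__ = [
    "GaitEvents",
    "GaitTrial",
    "GaitTrialSummary",
    "smooth_gait_curves",
    "rom_per_stride",
    "spatiotemporal",
    "peak_power",
    "summarize_gait_trial",
]

JOINTS = ("ankle", "knee", "hip")


@dataclass(frozen=True)
class GaitEvents:
    """Heel-strike / toe-off sample indices per side.

    Within each side, heel strikes and toe offs must be strictly increasing
    and alternate (each stride contains one toe off).
    """

    left_hs: tuple[int, ...]
    left_to: tuple[int, ...]
    right_hs: tuple[int, ...]
    right_to: tuple[int, ...]

    def __post_init__(self):
        for name in ("left_hs", "left_to", "right_hs", "right_to"):
            seq = tuple(int(i) for i in getattr(self, name))
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise InvalidSignalError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, seq)

    def hs(self, side: str) -> tuple[int, ...]:
        return self.left_hs if side == "left" else self.right_hs

    def to(self, side: str) -> tuple[int, ...]:
        return self.left_to if side == "left" else self.right_to

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, rate: float) -> "GaitEvents":
        """Build from a tidy events table with columns time, side, type
        (type in {HS, TO})."""
        need = {"time", "side", "type"}
        if not need.issubset(frame.columns):
            raise InvalidSignalError(f"events table needs columns {sorted(need)}")
        out = {}
        for side in ("left", "right"):
            for ev, key in (("HS", "hs"), ("TO", "to")):
                sel = frame[(frame["side"].str.lower() == side) & (frame["type"] == ev)]
                out[f"{side}_{key}"] = tuple(
                    int(round(t * rate)) for t in np.sort(sel["time"].to_numpy())
                )
        return cls(**out)


@dataclass(frozen=True)
class GaitTrial:
    """One treadmill walking trial.

    ``angles``/``powers`` map joint name to a curve sampled at ``rate``;
    ``foot_pos`` optionally maps side to an (n, 2) array of (AP, ML) foot
    positions in metres; ``belt_speed`` is the constant treadmill speed.
    """

    angles: dict[str, np.ndarray]
    powers: dict[str, np.ndarray]
    events: GaitEvents
    rate: float
    foot_pos: Optional[dict[str, np.ndarray]] = None
    belt_speed: Optional[float] = None

    def __post_init__(self):
        if self.rate <= 0:
            raise InvalidSignalError("rate must be positive")
        angles = {k: np.asarray(v, dtype=float) for k, v in self.angles.items()}
        powers = {k: np.asarray(v, dtype=float) for k, v in self.powers.items()}
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "powers", powers)
        if len(self.events.left_hs) < 4:
            raise InvalidSignalError("need at least 3 complete strides")
        if self.foot_pos is not None:
            fp = {k: np.asarray(v, dtype=float) for k, v in self.foot_pos.items()}
            object.__setattr__(self, "foot_pos", fp)


@dataclass(frozen=True)
class GaitTrialSummary:
    """Mean and across-stride SD for every gait parameter.

    ``table`` has one row per parameter with columns (parameter, mean, sd,
    n_strides).
    """

    table: pd.DataFrame

    def value(self, parameter: str, stat: str = "mean") -> float:
        row = self.table[self.table["parameter"] == parameter]
        if row.empty:
            raise KeyError(parameter)
        return float(row[stat].iloc[0])


def smooth_gait_curves(trial: GaitTrial, cutoff_hz: float = 6.0, order: int = 2) -> GaitTrial:
    """Low-pass every angle and power curve (2nd-order Butterworth, 6 Hz by
    default, zero-phase)."""

    def _f(curve: np.ndarray) -> np.ndarray:
        sig = SampledSignal(curve, rate=trial.rate, channels=("x",))
        return butterworth_lowpass(sig, order=order, cutoff_hz=cutoff_hz).data[:, 0]

    return replace(
        trial,
        angles={k: _f(v) for k, v in trial.angles.items()},
        powers={k: _f(v) for k, v in trial.powers.items()},
    )


def _stride_slices(hs: tuple[int, ...], n: int) -> list[slice]:
    slices = [
        slice(a, b + 1) for a, b in zip(hs, hs[1:]) if b < n
    ]
    if not slices:
        raise InvalidSignalError("no complete stride inside the recording")
    return slices


def rom_per_stride(angle_curve: np.ndarray, hs: tuple[int, ...]) -> np.ndarray:
    """Range of motion (max - min, degrees) of one joint for each stride."""
    curve = np.asarray(angle_curve, dtype=float)
    return np.array(
        [curve[s].max() - curve[s].min() for s in _stride_slices(hs, curve.size)]
    )


def peak_power(power_curve: np.ndarray, hs: tuple[int, ...]) -> np.ndarray:
    """Per-stride maximum of a joint power curve (W/kg)."""
    curve = np.asarray(power_curve, dtype=float)
    return np.array([curve[s].max() for s in _stride_slices(hs, curve.size)])


def spatiotemporal(trial: GaitTrial, side: str = "left") -> pd.DataFrame:
    """Per-stride spatio-temporal parameters (one row per reference stride).

    Columns: stride_time, stance_time, swing_time, step_length, step_width,
    walking_speed.  Step parameters need foot positions and a belt speed;
    rows where the contralateral event is missing hold NaN.
    """
    ev = trial.events
    hs = ev.hs(side)
    to = ev.to(side)
    other = "right" if side == "left" else "left"
    hs_c = ev.hs(other)
    rate = trial.rate
    rows = []
    for a, b in zip(hs, hs[1:]):
        stride_time = (b - a) / rate
        to_in = [t for t in to if a < t < b]
        stance = (to_in[0] - a) / rate if to_in else np.nan
        swing = stride_time - stance if to_in else np.nan
        # the contralateral heel strike inside this stride defines the step
        c_in = [t for t in hs_c if a < t < b]
        step_len = step_w = np.nan
        if c_in and trial.foot_pos is not None and trial.belt_speed is not None:
            c = c_in[0]
            p_ref = trial.foot_pos[side]
            p_oth = trial.foot_pos[other]
            interval = (c - a) / rate
            step_len = (
                p_oth[c, 0] - p_ref[a, 0] + trial.belt_speed * interval
            )
            step_w = abs(p_oth[c, 1] - p_ref[a, 1])
        rows.append(
            {
                "stride_time": stride_time,
                "stance_time": stance,
                "swing_time": swing,
                "step_length": step_len,
                "step_width": step_w,
                "walking_speed": trial.belt_speed if trial.belt_speed is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_gait_trial(trial: GaitTrial, side: str = "left") -> GaitTrialSummary:
    """Mean and across-stride SD of every gait parameter for one trial."""
    hs = trial.events.hs(side)
    records = []

    def _add(name: str, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            records.append({"parameter": name, "mean": np.nan, "sd": np.nan, "n_strides": 0})
        else:
            records.append(
                {
                    "parameter": name,
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                    "n_strides": int(values.size),
                }
            )

    for joint in JOINTS:
        if joint in trial.angles:
            _add(f"rom_{joint}", rom_per_stride(trial.angles[joint], hs))
    st = spatiotemporal(trial, side)
    for col in st.columns:
        _add(col, st[col].to_numpy())
    for joint in JOINTS:
        if joint in trial.powers:
            _add(f"peak_power_{joint}", peak_power(trial.powers[joint], hs))
    return GaitTrialSummary(table=pd.DataFrame(records))
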