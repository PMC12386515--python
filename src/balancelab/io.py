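"""File formats and run configuration.

Trial recordings travel as plain CSV with a ``time`` column (seconds,
strictly increasing, uniform to 1e-6 relative tolerance) and one column per
channel; units may be annotated in the header as ``name (unit)``.  Cohort
data are a long-format CSV (subject, group, sex, age, timepoint, outcome,
value).  The run configuration is a flat YAML mapping; every results file
embeds the SHA-256 hash of the canonical config that produced it.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reactive import ReactiveConfig
from .signals import InvalidSignalError, SampledSignal

__all__ = [
    "ParseError",
    "RunConfig",
    "read_trial_csv",
    "write_trial_csv",
    "read_cohort_csv",
    "write_cohort_csv",
]


class ParseError(InvalidSignalError):
    """Malformed input file."""


_UNIT_RE = re.compile(r"^\s*(?P<name>[^()]+?)\s*(?:\((?P<unit>[^()]*)\))?\s*$")


@dataclass(frozen=True)
class RunConfig:
    """Validated settings of one study run."""

    cop_rate: float = 1000.0
    com_rate: float = 100.0
    cop_filter_order: int = 4
    cop_cutoff_hz: float = 3.5
    gait_filter_order: int = 2
    gait_cutoff_hz: float = 6.0
    window_s: float = 60.0
    zero_phase: bool = True
    ellipse_mode: str = "sqrt"
    ellipse_coverage: float = 0.95
    reactive: ReactiveConfig = field(default_factory=ReactiveConfig)
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if self.cop_rate <= 0 or self.com_rate <= 0:
            raise InvalidSignalError("sampling rates must be positive")
        for cutoff, rate, label in (
            (self.cop_cutoff_hz, self.cop_rate, "cop"),
            (self.gait_cutoff_hz, self.com_rate, "gait"),
        ):
            if not 0 < cutoff:
                raise InvalidSignalError(f"{label} cutoff must be positive")
        if self.cop_filter_order < 1 or self.gait_filter_order < 1:
            raise InvalidSignalError("filter orders must be >= 1")
        if self.window_s <= 0:
            raise InvalidSignalError("window_s must be positive")
        if self.ellipse_mode not in ("sqrt", "literal"):
            raise InvalidSignalError("ellipse_mode must be 'sqrt' or 'literal'")
        if not 0 < self.ellipse_coverage < 1:
            raise InvalidSignalError("ellipse_coverage must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise InvalidSignalError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "reactive" in d and isinstance(d["reactive"], dict):
            d["reactive"] = ReactiveConfig(**d["reactive"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config {path} must be a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise ParseError(f"config {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON serialization (stable across runs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def read_trial_csv(path) -> SampledSignal:
    """Read one trial recording.

    The first column must be ``time`` in seconds; sampling must be uniform to
    a relative tolerance of 1e-6 on the step.  Channel units are parsed from
    ``name (unit)`` headers.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: need a time column plus at least one channel")
    first = _UNIT_RE.match(str(frame.columns[0]))
    if first is None or first.group("name").strip().lower() != "time":
        raise ParseError(f"{path}: first column must be 'time', got {frame.columns[0]!r}")
    t = frame.iloc[:, 0].to_numpy(float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if (dt <= 0).any():
        bad = int(np.flatnonzero(dt <= 0)[0]) + 2  # 1-based line after header
        raise ParseError(f"{path}: time not strictly increasing at data line {bad}")
    step = float(np.median(dt))
    if np.abs(dt - step).max() > 1e-6 * step:
        bad = int(np.argmax(np.abs(dt - step))) + 2
        raise ParseError(f"{path}: non-uniform sampling near data line {bad}")
    channels, units = [], []
    for col in frame.columns[1:]:
        m = _UNIT_RE.match(str(col))
        channels.append(m.group("name").strip())
        units.append((m.group("unit") or "").strip())
    return SampledSignal(
        data=frame.iloc[:, 1:].to_numpy(float),
        rate=1.0 / step,
        channels=tuple(channels),
        units=tuple(units),
    )


def write_trial_csv(path, sig: SampledSignal) -> None:
    """Write a trial recording in the format :func:`read_trial_csv` accepts."""
    cols = {"time (s)": np.arange(sig.n_samples) / sig.rate}
    for i, (name, unit) in enumerate(zip(sig.channels, sig.units)):
        header = f"{name} ({unit})" if unit else name
        cols[header] = sig.data[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path) -> pd.DataFrame:
    from .stats import validate_cohort

    return validate_cohort(pd.read_csv(path))


def write_cohort_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
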