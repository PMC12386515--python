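"""End-to-end study pipeline: trials -> metrics -> mixed ANCOVA -> tables.

The pipeline consumes a manifest (JSON) listing the cohort and the per-trial
recordings, computes every per-trial metric, assembles the long outcome
table, runs the two-timepoint mixed ANCOVA with age covariate for each
outcome, and writes tidy CSV tables plus a findings summary (significant
time x group interactions with partial eta squared and simple main effects).

Per-trial failures are quarantined and reported, and the pipeline continues:
small clinical datasets routinely lose individual recordings, and the
statistical layer handles per-outcome missingness by listwise deletion.

Manifest schema (paths relative to the manifest's directory)::

    {
      "subjects":        [{"subject", "group", "sex", "age"}, ...],
      "static_trials":   [{"subject", "timepoint", "condition", "path"}, ...],
      "reactive_trials": [{"subject", "timepoint", "path"}, ...],
      "gait_trials":     [{"subject", "timepoint", "path", "events_path"}, ...]
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .gait import GaitEvents, GaitTrial, smooth_gait_curves, summarize_gait_trial
from .io import ParseError, RunConfig, read_trial_csv
from .posturography import summarize_static_trial
from .reactive import PerturbationTrial, analyze_perturbation_trial
from .signals import (
    InvalidSignalError,
    SampledSignal,
    butterworth_lowpass,
    preprocess_static_trial,
    remove_offset,
)
from .stats import StatsError, mixed_ancova, simple_main_effects

__all__ = ["StudyResults", "run_study_pipeline", "preprocess_reactive_record"]


@dataclass
class StudyResults:
    """Outputs of one pipeline run."""

    metrics: pd.DataFrame  # long: subject, timepoint, outcome, value
    anova_table: pd.DataFrame  # one row per outcome x effect
    findings: dict  # significant interactions + simple effects
    quarantined: list = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return 3 if self.quarantined else 0


def preprocess_reactive_record(
    sig: SampledSignal, config: RunConfig
) -> PerturbationTrial:
    """Demean and low-pass the AP CoP of a perturbation trial.

    The whole ~90 s record is kept (no central-window extraction: the
    perturbations span the record); the belt-speed channel, when present, is
    passed through unfiltered.
    """
    ap_sig = SampledSignal(
        sig.channel("ap"), rate=sig.rate, channels=("ap",), units=("m",)
    )
    ap_f = butterworth_lowpass(
        remove_offset(ap_sig),
        order=config.cop_filter_order,
        cutoff_hz=config.cop_cutoff_hz,
        zero_phase=config.zero_phase,
    )
    belt = None
    if "belt_speed" in [c.lower() for c in sig.channels]:
        belt = sig.channel("belt_speed")
    return PerturbationTrial(cop_ap=ap_f.data[:, 0], rate=sig.rate, belt_speed=belt)


def _static_rows(entry: dict, base: Path, config: RunConfig) -> list[dict]:
    sig = read_trial_csv(base / entry["path"])
    trace = preprocess_static_trial(
        sig,
        condition=entry["condition"],
        window_s=config.window_s,
        cutoff_hz=config.cop_cutoff_hz,
        order=config.cop_filter_order,
        zero_phase=config.zero_phase,
    )
    summary = summarize_static_trial(
        trace, coverage=config.ellipse_coverage, ellipse_mode=config.ellipse_mode
    )
    return [
        {
            "subject": entry["subject"],
            "timepoint": entry["timepoint"],
            "outcome": f"{entry['condition']}:{metric}",
            "value": value,
        }
        for metric, value in summary.as_dict().items()
    ]


def _reactive_rows(entry: dict, base: Path, config: RunConfig) -> list[dict]:
    sig = read_trial_csv(base / entry["path"])
    trial = preprocess_reactive_record(sig, config)
    _, avg = analyze_perturbation_trial(trial, config.reactive)
    rows = []
    for name in ("range_p", "range_r", "peak", "ttp", "tor"):
        value = getattr(avg, name)
        if value is None:
            continue  # missing features are recorded by omission, not fabricated
        rows.append(
            {
                "subject": entry["subject"],
                "timepoint": entry["timepoint"],
                "outcome": f"reactive:{name}",
                "value": value,
            }
        )
    return rows


def _gait_rows(entry: dict, base: Path, config: RunConfig) -> list[dict]:
    sig = read_trial_csv(base / entry["path"])
    events = GaitEvents.from_frame(pd.read_csv(base / entry["events_path"]), sig.rate)
    angles = {
        j: sig.channel(f"angle_{j}") for j in ("ankle", "knee", "hip")
        if f"angle_{j}" in [c.lower() for c in sig.channels]
    }
    powers = {
        j: sig.channel(f"power_{j}") for j in ("ankle", "knee", "hip")
        if f"power_{j}" in [c.lower() for c in sig.channels]
    }
    labels = [c.lower() for c in sig.channels]
    foot_pos = None
    if {"left_ap", "left_ml", "right_ap", "right_ml"}.issubset(labels):
        foot_pos = {
            s: np.column_stack([sig.channel(f"{s}_ap"), sig.channel(f"{s}_ml")])
            for s in ("left", "right")
        }
    belt = float(entry["belt_speed"]) if "belt_speed" in entry else None
    trial = GaitTrial(
        angles=angles,
        powers=powers,
        events=events,
        rate=sig.rate,
        foot_pos=foot_pos,
        belt_speed=belt,
    )
    trial = smooth_gait_curves(
        trial, cutoff_hz=config.gait_cutoff_hz, order=config.gait_filter_order
    )
    summary = summarize_gait_trial(trial)
    rows = []
    for _, r in summary.table.iterrows():
        for stat in ("mean", "sd"):
            if np.isfinite(r[stat]):
                rows.append(
                    {
                        "subject": entry["subject"],
                        "timepoint": entry["timepoint"],
                        "outcome": f"gait:{r['parameter']}:{stat}",
                        "value": float(r[stat]),
                    }
                )
    return rows


def run_study_pipeline(
    config: RunConfig,
    manifest: dict | str | Path,
    output_dir: Optional[Path] = None,
) -> StudyResults:
    """Run the full study analysis described by ``manifest``.

    ``manifest`` is a dict or a path to a manifest JSON.  When ``output_dir``
    (or ``config.output_dir``) exists or can be created, tidy CSVs and the
    findings JSON are written there; the function also returns everything
    in memory.
    """
    if not isinstance(manifest, dict):
        mpath = Path(manifest)
        with open(mpath) as fh:
            manifest_data = json.load(fh)
        base = mpath.parent
    else:
        manifest_data = manifest
        base = Path(manifest_data.get("base_dir", "."))
    if not manifest_data.get("subjects"):
        raise ParseError("manifest lists no subjects")

    subjects = pd.DataFrame(manifest_data["subjects"])
    handlers = {
        "static_trials": _static_rows,
        "reactive_trials": _reactive_rows,
        "gait_trials": _gait_rows,
    }
    rows: list[dict] = []
    quarantined: list[dict] = []
    for kind, handler in handlers.items():
        for entry in manifest_data.get(kind, []):
            try:
                rows.extend(handler(entry, base, config))
            except (InvalidSignalError, StatsError, OSError, KeyError) as exc:
                quarantined.append(
                    {"kind": kind, "entry": entry, "error": f"{type(exc).__name__}: {exc}"}
                )
    if not rows:
        raise ParseError("no analyzable trials in manifest")
    metrics = pd.DataFrame(rows).merge(
        subjects[["subject", "group", "sex", "age"]], on="subject", how="left"
    )

    anova_rows: list[dict] = []
    findings: dict = {
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "alpha": config.alpha,
        "significant_interactions": [],
        "quarantined_trials": len(quarantined),
    }
    for outcome in sorted(metrics["outcome"].unique()):
        try:
            result = mixed_ancova(metrics, outcome)
        except StatsError as exc:
            quarantined.append(
                {"kind": "ancova", "entry": {"outcome": outcome}, "error": str(exc)}
            )
            continue
        for effect_name, eff in result.effects.items():
            anova_rows.append(
                {
                    "outcome": outcome,
                    "effect": effect_name,
                    "F": eff.F,
                    "df1": eff.df1,
                    "df2": eff.df2,
                    "p": eff.p,
                    "partial_eta_sq": eff.partial_eta_sq,
                }
            )
        inter = result.interaction
        if inter.p < config.alpha:
            simples = simple_main_effects(result)
            findings["significant_interactions"].append(
                {
                    "outcome": outcome,
                    "F": inter.F,
                    "df": [inter.df1, inter.df2],
                    "p": inter.p,
                    "partial_eta_sq": inter.partial_eta_sq,
                    "simple_effects": [
                        {
                            "group": s.group,
                            "change": s.estimate,
                            "p": s.p,
                            "partial_eta_sq": s.partial_eta_sq,
                        }
                        for s in simples
                    ],
                }
            )
    anova_table = pd.DataFrame(anova_rows)

    outdir = Path(output_dir) if output_dir is not None else Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(outdir / "metrics_long.csv", index=False, float_format="%.12g")
    anova_table.to_csv(outdir / "ancova_results.csv", index=False, float_format="%.12g")
    with open(outdir / "findings.json", "w") as fh:
        json.dump(findings, fh, indent=2)
    with open(outdir / "quarantine.json", "w") as fh:
        json.dump(quarantined, fh, indent=2, default=str)
    config.to_yaml(outdir / "config_used.yaml")

    return StudyResults(
        metrics=metrics,
        anova_table=anova_table,
        findings=findings,
        quarantined=quarantined,
    )
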