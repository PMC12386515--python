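"""Synthetic-data generators with stored ground truth.

Every generator emulates one input class of the balance-analysis pipeline and
emits the parameters it used, so downstream recovery can be tested against
ground truth:

* quiet-stance CoP sway — two independent Ornstein-Uhlenbeck (OU) paths
  (ML, AP) by exact discretization.  The OU process is the simplest
  stationary process with tunable bandwidth; with timescale ``tau`` and
  diffusion ``D`` the stationary SD is ``sqrt(D * tau / 2)`` and the power
  rolls off above ``1 / (2 pi tau)`` Hz, well below the pipeline's 3.5 Hz
  cutoff for the defaults used;
* perturbation trials — baseline OU noise plus, at each onset, a linear rise
  to a set amplitude followed by exponential return, with a matching
  trapezoidal belt-speed pulse (6 m/s² to 0.4 m/s);
* gait trials — per-stride raised-cosine angle cycles with per-stride
  amplitude drawn around the target ROM, half-sine power bursts with known
  peaks, events at cycle boundaries with optional timing jitter;
* cohorts — bivariate-normal (T0, T1) outcomes per subject with test-retest
  correlation rho, additive group/time/interaction effects (standardized, in
  units of the baseline SD), and an age covariate with a linear slope.

All randomness flows through one ``numpy.random.Generator`` derived from the
seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .reactive import PerturbationTrial
from .gait import GaitEvents, GaitTrial
from .signals import InvalidSignalError, SampledSignal

__all__ = [
    "SwayModelParams",
    "PerturbationModelParams",
    "GaitModelParams",
    "CohortModelParams",
    "generate_cop_trace",
    "generate_perturbation_trial",
    "generate_gait_trial",
    "generate_cohort",
    "cohort_arrays",
    "StudyModelParams",
    "write_synthetic_study",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _ou_path(n: int, dt: float, tau: float, stat_sd: float, rng) -> np.ndarray:
    """Exact OU discretization: x[k+1] = phi x[k] + stat_sd sqrt(1-phi²) z."""
    from scipy.signal import lfilter

    phi = np.exp(-dt / tau)
    innov_sd = stat_sd * np.sqrt(1.0 - phi * phi)
    e = np.empty(n)
    e[0] = stat_sd * rng.standard_normal()  # stationary start
    e[1:] = rng.standard_normal(n - 1) * innov_sd
    return lfilter([1.0], [1.0, -phi], e)


# ---------------------------------------------------------------- quiet stance

@dataclass(frozen=True)
class SwayModelParams:
    """OU sway model: ``ou_timescale`` (s), ``diffusion`` (m²/s), ``rate``
    (Hz), ``duration`` (s).  Stationary SD = sqrt(diffusion * timescale / 2);
    defaults give ~5 mm sway with energy below ~0.5 Hz at force-plate rate."""

    ou_timescale: float = 0.4
    diffusion: float = 1.25e-4
    rate: float = 1000.0
    duration: float = 90.0
    offset_ml: float = 0.0
    offset_ap: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.ou_timescale <= 0 or self.diffusion < 0:
            raise InvalidSignalError("timescale must be > 0 and diffusion >= 0")
        if self.rate <= 0 or self.duration <= 0:
            raise InvalidSignalError("rate and duration must be positive")

    @property
    def stationary_sd(self) -> float:
        return float(np.sqrt(self.diffusion * self.ou_timescale / 2.0))


def generate_cop_trace(params: SwayModelParams) -> SampledSignal:
    """Raw two-channel (ml, ap) CoP displacement record in metres."""
    rng = _rng(params.seed)
    n = int(round(params.duration * params.rate))
    dt = 1.0 / params.rate
    sd = params.stationary_sd
    if sd == 0.0:
        ml = np.zeros(n)
        ap = np.zeros(n)
    else:
        ml = _ou_path(n, dt, params.ou_timescale, sd, rng)
        ap = _ou_path(n, dt, params.ou_timescale, sd, rng)
    data = np.column_stack([ml + params.offset_ml, ap + params.offset_ap])
    return SampledSignal(data, rate=params.rate, channels=("ml", "ap"), units=("m", "m"))


# --------------------------------------------------------------- perturbations

@dataclass(frozen=True)
class PerturbationModelParams:
    """Perturb-and-recover model: linear rise to ``amplitude`` (m) over
    ``rise_time`` (s), exponential return with time constant ``tau`` (s),
    additive OU baseline noise of SD ``noise_sd`` (m); belt accelerates at
    ``belt_accel`` to ``belt_speed`` and the belt pulse lasts
    ``active_duration``."""

    amplitude: float = 0.03
    tau: float = 1.0
    noise_sd: float = 0.002
    onsets_s: tuple[float, ...] = (15.0, 45.0, 75.0)
    rise_time: float = 0.5
    rate: float = 1000.0
    duration: float = 90.0
    belt_speed: float = 0.4
    belt_accel: float = 6.0
    active_duration: float = 1.5
    seed: int = 0


def generate_perturbation_trial(
    params: PerturbationModelParams,
) -> tuple[PerturbationTrial, dict]:
    """Perturbation trial plus its ground truth.

    Returns ``(trial, truth)`` where ``truth`` records the onset indices,
    injected amplitude, tau and rise time.
    """
    rng = _rng(params.seed)
    n = int(round(params.duration * params.rate))
    t = np.arange(n) / params.rate
    if params.noise_sd > 0:
        ap = _ou_path(n, 1.0 / params.rate, 0.5, params.noise_sd, rng)
    else:
        ap = np.zeros(n)
    belt = np.zeros(n)
    ramp = params.belt_speed / params.belt_accel
    onset_idx = []
    for t0 in params.onsets_s:
        i0 = int(round(t0 * params.rate))
        onset_idx.append(i0)
        # CoP response: linear rise then exponential return
        rel = t - t0
        rise = (rel >= 0) & (rel < params.rise_time)
        decay = rel >= params.rise_time
        ap[rise] += params.amplitude * rel[rise] / params.rise_time
        ap[decay] += params.amplitude * np.exp(
            -(rel[decay] - params.rise_time) / params.tau
        )
        # trapezoidal belt pulse
        up = (rel >= 0) & (rel < ramp)
        plateau = (rel >= ramp) & (rel < params.active_duration - ramp)
        down = (rel >= params.active_duration - ramp) & (rel < params.active_duration)
        belt[up] = params.belt_accel * rel[up]
        belt[plateau] = params.belt_speed
        belt[down] = params.belt_speed - params.belt_accel * (
            rel[down] - (params.active_duration - ramp)
        )
    trial = PerturbationTrial(
        cop_ap=ap,
        rate=params.rate,
        belt_speed=belt,
        onsets=tuple(onset_idx),
        expected_perturbations=len(onset_idx),
    )
    truth = {
        "onsets": tuple(onset_idx),
        "amplitude": params.amplitude,
        "tau": params.tau,
        "rise_time": params.rise_time,
        "active_duration": params.active_duration,
    }
    return trial, truth


# ------------------------------------------------------------------------ gait

@dataclass(frozen=True)
class GaitModelParams:
    """Quasi-periodic synthetic walker.

    Each stride lasts ``stride_time`` s (plus Gaussian jitter of SD
    ``stride_jitter``); joint angles follow a raised-cosine cycle whose
    per-stride amplitude (= ROM) is drawn as N(rom_mean, rom_sd); joint
    powers are half-sine push-off bursts of known height.  Defaults are a
    comfortable child treadmill walk."""

    n_strides: int = 50
    stride_time: float = 1.0
    stride_jitter: float = 0.0
    stance_fraction: float = 0.6
    rom_means: dict = field(
        default_factory=lambda: {"ankle": 25.0, "knee": 60.0, "hip": 45.0}
    )
    rom_sd: float = 1.5
    power_peaks: dict = field(
        default_factory=lambda: {"ankle": 3.5, "knee": 1.0, "hip": 1.0}
    )
    belt_speed: float = 1.0
    step_width: float = 0.12
    placement_noise: float = 0.0  # per-sample foot-position noise SD (m)
    rate: float = 100.0
    seed: int = 0


def generate_gait_trial(params: GaitModelParams) -> tuple[GaitTrial, dict]:
    """Gait trial plus ground truth (per-stride durations, ROMs, peaks)."""
    rng = _rng(params.seed)
    rate = params.rate
    durations = params.stride_time + params.stride_jitter * rng.standard_normal(
        params.n_strides
    )
    durations = np.clip(durations, 0.3 * params.stride_time, None)
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    n = int(round(boundaries[-1] * rate)) + 1
    t = np.arange(n) / rate

    roms = {
        j: rng.normal(params.rom_means[j], params.rom_sd, params.n_strides)
        for j in params.rom_means
    }
    peaks = {
        j: np.full(params.n_strides, params.power_peaks[j]) for j in params.power_peaks
    }

    angles = {j: np.zeros(n) for j in params.rom_means}
    powers = {j: np.zeros(n) for j in params.power_peaks}
    left_hs, left_to, right_hs, right_to = [], [], [], []
    for i in range(params.n_strides):
        a, b = boundaries[i], boundaries[i + 1]
        ia, ib = int(round(a * rate)), min(int(round(b * rate)), n - 1)
        left_hs.append(ia)
        left_to.append(ia + int(round((ib - ia) * params.stance_fraction)))
        right_hs.append(ia + int(round((ib - ia) * 0.5)))
        right_to.append(ia + int(round((ib - ia) * min(params.stance_fraction + 0.5, 0.99))))
        seg = slice(ia, ib + 1)
        phase = (t[seg] - a) / (b - a)
        for j in angles:
            # raised cosine: min at heel strike, ROM = amplitude
            angles[j][seg] = roms[j][i] * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        burst = (phase > 0.45) & (phase < 0.6)
        for j in powers:
            powers[j][seg][burst] = peaks[j][i] * np.sin(
                np.pi * (phase[burst] - 0.45) / 0.15
            )
    left_hs.append(n - 1)  # closing heel strike of the last stride

    pn = params.placement_noise
    foot_pos = {
        "left": np.column_stack(
            [
                pn * rng.standard_normal(n),
                params.step_width / 2.0 + pn * rng.standard_normal(n),
            ]
        ),
        "right": np.column_stack(
            [
                pn * rng.standard_normal(n),
                -params.step_width / 2.0 + pn * rng.standard_normal(n),
            ]
        ),
    }
    trial = GaitTrial(
        angles=angles,
        powers=powers,
        events=GaitEvents(
            left_hs=tuple(left_hs),
            left_to=tuple(left_to),
            right_hs=tuple(right_hs),
            right_to=tuple(right_to),
        ),
        rate=rate,
        foot_pos=foot_pos,
        belt_speed=params.belt_speed,
    )
    truth = {
        "stride_durations": durations,
        "roms": roms,
        "power_peaks": peaks,
        "step_width": params.step_width,
        "belt_speed": params.belt_speed,
    }
    return trial, truth


# ---------------------------------------------------------------------- cohort

@dataclass(frozen=True)
class CohortModelParams:
    """Two-group, two-timepoint cohort with an age covariate.

    ``group_effect``, ``time_effect`` and ``interaction_effect`` are
    standardized (units of ``baseline_sd``); the interaction is the extra T1
    change in the training group.  ``retest_rho`` is the T0-T1 correlation.
    Defaults mirror a small pediatric balance trial: 10 subjects per group,
    training group ~9.1 y (SD 1.9), control ~10.8 y (SD 1.7), mostly male.
    """

    n_per_group: int = 10
    baseline_mean: float = 1.0
    baseline_sd: float = 0.4
    retest_rho: float = 0.8
    group_effect: float = 0.0
    time_effect: float = 0.0
    interaction_effect: float = 0.0
    age_mean_training: float = 9.1
    age_mean_control: float = 10.8
    age_sd_training: float = 1.9
    age_sd_control: float = 1.7
    age_slope: float = 0.0
    male_fraction: float = 0.85
    outcome: str = "outcome"
    seed: int = 0

    def __post_init__(self):
        if not -1.0 < self.retest_rho < 1.0:
            raise InvalidSignalError("retest_rho must lie in (-1, 1)")
        if self.baseline_sd < 0 or self.n_per_group < 2:
            raise InvalidSignalError("baseline_sd >= 0 and n_per_group >= 2 required")


def cohort_arrays(params: CohortModelParams, rng=None):
    """Simulate (t0, t1, group, age) arrays for one cohort replicate.

    Fast path used by Monte-Carlo studies; :func:`generate_cohort` wraps it
    into the long cohort table.
    """
    rng = _rng(params.seed if rng is None else rng)
    n = params.n_per_group
    sd = params.baseline_sd
    rho = params.retest_rho
    # bivariate normal via Cholesky of [[1, rho], [rho, 1]]
    z0 = rng.standard_normal(2 * n)
    z1 = rho * z0 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(2 * n)
    group = np.array(["training"] * n + ["control"] * n)
    is_tr = group == "training"
    age = np.where(
        is_tr,
        rng.normal(params.age_mean_training, params.age_sd_training, 2 * n),
        rng.normal(params.age_mean_control, params.age_sd_control, 2 * n),
    )
    base = params.baseline_mean + params.age_slope * (age - 10.0)
    t0 = base + sd * z0 + sd * params.group_effect * is_tr
    t1 = (
        base
        + sd * z1
        + sd * params.group_effect * is_tr
        + sd * params.time_effect
        + sd * params.interaction_effect * is_tr
    )
    return t0, t1, group, age


def generate_cohort(params: CohortModelParams) -> pd.DataFrame:
    """Long-format cohort table (subject, group, sex, age, timepoint,
    outcome, value) with injected effects; ground truth is ``params``."""
    rng = _rng(params.seed)
    t0, t1, group, age = cohort_arrays(params, rng)
    n = t0.size
    sex = np.where(rng.random(n) < params.male_fraction, "M", "F")
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    rows = []
    for tp, vals in (("T0", t0), ("T1", t1)):
        for i in range(n):
            rows.append(
                {
                    "subject": subjects[i],
                    "group": group[i],
                    "sex": sex[i],
                    "age": age[i],
                    "timepoint": tp,
                    "outcome": params.outcome,
                    "value": vals[i],
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- full study

@dataclass(frozen=True)
class StudyModelParams:
    """Conditions of a full synthetic pre/post balance study.

    Per subject and timepoint the study writes four quiet-stance trials
    (eyes open/closed x wide/narrowed feet, with sway scaled up for the
    harder conditions), one three-perturbation reactive trial, and one gait
    trial.  ``sway_reduction_t1_training`` injects the time x group
    interaction: the training group's sway SD (and perturbation amplitude)
    shrinks by that fraction at T1.  The default acquisition scale (100 Hz,
    70-s static records analyzed over a 60-s window) keeps a whole study
    writable in seconds while preserving every structural feature the
    pipeline consumes.
    """

    n_per_group: int = 10
    rate: float = 100.0
    static_duration: float = 70.0
    sway_sd: float = 0.005
    sway_subject_cv: float = 0.25
    condition_scale: tuple = (("EOWF", 1.0), ("ECWF", 1.15), ("EONF", 1.35), ("ECNF", 1.55))
    sway_reduction_t1_training: float = 0.15
    perturb_amplitude: float = 0.03
    perturb_tau: float = 1.0
    perturb_noise_sd: float = 0.002
    n_strides: int = 50
    stride_jitter: float = 0.02
    rom_sd: float = 1.5
    age_slope: float = 0.0
    seed: int = 0


def write_synthetic_study(outdir, params: StudyModelParams = StudyModelParams()) -> dict:
    """Write a complete synthetic study (trial CSVs + manifest JSON).

    Returns the manifest dict; ``manifest["ground_truth"]`` records the
    generating parameters.  Files go under ``outdir`` with one CSV per trial.
    """
    import json
    from pathlib import Path

    from .io import write_trial_csv
    from .signals import SampledSignal as _Sig

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(params.seed)
    n = params.n_per_group
    subjects = []
    for i in range(2 * n):
        group = "training" if i < n else "control"
        age = rng.normal(9.1, 1.9) if group == "training" else rng.normal(10.8, 1.7)
        subjects.append(
            {
                "subject": f"S{i + 1:03d}",
                "group": group,
                "sex": "M" if rng.random() < 0.85 else "F",
                "age": round(float(age), 2),
            }
        )

    static_trials, reactive_trials, gait_trials = [], [], []
    for subj in subjects:
        subj_scale = float(
            np.exp(rng.normal(0.0, params.sway_subject_cv))
        )  # lognormal between-subject sway size
        for tp in ("T0", "T1"):
            shrink = (
                1.0 - params.sway_reduction_t1_training
                if (tp == "T1" and subj["group"] == "training")
                else 1.0
            )
            for cond, scale in params.condition_scale:
                sd = params.sway_sd * subj_scale * scale * shrink
                sway = SwayModelParams(
                    diffusion=2.0 * sd**2 / 0.4,
                    ou_timescale=0.4,
                    rate=params.rate,
                    duration=params.static_duration,
                    offset_ml=float(rng.normal(0, 0.05)),
                    offset_ap=float(rng.normal(0, 0.05)),
                    seed=rng,
                )
                sig = generate_cop_trace(sway)
                path = f"static_{subj['subject']}_{tp}_{cond}.csv"
                write_trial_csv(outdir / path, sig)
                static_trials.append(
                    {"subject": subj["subject"], "timepoint": tp, "condition": cond, "path": path}
                )
            pt, _ = generate_perturbation_trial(
                PerturbationModelParams(
                    amplitude=params.perturb_amplitude * subj_scale * shrink,
                    tau=params.perturb_tau,
                    noise_sd=params.perturb_noise_sd,
                    rate=params.rate,
                    seed=rng,
                )
            )
            sig = _Sig(
                np.column_stack([pt.cop_ap, pt.belt_speed]),
                rate=params.rate,
                channels=("ap", "belt_speed"),
                units=("m", "m/s"),
            )
            path = f"reactive_{subj['subject']}_{tp}.csv"
            write_trial_csv(outdir / path, sig)
            reactive_trials.append({"subject": subj["subject"], "timepoint": tp, "path": path})

            gt, _ = generate_gait_trial(
                GaitModelParams(
                    n_strides=params.n_strides,
                    stride_jitter=params.stride_jitter,
                    rom_sd=params.rom_sd,
                    placement_noise=0.005,
                    rate=params.rate,
                    seed=rng,
                )
            )
            nsamp = next(iter(gt.angles.values())).size
            cols = [gt.angles[j] for j in ("ankle", "knee", "hip")] + [
                gt.powers[j] for j in ("ankle", "knee", "hip")
            ] + [
                gt.foot_pos["left"][:, 0],
                gt.foot_pos["left"][:, 1],
                gt.foot_pos["right"][:, 0],
                gt.foot_pos["right"][:, 1],
            ]
            names = (
                "angle_ankle", "angle_knee", "angle_hip",
                "power_ankle", "power_knee", "power_hip",
                "left_ap", "left_ml", "right_ap", "right_ml",
            )
            units = ("deg",) * 3 + ("W/kg",) * 3 + ("m",) * 4
            sig = _Sig(np.column_stack(cols), rate=params.rate, channels=names, units=units)
            path = f"gait_{subj['subject']}_{tp}.csv"
            write_trial_csv(outdir / path, sig)
            ev_rows = []
            for side in ("left", "right"):
                for kind, idxs in (("HS", gt.events.hs(side)), ("TO", gt.events.to(side))):
                    for i in idxs:
                        ev_rows.append({"time": i / params.rate, "side": side, "type": kind})
            ev_path = f"gait_{subj['subject']}_{tp}_events.csv"
            pd.DataFrame(ev_rows).sort_values("time").to_csv(outdir / ev_path, index=False)
            gait_trials.append(
                {
                    "subject": subj["subject"],
                    "timepoint": tp,
                    "path": path,
                    "events_path": ev_path,
                    "belt_speed": 1.0,
                }
            )

    manifest = {
        "subjects": subjects,
        "static_trials": static_trials,
        "reactive_trials": reactive_trials,
        "gait_trials": gait_trials,
        "ground_truth": {
            "seed": params.seed,
            "sway_sd": params.sway_sd,
            "sway_reduction_t1_training": params.sway_reduction_t1_training,
            "perturb_amplitude": params.perturb_amplitude,
            "rom_sd": params.rom_sd,
            "stride_jitter": params.stride_jitter,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
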