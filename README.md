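# balancelab

Quantitative balance analysis for small pre/post clinical trials on an
instrumented treadmill: center-of-pressure (CoP) stabilometry, reactive
perturbation-recovery features, stride-level gait variability, and the
two-timepoint mixed-ANCOVA layer that ties per-trial metrics to a
group × time study design.

The package is aimed at movement-analysis labs running balance-training
interventions (here the motivating setting is postural training for autistic
children): per-trial force-plate or accelerometer recordings go in, tidy
metric tables and effect-size statistics come out, and a synthetic-data
module generates every input class with stored ground truth so the whole
pipeline is testable end to end without patient data.

## What it computes

**Static stabilometry.** A quiet-stance trial is preprocessed by removing
each channel's own mean (the subject's standing offset), filtering with a
4th-order low-pass Butterworth at 3.5 Hz (zero-phase by default), and
retaining the central 60-s window. Five metrics are computed on the
preprocessed ML/AP displacement (x = ML, y = AP, N samples):

- sway path length: `L = Σ_n √((AP_{n+1} − AP_n)² + (ML_{n+1} − ML_n)²)` (m)
- 95% confidence-ellipse area: `A = π · χ²_{2,0.95} · √(λ_max λ_min)` (mm²),
  with λ the eigenvalues of the 2×2 displacement covariance and
  χ²_{2,0.95} ≈ 5.991
- mean velocity per axis: `mean |d(ML)/dt|`, `mean |d(AP)/dt|` (m/s)
- jerk metric: `∫ (⃛x² + ⃛y²) dt` over the window (m²/s⁵), the time
  integral of squared third-derivative magnitude

**Reactive balance.** Treadmill-belt perturbation trials (three pulses at
6 m/s² up to 0.4 m/s) yield, per perturbation and averaged: AP CoP range
during the active phase (Range_p) and the recovery phase (Range_r), peak
baseline-referenced excursion, time to peak (TTP), and time of recovery
(TOR, re-entry into the baseline mean ± 2 SD band with a 1-s dwell).

**Gait.** Per-stride range of motion of ankle/knee/hip, stride, stance and
swing times, step length/width, walking speed and peak joint power, each
summarized by its mean and by its SD across strides (the gait-variability
measure).

**Statistics.** For each outcome, a two-timepoint mixed ANCOVA with time as
within-subject factor, group as between-subject factor and age as covariate,
reported as F, df, p and partial η² = SS_effect/(SS_effect + SS_error) per
effect, with per-group simple main effects after significant interactions.
Baseline comparability helpers reconstruct a one-way ANOVA from per-group
(n, mean, SD) and the uncorrected 2×2 Pearson χ².

## Worked example

```python
from balancelab import *
from balancelab.synth import SwayModelParams, generate_cop_trace

raw = generate_cop_trace(SwayModelParams(rate=100.0, duration=90.0, seed=42,
                                         offset_ml=0.31, offset_ap=-0.12))
trace = preprocess_static_trial(raw, condition="EOWF")
s = summarize_static_trial(trace)
print(f"sway_path_length = {s.sway_path_length:.4f} m")
print(f"area_ce          = {s.area_ce:.2f} mm^2")
print(f"vel_ap           = {s.vel_ap:.5f} m/s")
```

prints

```
sway_path_length = 1.9094 m
area_ce          = 496.86 mm^2
vel_ap           = 0.02067 m/s
```

— the simulated subject's CoP travelled 1.91 m over the 60-s window, 95% of
its excursion fits an ellipse of ~497 mm², and its mean antero-posterior
speed was ~2.1 cm/s. The 0.31/−0.12 m standing offset is removed by the
pipeline and does not affect any metric.

The statistical layer on a synthetic cohort with an injected training
benefit (10 subjects/group, test–retest ρ = 0.9):

```python
from balancelab.synth import CohortModelParams, generate_cohort
tab = generate_cohort(CohortModelParams(interaction_effect=-0.9,
                                        retest_rho=0.9, seed=3))
res = mixed_ancova(tab, "outcome")
```

```
time           F(1,17) =  12.478  p = 0.0026  eta_p^2 = 0.423
time_x_group   F(1,17) =   4.635  p = 0.0460  eta_p^2 = 0.214
simple[training]: change = -0.272, p = 0.0009, eta_p^2 = 0.485
simple[control]:  change = -0.060, p = 0.3868, eta_p^2 = 0.044
```

— a significant time × group interaction driven by the training group's
decrease, exactly the pattern the injected effect encodes.

A command-line interface mirrors the library
(`balancelab preprocess|static|reactive|gait|stats|synth|run`); `synth`
writes a complete synthetic study (trial CSVs plus a ground-truth manifest)
and `run` executes the full pipeline from a manifest.

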