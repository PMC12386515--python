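# Methods

This note records the models, conventions and numerical choices behind
balancelab, and what the synthetic-data generators do and do not emulate.

## Signal preprocessing

Static trials are processed in acquisition order: per-channel mean removal
(the offset is the subject's standing position and carries no postural
information), low-pass filtering, then extraction of the central analysis
window. Defaults: 4th-order Butterworth, 3.5 Hz cutoff, 60-s window. The
trunk-accelerometer (CoM) pathway reuses the same pipeline on acceleration
channels; no double integration is applied — CoM metrics are computed on the
preprocessed acceleration trace as recorded.

**Zero-phase filtering.** The filter is applied forward and backward
(`scipy.signal.filtfilt`, default odd-reflection padding of
`3·(max(len(a), len(b)) − 1)` samples). Zero phase is the default because
phase distortion would bias derivative-based metrics, above all the jerk
metric (a third derivative); the effective magnitude response is the square
of the designed 4th-order response, i.e. steeper than nominal. A causal
single-pass mode is available (`zero_phase=False`) for parity with real-time
processing chains.

**Window centering.** "Central" means start index `floor((L − W)/2)` with
`W = round(duration · rate)`. Filtering precedes windowing, so filter edge
transients fall outside the retained segment by construction. Because a
centrally windowed segment of a globally demeaned record is not itself
exactly zero-mean, the retained window is demeaned once more; no metric
except the mean is affected (covariances and derivatives are
translation-invariant), and the preprocessing as a whole is exactly
translation-invariant.

**Derivatives.** Central finite differences at the native rate
(`numpy.gradient`, one-sided at the endpoints), exact for linear signals.
For the band-limited signals the pipeline produces (≤ 3.5 Hz at ≥ 100 Hz
sampling) the truncation error of one application is below
`(2πf)³/(6·rate²)` in amplitude; three applications (jerk) keep the relative
error of the squared-jerk integral under ~1% at 100 samples per cycle.

## Stabilometric metrics

Five per-trial metrics: sway path length (sum of Euclidean CoP steps),
95% confidence-ellipse area, per-axis mean absolute velocity, and the jerk
metric. Conventions that were genuinely open:

- **Ellipse area.** The default is `π · χ²_{2,0.95} · √(λmax·λmin)` — the
  standard bivariate-normal 95% coverage ellipse, and the only convention
  with units of area. Some posturography reports print the same equation
  without the square root; that literal form is available as
  `mode="literal"` and is evaluated on mm-scaled displacements so its
  magnitude matches such reports. Both modes share
  χ²_{2,0.95} = 5.991 (scipy quantile, not a hard-coded constant).
- **Jerk metric.** Operationalized as the window time-integral of squared
  jerk magnitude, `∫(⃛x² + ⃛y²)dt`. This is the reading consistent with the
  conventional m²/s⁵ unit ((m/s³)²·s) and it reproduces the right order of
  magnitude (10⁵–10⁶ m²/s⁵) for centimetre-scale sway band-limited at
  3.5 Hz sampled at force-plate rates.
- **Mean velocity.** Mean absolute first derivative per axis; the signed
  mean is forced to ≈ 0 by offset removal and carries no information.
- **Units.** All displacement processing is in metres; the ellipse area
  alone is reported in mm² (one ×10⁶ conversion at reporting time).

Scaling identities used as test invariants: path and velocities are
1-homogeneous in amplitude, area and jerk 2-homogeneous; path, area and jerk
are rotation-invariant in the (ML, AP) plane; path/duration equals the mean
resultant speed.

## Reactive balance

Perturbation trials contain three belt pulses (6 m/s² to 0.4 m/s). Only the
AP CoP component is analyzed (the perturbation is sagittal). Operational
definitions, configurable in `ReactiveConfig`:

- **Onsets**: first sample of each contiguous belt-speed epoch above
  0.01 m/s; without a belt channel, upward crossings of |d(AP)/dt| above a
  threshold (default 0.05 m/s) after a 0.1-s centered moving average,
  separated by a 5-s refractory period. The smoothing suppresses
  sample-scale derivative noise without shifting the crossing.
- **Active phase**: onset until the belt speed falls back below threshold;
  CoP-only fallback is a fixed 1.5 s (time to reach 0.4 m/s at 6 m/s² plus a
  plateau estimate).
- **Peak / TTP**: peak absolute baseline-referenced AP excursion over the
  whole response, and the time from onset to it. Baseline is the 2 s before
  onset. (Excursion rather than absolute position: the sign depends on belt
  direction and the magnitude scale of interest is centimetres of
  displacement from quiet stance.)
- **Recovery / TOR / Range_r**: recovery is re-entry into the band
  baseline-mean ± max(2·SD_baseline, 1 mm) with a dwell of ≥ 1 s; TOR is
  measured from the end of the active phase; Range_r is the AP max − min
  over the recovery phase. The 1-mm absolute floor prevents a degenerate
  band on very quiet baselines. If no recovery occurs before the next
  perturbation, TOR and Range_r are recorded as missing, never extrapolated.
- Features are averaged across the three perturbations field-wise over
  non-missing entries, with the contributing count retained.

TTP under these definitions is sub-second for a mechanically driven peak;
published tables for this protocol sometimes show TTP/TOR of ~9–14 s, which
cannot arise from the above reading. The package keeps the operational
definitions and flags the discrepancy rather than reverse-engineering an
unstated convention; no acceptance check targets those values.

## Gait

Events (heel strike, toe off, per side) are consumed as input — on an
instrumented treadmill they come from the force plates; event detection from
raw signals is deliberately out of scope. Left heel strikes define the
reference cycle. Per-stride ROM is max − min of the sagittal joint angle
within the stride; stride time is HS-to-HS, stance HS→TO, swing the
remainder. Step length is the AP distance between contralateral foot
placements at heel strike plus belt displacement over the step interval
(treadmill frame correction); step width the ML distance; walking speed the
belt speed. Curves are smoothed with a 2nd-order, 6-Hz Butterworth (the
real-time convention for marker-derived curves). Every parameter is
summarized by its mean and its SD across strides within the trial; the SD is
the gait-variability measure (variability across trials is a different
quantity and is not computed here).

## Statistical layer

With exactly two timepoints the mixed-design ANCOVA decomposes exactly into
two OLS strata, which is how it is computed (plain normal equations, no
iterative fitting):

- between-subjects: subject means `(Y0+Y1)/2 ~ 1 + group + age_c` → group
  and covariate tests;
- within-subjects: difference scores `Y1−Y0 ~ 1 + group + age_c` → the
  intercept is the time effect, the group coefficient the time × group
  interaction, the covariate coefficient the time × age term.

Group is effect-coded (first label in sorted order = +1) and age is centered
on the analyzed subjects, so each single-df F (the squared coefficient
t statistic) is the Type III test — appropriate for the unbalanced group
sizes that arise from per-outcome missingness. Analysis is listwise per
outcome (subjects need both timepoints). The covariate enters both strata by
default, matching the mainstream repeated-measures ANCOVA convention; a
`within_covariate=False` flag restricts it to the between stratum. Partial
η² is SS_effect/(SS_effect + SS_error) within the effect's stratum.

Simple main effects are the per-group fitted mean change at the covariate
mean (`b0 ± b_group`), tested against the within-stratum error with F = t².
No multiplicity correction is applied anywhere: the comparisons are planned,
and the package reports raw p values with effect sizes.

Degenerate designs raise: fewer than two complete subjects in a group,
singular design, or zero error variance (e.g. a constant outcome such as a
fixed belt speed — the pipeline quarantines such outcomes and continues).

Identities verified in tests: without the covariate the interaction F equals
the squared two-sample t on difference scores; with an outcome-independent
covariate the interaction F distribution matches the no-covariate case;
group-label permutation on null data yields uniform interaction p values;
the null type-I error at n = 10/group is ≈ 0.05 over 10,000 simulated
cohorts.

**Design power.** `interaction_power` treats the interaction test as a
two-sample t on difference scores: a standardized between-group change
difference d operates at d/√(2(1−ρ)) on the difference-score scale, where ρ
is the test–retest correlation. A pre/post design with 10 subjects per group
reaches 80% power at d = 0.7 only under high outcome reliability;
`implied_retest_correlation` solves for the implied ρ (≈ 0.86 at α = 0.05).
The package reports this assumption set rather than asserting any particular
sample-size calculation.

## Synthetic data

The generators provide the statistical structure the analysis assumes, with
ground truth stored alongside; they are deliberately not biomechanical
models.

- **Sway**: two independent Ornstein–Uhlenbeck paths (exact discretization
  `x[k+1] = φx[k] + σ√(1−φ²)z`, φ = e^(−Δt/τ)), stationary SD
  √(Dτ/2) ≈ 5 mm with τ = 0.4 s by default, so the energy sits well below
  the 3.5-Hz cutoff. The OU model is the simplest stationary process with
  tunable bandwidth; it reproduces second-order statistics (bounded
  zero-mean sway with low-frequency energy) but not intermittent postural
  corrections, drift nonstationarity, or the two-rate structure of real CoP —
  passing tests therefore validate the computation, not physiological
  realism.
- **Perturbations**: linear rise to a set amplitude over 0.5 s followed by
  exponential return (τ = 1 s) on OU baseline noise, with a matching
  trapezoidal belt pulse. Closed-form peak, TTP and band-crossing times make
  the extractor's output checkable analytically.
- **Gait**: raised-cosine angle cycles with per-stride amplitude N(ROM,
  rom_sd²), half-sine power bursts of known height, events at cycle
  boundaries with optional Gaussian stride-time jitter, and constant-mean
  foot placements with optional noise. Injected variability (ROM SD, stride
  jitter) is recovered within 15% at 50 strides.
- **Cohorts**: bivariate-normal (T0, T1) per subject with test–retest
  correlation ρ = 0.8 by default, additive standardized group/time/
  interaction effects, and a group-specific age covariate (training
  ≈ 9.1 ± 1.9 y, control ≈ 10.8 ± 1.7 y, reflecting the marginal age
  imbalance such small trials show). Note the deliberate consequence: the
  group–age correlation inflates the covariate-adjusted interaction SE, so
  adjusted power at a given effect is slightly below the balanced-design
  analytic curve.
- **Full study**: `write_synthetic_study` emits per-subject trial CSVs
  (4 standing conditions, 1 reactive, 1 gait trial per timepoint) plus a
  ground-truth manifest; a training-group sway reduction at T1 (default 15%)
  injects the time × group interaction at the signal level. The default
  synthetic acquisition scale is 100 Hz with 70-s static records; tests and
  the acceptance script use further reduced scales (50 Hz, 15-s records with
  a 10-s window, 3–5 subjects per group for file-level smoke tests; 10/group
  for all statistical calibration), chosen so a full run completes in
  seconds while preserving every structural feature the pipeline consumes.

All randomness flows through one explicitly passed `numpy.random.Generator`;
every generator is deterministic given its seed.

## Known limitations

- The CoM pathway is metric-compatible but has no dedicated accelerometer
  noise model in the generator.
- CoP-only onset detection assumes perturbation responses well above the
  baseline derivative noise after 0.1-s smoothing; very small perturbations
  require the belt-speed channel.
- The ANCOVA layer is restricted to two timepoints and two groups by
  design; k > 2 timepoints would need sphericity machinery that two
  timepoints make moot.
- Frequency-domain posturography (spectral power, sway density), Romberg
  quotients, and event detection from raw force signals are out of scope.
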