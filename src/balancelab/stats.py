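"""Statistical layer: baseline comparisons and the two-timepoint mixed ANCOVA.

The design is a pre/post parallel-group trial: time (T0, T1) is the
within-subjects factor, group (training, control) the between-subjects
factor, and age a continuous covariate.  With exactly two timepoints the
mixed-design ANCOVA decomposes exactly into two independent OLS strata:

* between-subjects stratum — subject means ``(Y0 + Y1) / 2`` regressed on an
  effect-coded group indicator and the centered covariate; tests the group
  main effect and the covariate;
* within-subjects stratum — difference scores ``Y1 - Y0`` regressed on the
  same design; the intercept tests the time main effect, the group
  coefficient the time x group interaction, and the covariate coefficient the
  time x covariate term.

Effect coding plus a centered covariate makes the single-degree-of-freedom
F tests Type III, appropriate for the unbalanced group sizes that arise from
per-outcome missingness (analysis is listwise per outcome).  Effect sizes are
partial eta squared, ``SS_effect / (SS_effect + SS_error)``.  Simple main
effects (the per-group T0-vs-T1 contrast at the covariate mean) are evaluated
on the within-stratum fit, uncorrected for multiplicity — comparisons in this
design are planned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "StatsError",
    "EffectResult",
    "SimpleEffect",
    "AnovaResult",
    "validate_cohort",
    "mixed_ancova",
    "mixed_ancova_arrays",
    "simple_main_effects",
    "one_way_anova_summary",
    "chi_square_2x2",
    "partial_eta_squared",
    "interaction_power",
    "implied_retest_correlation",
]

TIMEPOINTS = ("T0", "T1")


class StatsError(ValueError):
    """Raised on invalid designs or degenerate data."""


@dataclass(frozen=True)
class EffectResult:
    """One F test: statistic, degrees of freedom, p and partial eta squared."""

    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    estimate: Optional[float] = None


@dataclass(frozen=True)
class SimpleEffect:
    """Per-group T0-vs-T1 contrast at the covariate mean."""

    group: str
    estimate: float  # adjusted mean change (T1 - T0)
    se: float
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    """Mixed two-timepoint ANCOVA for one outcome.

    ``effects`` holds the time, group, time x group (and covariate terms)
    F tests; ``groups`` maps the effect-coding (+1 for the first group in
    sorted order, -1 for the second).
    """

    outcome: str
    n_per_group: dict[str, int]
    groups: tuple[str, str]
    effects: dict[str, EffectResult]
    covariate: Optional[str]
    simple_effects: list[SimpleEffect] = field(default_factory=list)

    @property
    def interaction(self) -> EffectResult:
        return self.effects["time_x_group"]


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """``SS_effect / (SS_effect + SS_error)``; both inputs must be >= 0."""
    if ss_effect < 0 or ss_error < 0:
        raise StatsError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise StatsError("SS_effect and SS_error cannot both be zero")
    return ss_effect / (ss_effect + ss_error)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format cohort table invariants.

    Expected columns: subject, group, age, timepoint, outcome, value (sex
    optional).  Each subject belongs to exactly one group; at most one value
    per (subject, timepoint, outcome).
    """
    need = {"subject", "group", "age", "timepoint", "outcome", "value"}
    missing = need - set(table.columns)
    if missing:
        raise StatsError(f"cohort table missing columns {sorted(missing)}")
    g = table.groupby("subject")["group"].nunique()
    if (g > 1).any():
        bad = g[g > 1].index.tolist()
        raise StatsError(f"subjects in more than one group: {bad}")
    dup = table.duplicated(subset=["subject", "timepoint", "outcome"])
    if dup.any():
        raise StatsError("duplicate (subject, timepoint, outcome) rows")
    if not set(table["timepoint"]).issubset(TIMEPOINTS):
        raise StatsError(f"timepoint must be one of {TIMEPOINTS}")
    return table


def _pivot_complete(table: pd.DataFrame, outcome: str):
    """Wide (T0, T1) arrays for subjects with both timepoints (listwise)."""
    sub = table[table["outcome"] == outcome]
    if sub.empty:
        raise StatsError(f"no rows for outcome {outcome!r}")
    wide = sub.pivot(index="subject", columns="timepoint", values="value")
    if "T0" not in wide.columns or "T1" not in wide.columns:
        raise StatsError(f"outcome {outcome!r} lacks one of the timepoints")
    wide = wide.dropna(subset=["T0", "T1"])
    meta = sub.drop_duplicates("subject").set_index("subject")
    meta = meta.loc[wide.index]
    return (
        wide["T0"].to_numpy(float),
        wide["T1"].to_numpy(float),
        meta["group"].to_numpy(),
        meta["age"].to_numpy(float),
    )


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares fit returning (beta, XtX_inv, rss, df_error)."""
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise StatsError("singular design matrix") from exc
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = y.size - X.shape[1]
    return beta, xtx_inv, rss, df


def _coef_tests(beta, xtx_inv, rss, df, names) -> dict[str, EffectResult]:
    if df <= 0:
        raise StatsError("no error degrees of freedom")
    mse = rss / df
    if mse <= 0:
        raise StatsError("zero error variance")
    out = {}
    for j, name in enumerate(names):
        if name is None:
            continue
        se2 = mse * xtx_inv[j, j]
        F = float(beta[j] ** 2 / se2)
        ss_eff = F * mse
        out[name] = EffectResult(
            F=F,
            df1=1,
            df2=df,
            p=float(spstats.f.sf(F, 1, df)),
            partial_eta_sq=partial_eta_squared(ss_eff, rss),
            ss_effect=ss_eff,
            ss_error=rss,
            estimate=float(beta[j]),
        )
    return out


def _design(group_codes: np.ndarray, age_c: Optional[np.ndarray]) -> np.ndarray:
    cols = [np.ones_like(group_codes, dtype=float), group_codes.astype(float)]
    if age_c is not None:
        cols.append(age_c)
    return np.column_stack(cols)


def mixed_ancova_arrays(
    t0: np.ndarray,
    t1: np.ndarray,
    group: np.ndarray,
    age: Optional[np.ndarray] = None,
    within_covariate: bool = True,
    outcome: str = "outcome",
) -> AnovaResult:
    """Core mixed-ANCOVA computation on plain arrays.

    ``group`` holds the two group labels per subject; the first label in
    sorted order is effect-coded +1.  ``age=None`` fits the plain mixed ANOVA.
    ``within_covariate=False`` keeps age out of the within-subjects stratum
    (classical ANCOVA covariate only).
    """
    t0 = np.asarray(t0, float)
    t1 = np.asarray(t1, float)
    group = np.asarray(group)
    labels = tuple(sorted(np.unique(group).tolist()))
    if len(labels) != 2:
        raise StatsError(f"need exactly 2 groups, got {labels}")
    codes = np.where(group == labels[0], 1.0, -1.0)
    n_per = {lab: int((group == lab).sum()) for lab in labels}
    if min(n_per.values()) < 2:
        raise StatsError(f"need >= 2 complete subjects per group, got {n_per}")
    age_c = None
    if age is not None:
        age = np.asarray(age, float)
        if np.isnan(age).any():
            raise StatsError("age missing for analyzed subjects")
        age_c = age - age.mean()

    effects: dict[str, EffectResult] = {}

    # between-subjects stratum: subject means
    Xb = _design(codes, age_c)
    names_b = [None, "group"] + (["age"] if age_c is not None else [])
    yb = (t0 + t1) / 2.0
    effects.update(_coef_tests(*_ols(Xb, yb), names_b))

    # within-subjects stratum: difference scores
    Xw = _design(codes, age_c if within_covariate else None)
    names_w = ["time", "time_x_group"] + (
        ["time_x_age"] if (age_c is not None and within_covariate) else []
    )
    yw = t1 - t0
    beta_w, inv_w, rss_w, df_w = _ols(Xw, yw)
    effects.update(_coef_tests(beta_w, inv_w, rss_w, df_w, names_w))

    result = AnovaResult(
        outcome=outcome,
        n_per_group=n_per,
        groups=labels,
        effects=effects,
        covariate="age" if age is not None else None,
    )
    # stash the within fit for simple-effects computation
    object.__setattr__(result, "_within_fit", (beta_w, inv_w, rss_w, df_w, Xw.shape[1]))
    return result


def mixed_ancova(
    table: pd.DataFrame,
    outcome: str,
    covariate: str = "age",
    within_covariate: bool = True,
) -> AnovaResult:
    """Two-timepoint mixed ANCOVA for one outcome of a long cohort table.

    Subjects lacking either timepoint for this outcome are dropped
    (listwise deletion per outcome).  See :func:`mixed_ancova_arrays`.
    """
    validate_cohort(table)
    t0, t1, group, age = _pivot_complete(table, outcome)
    return mixed_ancova_arrays(
        t0,
        t1,
        group,
        age if covariate is not None else None,
        within_covariate=within_covariate,
        outcome=outcome,
    )


def simple_main_effects(result: AnovaResult) -> list[SimpleEffect]:
    """Per-group T0-vs-T1 contrast evaluated at the covariate mean.

    The contrast is the fitted mean difference score for each group at the
    (centered) covariate mean: ``b0 + b_group * code``.  p values are
    uncorrected.
    """
    beta, xtx_inv, rss, df, p = result._within_fit  # type: ignore[attr-defined]
    mse = rss / df
    if mse <= 0:
        raise StatsError("zero error variance")
    out = []
    for label, code in zip(result.groups, (1.0, -1.0)):
        c = np.zeros(p)
        c[0] = 1.0
        c[1] = code
        est = float(c @ beta)
        se = float(np.sqrt(mse * (c @ xtx_inv @ c)))
        F = (est / se) ** 2 if se > 0 else np.inf
        ss_eff = F * mse
        out.append(
            SimpleEffect(
                group=label,
                estimate=est,
                se=se,
                F=float(F),
                df1=1,
                df2=df,
                p=float(spstats.f.sf(F, 1, df)),
                partial_eta_sq=partial_eta_squared(ss_eff, rss),
            )
        )
    result.simple_effects.clear()
    result.simple_effects.extend(out)
    return out


def one_way_anova_summary(
    groups: Sequence[tuple[int, float, float]],
) -> tuple[float, float]:
    """One-way ANOVA F and p reconstructed from per-group (n, mean, sd).

    Used for baseline comparability checks where only summary statistics are
    available.  ``sd`` is the sample standard deviation (ddof=1).
    """
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    ns = np.array([g[0] for g in groups], float)
    means = np.array([g[1] for g in groups], float)
    sds = np.array([g[2] for g in groups], float)
    if (ns < 2).any():
        raise StatsError("each group needs n >= 2")
    if (sds < 0).any():
        raise StatsError("sd must be >= 0")
    N = ns.sum()
    k = len(groups)
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    if ss_within <= 0:
        raise StatsError("zero within-group variance")
    F = (ss_between / (k - 1)) / (ss_within / (N - k))
    p = float(spstats.f.sf(F, k - 1, int(N - k)))
    return float(F), p


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    The uncorrected statistic is the planned-comparison convention here; the
    Yates-corrected value would collapse small-sample tables toward 0.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise StatsError("counts must be a 2x2 table")
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        raise StatsError("counts must be non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise StatsError("all marginals must be positive")
    chi2, p, _, _ = spstats.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)


def interaction_power(
    effect_size: float,
    n_per_group: int,
    retest_rho: float,
    alpha: float = 0.05,
) -> float:
    """Power of the time x group interaction test.

    With two timepoints the interaction test is a two-sample t test on
    difference scores.  ``effect_size`` is the standardized between-group
    difference in change (units of the outcome SD at one timepoint);
    difference scores have SD ``sqrt(2 * (1 - retest_rho))`` on that scale,
    so the operative Cohen's d is ``effect_size / sqrt(2 * (1 - rho))``.
    """
    if not -1.0 < retest_rho < 1.0:
        raise StatsError("retest correlation must lie in (-1, 1)")
    d = effect_size / np.sqrt(2.0 * (1.0 - retest_rho))
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    crit = spstats.t.ppf(1 - alpha / 2.0, df)
    return float(
        spstats.nct.sf(crit, df, nc) + spstats.nct.cdf(-crit, df, nc)
    )


def implied_retest_correlation(
    effect_size: float = 0.7,
    n_per_group: int = 10,
    power: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Test-retest correlation under which the design attains the stated power.

    Small pre/post trials sized at an effect of 0.7 with 10 subjects per
    group implicitly assume highly reliable outcomes: this solves for the
    test-retest correlation rho at which the interaction (difference-score)
    test reaches ``power``.
    """
    from scipy.optimize import brentq

    f = lambda rho: interaction_power(effect_size, n_per_group, rho, alpha) - power
    return float(brentq(f, -0.9999, 0.9999, xtol=1e-10))
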