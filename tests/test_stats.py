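"""Statistical layer: baseline tests and the two-timepoint mixed ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from balancelab.stats import (
    StatsError,
    chi_square_2x2,
    implied_retest_correlation,
    interaction_power,
    mixed_ancova,
    mixed_ancova_arrays,
    one_way_anova_summary,
    partial_eta_squared,
    simple_main_effects,
    validate_cohort,
)
from balancelab.synth import CohortModelParams, cohort_arrays, generate_cohort


def long_table(t0, t1, group, age):
    rows = []
    for i in range(len(t0)):
        for tp, v in (("T0", t0[i]), ("T1", t1[i])):
            rows.append(
                {
                    "subject": f"S{i:02d}",
                    "group": group[i],
                    "age": age[i],
                    "timepoint": tp,
                    "outcome": "y",
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


# fixed small worked dataset: 8 subjects, 2 groups, age covariate
T0 = np.array([1.2, 0.9, 1.4, 1.1, 0.8, 1.0, 1.3, 0.7])
T1 = np.array([1.0, 0.8, 1.1, 1.0, 0.9, 1.1, 1.4, 0.8])
GROUP = np.array(["training"] * 4 + ["control"] * 4)
AGE = np.array([8.0, 9.5, 11.0, 7.5, 10.0, 12.0, 9.0, 8.5])


class TestChiSquare:
    def test_sex_table(self):
        chi2, p = chi_square_2x2(np.array([[9, 1], [8, 2]]))
        assert chi2 == pytest.approx(0.392, abs=5e-4)
        assert p == pytest.approx(0.531, abs=5e-3)

    def test_balanced_table_zero(self):
        chi2, _ = chi_square_2x2(np.array([[5, 5], [5, 5]]))
        assert chi2 == 0.0

    def test_brute_force_oracle(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 30, size=(2, 2))
            chi2, _ = chi_square_2x2(counts)
            total = counts.sum()
            expected = np.outer(counts.sum(1), counts.sum(0)) / total
            brute = ((counts - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(brute, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(StatsError):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))


class TestOneWayAnova:
    @pytest.mark.parametrize(
        "groups,f_expected,tol",
        [
            ([(10, 97.9, 15.42), (9, 101.44, 18.82)], 0.203, 5e-4),  # IQ row
            ([(10, 9.14, 1.85), (10, 10.75, 1.71)], 4.075, 0.02),    # age row
            ([(6, 5.33, 2.34), (9, 6.56, 1.67)], 1.411, 0.02),       # ADOS row
        ],
    )
    def test_baseline_rows(self, groups, f_expected, tol):
        F, _ = one_way_anova_summary(groups)
        assert F == pytest.approx(f_expected, abs=tol)

    def test_equal_means_zero(self):
        F, p = one_way_anova_summary([(5, 2.0, 1.0), (7, 2.0, 2.0)])
        assert F == 0.0 and p == 1.0

    def test_moment_matched_sample_oracle(self, rng):
        # reconstruct samples with the exact moments, compare to scipy ANOVA
        for _ in range(10):
            specs = [
                (int(rng.integers(3, 12)), rng.normal(0, 5), rng.uniform(0.5, 3))
                for _ in range(3)
            ]
            samples = []
            for n, m, sd in specs:
                z = rng.normal(size=n)
                z = (z - z.mean()) / z.std(ddof=1)
                samples.append(m + sd * z)
            F, p = one_way_anova_summary(specs)
            F_ref, p_ref = spstats.f_oneway(*samples)
            assert F == pytest.approx(F_ref, rel=1e-9)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_single_subject_groups_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova_summary([(1, 0.0, 0.0), (1, 1.0, 0.0)])


class TestPartialEtaSquared:
    @pytest.mark.parametrize("ss,err,expected", [(0, 5, 0.0), (5, 0, 1.0), (3, 9, 0.25)])
    def test_values(self, ss, err, expected):
        assert partial_eta_squared(ss, err) == expected

    def test_negative_rejected(self):
        with pytest.raises(StatsError):
            partial_eta_squared(-1, 2)


class TestMixedAncova:
    def test_identical_groups_zero_interaction(self):
        # both groups show the same (T0, T1) pattern and ages
        t0 = np.tile([1.0, 1.2, 0.8, 1.1], 2)
        t1 = np.tile([1.1, 1.3, 0.8, 1.0], 2)
        group = np.array(["training"] * 4 + ["control"] * 4)
        age = np.tile([8.0, 9.0, 10.0, 11.0], 2)
        res = mixed_ancova_arrays(t0, t1, group, age)
        assert res.interaction.F < 1e-10

    def test_ols_design_matrix_oracle(self):
        """F for each effect equals an independent statsmodels GLM fit."""
        import statsmodels.api as sm

        res = mixed_ancova_arrays(T0, T1, GROUP, AGE)
        codes = np.where(GROUP == "control", 1.0, -1.0)  # sorted: control first
        age_c = AGE - AGE.mean()
        X = np.column_stack([np.ones(8), codes, age_c])
        for y, effects in (
            ((T0 + T1) / 2, {"group": 1, "age": 2}),
            (T1 - T0, {"time": 0, "time_x_group": 1, "time_x_age": 2}),
        ):
            fit = sm.OLS(y, X).fit()
            for name, col in effects.items():
                F_ref = float(fit.tvalues[col] ** 2)
                assert res.effects[name].F == pytest.approx(F_ref, rel=1e-8)
                assert res.effects[name].p == pytest.approx(
                    float(fit.pvalues[col]), rel=1e-8
                )

    def test_interaction_equals_squared_t_without_covariate(self, rng):
        # with no covariate the interaction F is the squared two-sample t
        # on difference scores
        for _ in range(5):
            t0 = rng.normal(1, 0.3, 14)
            t1 = rng.normal(1, 0.3, 14)
            group = np.array(["training"] * 7 + ["control"] * 7)
            res = mixed_ancova_arrays(t0, t1, group, age=None)
            d = t1 - t0
            t_ref, _ = spstats.ttest_ind(d[group == "control"], d[group == "training"])
            assert res.interaction.F == pytest.approx(t_ref**2, rel=1e-8)

    def test_long_table_listwise_deletion(self):
        table = long_table(T0, T1, GROUP, AGE)
        # drop one subject's T1 -> analyzed n should fall by 1
        table = table.drop(table[(table.subject == "S00") & (table.timepoint == "T1")].index)
        res = mixed_ancova(table, "y")
        assert sum(res.n_per_group.values()) == 7

    def test_small_group_rejected(self):
        t0 = np.array([1.0, 1.1, 0.9])
        t1 = np.array([1.0, 1.2, 0.8])
        group = np.array(["training", "control", "control"])
        with pytest.raises(StatsError):
            mixed_ancova_arrays(t0, t1, group)

    def test_independent_covariate_matches_no_covariate_distribution(self, rng):
        # age generated independent of outcome: interaction F distribution
        # matches the no-covariate case within Monte-Carlo error
        n_sim = 400
        p_cov, p_nocov = [], []
        for _ in range(n_sim):
            t0 = rng.normal(0, 1, 20)
            t1 = rng.normal(0, 1, 20)
            group = np.array(["training"] * 10 + ["control"] * 10)
            age = rng.normal(10, 2, 20)
            p_cov.append(mixed_ancova_arrays(t0, t1, group, age).interaction.p)
            p_nocov.append(mixed_ancova_arrays(t0, t1, group).interaction.p)
        r_cov = np.mean(np.array(p_cov) < 0.05)
        r_nocov = np.mean(np.array(p_nocov) < 0.05)
        assert abs(r_cov - r_nocov) < 0.04

    def test_permutation_null_uniform(self, rng):
        # permuting group labels on null data: interaction p ~ Uniform(0,1)
        t0 = rng.normal(0, 1, 20)
        t1 = rng.normal(0, 1, 20)
        age = rng.normal(10, 2, 20)
        base = np.array(["training"] * 10 + ["control"] * 10)
        ps = []
        for _ in range(2000):
            res = mixed_ancova_arrays(t0, t1, rng.permutation(base), age)
            ps.append(res.interaction.p)
        ks = spstats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestSimpleEffects:
    def test_unchanged_group_null_contrast(self):
        # training group identical at T0/T1, balanced ages -> zero contrast
        t0 = np.array([1.0, 1.2, 0.8, 1.1, 0.5, 0.9, 1.3, 1.0])
        t1 = np.array([1.0, 1.2, 0.8, 1.1, 0.7, 1.2, 1.5, 1.1])
        group = np.array(["training"] * 4 + ["control"] * 4)
        age = np.tile([8.0, 9.0, 10.0, 11.0], 2)
        res = mixed_ancova_arrays(t0, t1, group, age)
        simples = {s.group: s for s in simple_main_effects(res)}
        assert simples["training"].estimate == pytest.approx(0.0, abs=1e-12)
        assert simples["training"].p == pytest.approx(1.0, abs=1e-9)
        assert simples["control"].estimate > 0

    def test_contrast_equals_adjusted_mean_difference(self):
        res = mixed_ancova_arrays(T0, T1, GROUP, AGE)
        simples = {s.group: s for s in simple_main_effects(res)}
        # brute force: fitted difference score at the covariate mean per group
        codes = np.where(GROUP == "control", 1.0, -1.0)
        age_c = AGE - AGE.mean()
        X = np.column_stack([np.ones(8), codes, age_c])
        beta = np.linalg.lstsq(X, T1 - T0, rcond=None)[0]
        assert simples["control"].estimate == pytest.approx(beta[0] + beta[1], rel=1e-10)
        assert simples["training"].estimate == pytest.approx(beta[0] - beta[1], rel=1e-10)

    def test_injected_training_effect_detected(self):
        # effect only in the training group at calibrated power: the training
        # contrast should be significant far more often than the control one
        n_rep = 200
        rng = np.random.default_rng(7)
        sig_tr = sig_co = 0
        params = CohortModelParams(interaction_effect=-1.5, retest_rho=0.9)
        for _ in range(n_rep):
            t0, t1, group, age = cohort_arrays(params, rng)
            res = mixed_ancova_arrays(t0, t1, group, age)
            simples = {s.group: s for s in simple_main_effects(res)}
            sig_tr += simples["training"].p < 0.05
            sig_co += simples["control"].p < 0.05
        assert sig_tr / n_rep >= 0.90
        assert sig_co / n_rep < 0.20


class TestCohortValidation:
    def test_subject_in_two_groups_rejected(self):
        table = long_table(T0, T1, GROUP, AGE)
        table.loc[table.index[-1], "group"] = "training"
        with pytest.raises(StatsError):
            validate_cohort(table)

    def test_duplicate_measurement_rejected(self):
        table = long_table(T0, T1, GROUP, AGE)
        with pytest.raises(StatsError):
            validate_cohort(pd.concat([table, table.iloc[[0]]]))


class TestPower:
    def test_power_monotone_in_rho(self):
        powers = [interaction_power(0.7, 10, r) for r in (0.3, 0.6, 0.9)]
        assert powers[0] < powers[1] < powers[2]

    def test_implied_rho_consistent(self):
        rho = implied_retest_correlation(0.7, 10, 0.8)
        assert interaction_power(0.7, 10, rho) == pytest.approx(0.8, abs=1e-6)
        assert 0.8 < rho < 0.95
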