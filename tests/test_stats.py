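"""Statistical stage: exact tests, adjusted GLM comparisons, FDR,
subgrouping, sample size."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import bruteforce as bf
from hemilat.errors import ConfigurationError, InputError
from hemilat.lateralization import ALL_METRICS
from hemilat.stats import (
    analytic_sample_size,
    chi_square_2x2,
    compare_lateralization,
    correlate_with_age,
    fdr_bh,
    fisher_exact_2x2,
    glm_adjusted_compare,
    group_test,
    proportion_pct,
    sample_size_two_proportions,
    subgroup_compare,
)


def _cohort_frame(n_group1=30, n_group2=20, seed=0, group_col_values=None):
    rng = np.random.default_rng(seed)
    n = n_group1 + n_group2
    groups = (["preterm"] * n_group1 + ["term"] * n_group2
              if group_col_values is None else group_col_values)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "group": groups,
            "sex": rng.choice(["male", "female"], size=n),
            "age_at_mri": rng.normal(38, 1, size=n).round(2),
            "gestational_age": rng.normal(33, 3, size=n).round(2),
            "bpd": rng.choice(["yes", "no"], size=n),
        }
    )


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_bayley_se_table_matches_enumeration_oracle(self):
        p = fisher_exact_2x2(13, 44, 0, 21)
        assert p == pytest.approx(bf.fisher_two_sided(13, 44, 0, 21),
                                  rel=1e-9)

    def test_equals_enumeration_on_all_small_tables(self):
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    for d in range(6):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                            bf.fisher_two_sided(a, b, c, d), abs=1e-10
                        ), (a, b, c, d)

    def test_empty_margin_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_2x2(0, 0, 3, 4)


class TestChiSquare:
    def test_hand_formula_on_bayley_table(self):
        stat, _ = chi_square_2x2(13, 44, 0, 21)
        n = 78
        expected = n * (13 * 21 - 44 * 0) ** 2 / (57 * 21 * 13 * 65)
        assert stat == pytest.approx(expected)

    def test_independent_table_zero(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_yates_never_larger(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(1, 30, size=4)
            plain, _ = chi_square_2x2(a, b, c, d, yates=False)
            corrected, _ = chi_square_2x2(a, b, c, d, yates=True)
            assert corrected <= plain + 1e-12


class TestGroupTest:
    def test_identical_groups_mann_whitney(self):
        assert group_test([1, 2, 3, 4], [1, 2, 3, 4],
                          "mann_whitney") == pytest.approx(1.0)

    def test_t_statistic_closed_form(self):
        # pooled t on (1,2,3) vs (4,5,6): s_p^2 = 1, t = -3/sqrt(2/3)
        p = group_test([1, 2, 3], [4, 5, 6], "student_t")
        t = -3 / math.sqrt(2 / 3)
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=4))

    def test_power_on_two_sd_shift(self):
        rng = np.random.default_rng(123)
        hits = sum(
            group_test(rng.normal(0, 1, 50), rng.normal(2, 1, 50),
                       "student_t") < 1e-3
            for _ in range(100)
        )
        assert hits >= 99

    def test_too_small_group_rejected(self):
        with pytest.raises(InputError):
            group_test([1], [2, 3], "student_t")


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(1e-6, 1, size=25)
        adj = fdr_bh(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            fdr_bh([0.0, 0.5])


class TestGlmAdjustedCompare:
    def test_zero_covariates_reproduces_pooled_t(self):
        rng = np.random.default_rng(5)
        cohort = _cohort_frame(25, 25, seed=5)
        y = pd.Series(rng.normal(0, 1, 50), index=cohort["subject_id"])
        y[cohort["group"].values == "preterm"] += 0.4
        res = glm_adjusted_compare(y, cohort, covariates=())
        x1 = y[(cohort["group"] == "preterm").values]
        x2 = y[(cohort["group"] == "term").values]
        p_t = sps.ttest_ind(x1, x2, equal_var=True).pvalue
        assert res.p_raw == pytest.approx(p_t, abs=1e-9)
        assert res.effect == pytest.approx(x1.mean() - x2.mean(), abs=1e-12)

    def test_orthogonal_covariate_leaves_p_unchanged(self):
        """Orthogonality limit: a covariate orthogonal to outcome and group
        leaves the group effect untouched; the p-value converges to the
        plain t-test p as the residual-df difference becomes negligible."""
        n = 400_000
        rng = np.random.default_rng(600)
        cohort = _cohort_frame(n // 2, n // 2, seed=6)
        y = pd.Series(rng.normal(0, 1, n), index=cohort["subject_id"])
        # residualize the covariate against intercept, group and outcome so
        # the design blocks are exactly orthogonal
        g = (cohort["group"] == "preterm").astype(float).to_numpy()
        cov = rng.normal(0, 1, n)
        yv = y.to_numpy()
        for basis in (np.ones(n), g - g.mean(), yv - yv.mean()):
            cov = cov - cov @ basis / (basis @ basis) * basis
        cohort["ortho"] = cov
        res = glm_adjusted_compare(y, cohort, covariates=("ortho",))
        base = glm_adjusted_compare(y, cohort, covariates=())
        assert res.effect == pytest.approx(base.effect, abs=1e-10)
        assert res.p_raw == pytest.approx(base.p_raw, abs=1e-6)

    def test_null_group_effect_ci_coverage(self):
        """Outcome driven by a covariate only: the group CI should cover 0
        (p > .05) in >= 93/100 replicates."""
        covered = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            cohort = _cohort_frame(30, 30, seed=1000 + rep)
            y = pd.Series(
                2.0 * cohort["age_at_mri"].to_numpy()
                + rng.normal(0, 1, 60),
                index=cohort["subject_id"],
            )
            res = glm_adjusted_compare(y, cohort,
                                       covariates=("age_at_mri",))
            covered += res.p_raw > 0.05
        assert covered >= 93

    def test_adjustment_recovers_confounded_effect(self):
        """With a confounder correlated with group, the adjusted estimate
        should be closer to the true effect than the unadjusted one."""
        delta = 1.0
        adj_err, unadj_err = [], []
        for rep in range(100):
            rng = np.random.default_rng(2000 + rep)
            cohort = _cohort_frame(40, 40, seed=2000 + rep)
            g = (cohort["group"] == "preterm").astype(float).to_numpy()
            confounder = g * 1.5 + rng.normal(0, 1, 80)
            cohort["conf"] = confounder
            y = pd.Series(delta * g + 2.0 * confounder
                          + rng.normal(0, 1, 80),
                          index=cohort["subject_id"])
            adj = glm_adjusted_compare(y, cohort, covariates=("conf",))
            unadj = glm_adjusted_compare(y, cohort, covariates=())
            adj_err.append(abs(adj.effect - delta))
            unadj_err.append(abs(unadj.effect - delta))
        assert np.mean(adj_err) < np.mean(unadj_err)

    def test_collinear_design_named(self):
        cohort = _cohort_frame(10, 10, seed=7)
        cohort["dup"] = cohort["age_at_mri"]
        y = pd.Series(np.arange(20, dtype=float),
                      index=cohort["subject_id"])
        with pytest.raises(InputError, match="dup|age_at_mri"):
            glm_adjusted_compare(y, cohort,
                                 covariates=("age_at_mri", "dup"))


def _as_table_from_values(values: dict[str, np.ndarray], subject_ids):
    rows = []
    for metric, vals in values.items():
        for sid, v in zip(subject_ids, vals):
            rows.append({"subject_id": sid, "metric": metric,
                         "x_left": np.nan, "x_right": np.nan,
                         "AS": v, "defined": not np.isnan(v)})
    return pd.DataFrame(rows)


def _full_cohort(n_pre=64, n_term=33, n_abnormal=13, n_assessed=57, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pre + n_term
    cohort = _cohort_frame(n_pre, n_term, seed=seed)
    assessed = np.zeros(n, dtype=bool)
    assessed[:n_assessed] = True  # preterm block first
    cohort["assessed_flag"] = assessed
    se = np.full(n, np.nan)
    se[:n_assessed] = rng.normal(97, 17, n_assessed)
    order = np.argsort(se[:n_assessed])
    abnormal = np.zeros(n, dtype=bool)
    abnormal[order[:n_abnormal]] = True
    cohort["se_abnormal"] = abnormal
    cohort["bayley_se"] = se
    return cohort


class TestCompareLateralization:
    def test_families_and_schema(self):
        rng = np.random.default_rng(900_003)
        cohort = _full_cohort(seed=3)
        values = {m: rng.normal(0, 5, len(cohort)) for m in ALL_METRICS}
        table = _as_table_from_values(values, cohort["subject_id"])
        comp = compare_lateralization(table, cohort)
        assert set(comp["family"]) == {"global", "roi"}
        assert len(comp) == 9
        assert (comp["p_fdr"] >= comp["p_raw"] - 1e-15).all()
        assert (comp["n_group1"] == 64).all()
        assert (comp["n_group2"] == 33).all()

    def test_undefined_records_dropped_and_counted(self):
        rng = np.random.default_rng(900_004)
        cohort = _full_cohort(seed=4)
        values = {m: rng.normal(0, 5, len(cohort)) for m in ALL_METRICS}
        values["amygdala"][:10] = np.nan
        table = _as_table_from_values(values, cohort["subject_id"])
        comp = compare_lateralization(table, cohort)
        row = comp[comp["outcome"] == "amygdala"].iloc[0]
        assert row["n_dropped"] == 10
        assert row["n_group1"] + row["n_group2"] == 87


class TestCorrelateWithAge:
    def test_constant_as_flagged_undefined(self):
        cohort = _full_cohort(seed=5)
        table = _as_table_from_values(
            {"sigma": np.full(len(cohort), 2.0)}, cohort["subject_id"])
        out = correlate_with_age(table, cohort)
        assert not out["defined"].iloc[0]

    def test_exact_linear_relation_r_one(self):
        cohort = _full_cohort(seed=6)
        table = _as_table_from_values(
            {"sigma": 3.0 * cohort["age_at_mri"].to_numpy() - 100},
            cohort["subject_id"])
        out = correlate_with_age(table, cohort)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_null_correlation_calibration(self):
        """Independent AS and age: mean r over replicates ~ 0."""
        rs = []
        for rep in range(100):
            rng = np.random.default_rng(920_000 + rep)
            cohort = _cohort_frame(40, 20, seed=3000 + rep)
            table = _as_table_from_values(
                {"sigma": rng.normal(0, 5, 60)}, cohort["subject_id"])
            rs.append(correlate_with_age(table, cohort)["r"].iloc[0])
        assert abs(np.mean(rs)) < 2 / math.sqrt(60)


class TestSubgroupCompare:
    def test_reported_group_sizes_13_44(self):
        rng = np.random.default_rng(900_008)
        cohort = _full_cohort(seed=8)
        values = {m: rng.normal(0, 5, len(cohort)) for m in ALL_METRICS}
        table = _as_table_from_values(values, cohort["subject_id"])
        out = subgroup_compare(table, cohort)
        assert (out["n_group1"] == 13).all()
        assert (out["n_group2"] == 44).all()
        assert len(out) == 9
        assert set(out["family"]) == {"subgroup"}

    def test_null_subgroup_rarely_significant(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(900_000 + rep)
            cohort = _full_cohort(seed=4000 + rep)
            values = {m: rng.normal(0, 5, len(cohort)) for m in ALL_METRICS}
            table = _as_table_from_values(values, cohort["subject_id"])
            out = subgroup_compare(table, cohort)
            hits += (out["p_fdr"] <= 0.05).any()
        assert 100 - hits >= 95

    def test_planted_mfog_shift_detected(self):
        """1.5-SD mFOG asymmetry shift in the abnormal subgroup should be
        FDR-detected in >= 80/100 replicates."""
        detected = 0
        for rep in range(100):
            rng = np.random.default_rng(910_000 + rep)
            cohort = _full_cohort(seed=5000 + rep)
            values = {m: rng.normal(0, 5, len(cohort)) for m in ALL_METRICS}
            mask = cohort["se_abnormal"].to_numpy()
            values["mFOG"] = values["mFOG"] + 1.5 * 5.0 * mask
            table = _as_table_from_values(values, cohort["subject_id"])
            out = subgroup_compare(table, cohort)
            row = out[out["outcome"] == "mFOG"]
            detected += float(row["p_fdr"].iloc[0]) <= 0.05
        assert detected >= 80


class TestSampleSize:
    def test_documented_output_for_printed_inputs(self):
        out = sample_size_two_proportions(0.15, 0.40, 0.05, 0.8, 0.10)
        # standard normal-approximation arithmetic for these inputs
        assert out["n_per_group"] == 49
        assert out["n_total"] == 98
        assert out["n_per_group_dropout"] == 55
        assert out["n_total_dropout"] == 110

    def test_n_increases_with_power(self):
        previous = 0
        for power in (0.5, 0.7, 0.8, 0.9, 0.99):
            n = sample_size_two_proportions(0.15, 0.40,
                                            power=power)["n_per_group"]
            assert n >= previous
            previous = n

    def test_equal_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_size_two_proportions(0.3, 0.3)

    def test_empirical_power_at_returned_n(self):
        """Simulation oracle: the two-proportion z-test at the returned
        pre-dropout n achieves roughly the target power."""
        p1, p2, target = 0.15, 0.40, 0.8
        n = sample_size_two_proportions(p1, p2, power=target)["n_per_group"]
        rng = np.random.default_rng(99)
        hits = 0
        trials = 2000
        for _ in range(trials):
            x1 = rng.binomial(n, p1)
            x2 = rng.binomial(n, p2)
            ph1, ph2 = x1 / n, x2 / n
            pbar = (x1 + x2) / (2 * n)
            se = math.sqrt(2 * pbar * (1 - pbar) / n)
            if se == 0:
                continue
            z = abs(ph1 - ph2) / se
            hits += z > sps.norm.ppf(1 - 0.05 / 2)
        assert hits / trials >= target - 0.03


class TestCohortAccounting:
    def test_attrition_arithmetic(self):
        assert analytic_sample_size(83, [8, 11]) == 64

    def test_over_exclusion_rejected(self):
        with pytest.raises(InputError):
            analytic_sample_size(10, [8, 5])

    def test_printed_percentages(self):
        assert proportion_pct(13, 57) == 22.8
        assert proportion_pct(24, 57) == 42.1
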