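import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from richclubkit import reference
from richclubkit.stats import (
    anova_from_summary,
    chi_squared_independence,
    classify_ctq,
    fdr_correct,
    partial_correlation,
    permutation_test,
    tukey_hsd_from_summary,
    two_sample_t_from_summary,
    validate_cohort,
)


def rescale_to_summary(raw, mean, sd):
    """Affine transform giving a sample with exactly the requested mean/SD."""
    raw = np.asarray(raw, dtype=float)
    z = (raw - raw.mean()) / raw.std(ddof=1)
    return mean + sd * z


class TestCTQClassification:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ({"EA": 13, "PA": 5, "SA": 5, "EN": 5, "PN": 5}, "CM"),  # inclusive boundary
            ({"EA": 12, "PA": 9, "SA": 7, "EN": 14, "PN": 9}, "nCM"),  # all strictly below
            ({"EA": 5, "PA": 5, "SA": 5, "EN": 5, "PN": 5}, "nCM"),
            ({"EA": 5, "PA": 5, "SA": 8, "EN": 5, "PN": 5}, "CM"),  # any one subscale suffices
        ],
    )
    def test_cutoff_rule(self, scores, expected):
        assert classify_ctq(scores) == expected

    def test_missing_subscale_raises(self):
        with pytest.raises(ValueError, match="missing"):
            classify_ctq({"EA": 10, "PA": 10, "SA": 10, "EN": 10})


class TestPermutation:
    def test_identical_samples_p_is_one(self):
        res = permutation_test([3, 3, 3], [3, 3, 3], n_perm=200, seed=0)
        assert res.p_value == 1.0

    def test_perfect_separation_matches_exhaustive_enumeration(self):
        from itertools import combinations

        a, b = [0.0] * 5, [10.0] * 5
        pooled = a + b
        observed = abs(np.mean(a) - np.mean(b))
        hits = sum(
            1
            for idx in combinations(range(10), 5)
            if abs(
                np.mean([pooled[i] for i in idx])
                - np.mean([pooled[i] for i in range(10) if i not in idx])
            )
            >= observed
        )
        exact = hits / 252  # the 2 extreme splits
        assert exact == pytest.approx(2 / 252)
        res = permutation_test(a, b, n_perm=10000, seed=1)
        assert res.observed_diff == -10
        # sampled estimator agrees with enumeration within ~4 binomial SDs
        assert abs(res.p_value - exact) < 0.004

    def test_add_one_estimator_floor(self):
        res = permutation_test([0.0, 0.1], [5.0, 5.1], n_perm=99, seed=2)
        assert res.p_value >= 1 / 100

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(size=15)
        r1 = permutation_test(a, b, 500, seed=9)
        r2 = permutation_test(a, b, 500, seed=9)
        assert r1.p_value == r2.p_value

    def test_custom_statistic_matches_default(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=10)
        stat = lambda x, y: abs(float(np.mean(x)) - float(np.mean(y)))
        r_default = permutation_test(a, b, 300, seed=5)
        r_custom = permutation_test(a, b, 300, seed=5, statistic=stat)
        # same seed, same statistic family: identical p up to code path
        assert abs(r_default.p_value - r_custom.p_value) < 0.05

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            permutation_test([], [1.0], 10, seed=0)

    def test_null_calibration(self):
        """Type-I error of the permutation test within [0.03, 0.07] at alpha=0.05."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for i in range(n_rep):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            res = permutation_test(a, b, n_perm=199, seed=int(rng.integers(2**31)))
            if res.p_value <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_p_values_superuniform_under_null(self):
        rng = np.random.default_rng(77)
        pvals = []
        for i in range(400):
            a, b = rng.normal(size=15), rng.normal(size=15)
            pvals.append(permutation_test(a, b, n_perm=199, seed=i).p_value)
        grid = np.linspace(0.01, 0.99, 50)
        emp = np.array([(np.asarray(pvals) <= g).mean() for g in grid])
        assert np.abs(emp - grid).max() <= 0.08


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.04])[0] == pytest.approx(0.04)

    def test_worked_example(self):
        # BH: p*m/rank with step-up monotonicity -> all 0.03
        assert fdr_correct([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_unchanged(self):
        assert fdr_correct([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_never_decreases_never_exceeds_one(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        adj = fdr_correct(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            fdr_correct([0.5, 1.2])


class TestPartialCorrelation:
    def test_constant_covariate_equals_plain_pearson(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, _ = partial_correlation(x, y, np.ones((30, 1)) * 5)
        assert r == pytest.approx(sps.pearsonr(x, y)[0])

    def test_y_equal_to_covariate_gives_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        cov = rng.normal(size=(40, 1))
        r, _ = partial_correlation(x, cov[:, 0], cov)
        assert abs(r) < 1e-10

    def test_precision_matrix_oracle(self):
        """r matches the partial correlation from the inverted correlation matrix."""
        rng = np.random.default_rng(8)
        cov = rng.normal(size=(50, 3))
        x = cov @ [1.0, -0.5, 0.2] + rng.normal(size=50)
        y = cov @ [0.3, 0.8, -1.0] + 0.5 * x + rng.normal(size=50)
        r, _ = partial_correlation(x, y, cov)
        corr = np.corrcoef(np.column_stack([x, y, cov]), rowvar=False)
        prec = np.linalg.inv(corr)
        expected = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(expected, abs=1e-10)

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(
            {
                "x": rng.normal(size=60),
                "y": rng.normal(size=60),
                "c1": rng.normal(size=60),
                "c2": rng.normal(size=60),
            }
        )
        frame["y"] += 0.4 * frame["x"] + 0.3 * frame["c1"]
        r, p = partial_correlation(frame["x"], frame["y"], frame[["c1", "c2"]])
        ref = pingouin.partial_corr(frame, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_affine_covariate_invariance(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=35), rng.normal(size=35)
        cov = rng.normal(size=(35, 2))
        r1, _ = partial_correlation(x, y, cov)
        r2, _ = partial_correlation(x, y, cov * 7.5 - 3.0)
        assert r1 == pytest.approx(r2)

    def test_collinear_covariate_named(self):
        rng = np.random.default_rng(11)
        c = rng.normal(size=20)
        cov = pd.DataFrame({"age": c, "age_copy": 2 * c})
        with pytest.raises(ValueError, match="age_copy"):
            partial_correlation(rng.normal(size=20), rng.normal(size=20), cov)


class TestSummaryReconstruction:
    def test_anova_identical_groups_zero(self):
        f, p = anova_from_summary([5, 5, 5], [1, 1, 1], [10, 10, 10])
        assert f == 0
        assert p == 1

    def test_anova_matches_raw_data_oracle(self):
        rng = np.random.default_rng(12)
        means, sds, ns = [3.0, 4.5, 2.0], [1.0, 2.0, 1.5], [12, 9, 15]
        groups = [
            rescale_to_summary(rng.normal(size=n), m, s)
            for m, s, n in zip(means, sds, ns)
        ]
        f_raw, p_raw = sps.f_oneway(*groups)
        f, p = anova_from_summary(means, sds, ns)
        assert f == pytest.approx(f_raw)
        assert p == pytest.approx(p_raw)

    def test_anova_shift_invariance(self):
        f1, _ = anova_from_summary([1, 2, 3], [1, 1, 1], [8, 8, 8])
        f2, _ = anova_from_summary([11, 12, 13], [1, 1, 1], [8, 8, 8])
        assert f1 == pytest.approx(f2)

    def test_anova_joint_scale_invariance(self):
        f1, _ = anova_from_summary([1, 2, 3], [1, 2, 1.5], [8, 8, 8])
        f2, _ = anova_from_summary([3, 6, 9], [3, 6, 4.5], [8, 8, 8])
        assert f1 == pytest.approx(f2)

    def test_small_n_raises(self):
        with pytest.raises(ValueError, match="n >= 2"):
            anova_from_summary([1, 2], [1, 1], [5, 1])

    def test_t_equal_means_zero(self):
        t, p = two_sample_t_from_summary(4, 1, 10, 4, 2, 12)
        assert t == 0

    def test_t_matches_raw_data_oracle(self):
        rng = np.random.default_rng(13)
        a = rescale_to_summary(rng.normal(size=14), 3.2, 1.1)
        b = rescale_to_summary(rng.normal(size=11), 2.4, 0.9)
        t_raw, p_raw = sps.ttest_ind(a, b)
        t, p = two_sample_t_from_summary(3.2, 1.1, 14, 2.4, 0.9, 11)
        assert t == pytest.approx(t_raw)
        assert p == pytest.approx(p_raw)

    def test_t_zero_variance_sentinel(self):
        t, p = two_sample_t_from_summary(3, 0, 5, 4, 0, 5)
        assert np.isinf(t) and t < 0
        assert p == 0

    def test_chi2_hand_expansion(self):
        # expected cell count 15 everywhere; 4 cells of (obs-15)^2/15 = 25/15
        chi2, _ = chi_squared_independence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(100 / 15)

    def test_chi2_identical_proportions_zero(self):
        chi2, _ = chi_squared_independence([[10, 20, 40], [5, 10, 20]])
        assert chi2 == pytest.approx(0)

    def test_chi2_zero_marginal_raises(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared_independence([[0, 5], [0, 7]])

    def test_tukey_identical_groups_p_near_one(self):
        hsd = tukey_hsd_from_summary([5, 5, 5], [1, 1, 1], [10, 10, 10])
        assert (hsd["p_adj"] > 0.999).all()

    def test_tukey_outlying_group_smallest_p(self):
        hsd = tukey_hsd_from_summary(
            [5, 5.1, 20], [1, 1, 1], [10, 10, 10], ["a", "b", "c"]
        )
        involving_c = hsd[(hsd.group_a == "c") | (hsd.group_b == "c")]
        others = hsd[(hsd.group_a != "c") & (hsd.group_b != "c")]
        assert involving_c["p_adj"].max() < others["p_adj"].min()

    def test_tukey_matches_scipy_raw_oracle(self):
        rng = np.random.default_rng(14)
        means, sds, ns = [3.0, 4.0, 5.5, 2.5], [1.2, 0.8, 1.5, 1.0], [12, 15, 9, 11]
        groups = [
            rescale_to_summary(rng.normal(size=n), m, s)
            for m, s, n in zip(means, sds, ns)
        ]
        ref = sps.tukey_hsd(*groups)
        hsd = tukey_hsd_from_summary(means, sds, ns)
        for row in hsd.itertuples():
            i = int(row.group_a[1:])
            j = int(row.group_b[1:])
            assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-8)


class TestCohortValidation:
    def _table(self):
        return pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "diagnosis": ["MDD", "HC"],
                "age": [25, 30],
                "sex": ["F", "M"],
                "education": [15, 16],
                "HAMD": [30, np.nan],
                "HAMA": [20, np.nan],
                "CTQ": [60, 27],
                "EA": [14, 5],
                "PA": [10, 6],
                "SA": [8, 5],
                "EN": [16, 6],
                "PN": [12, 5],
            }
        )

    def test_groups_derived_from_ctq(self):
        out = validate_cohort(self._table())
        assert out["group"].tolist() == ["MDD-CM", "HC-nCM"]

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="missing"):
            validate_cohort(self._table().drop(columns=["EN"]))

    def test_subscale_floor_enforced(self):
        bad = self._table()
        bad.loc[0, "PA"] = 3
        with pytest.raises(ValueError, match="below 5"):
            validate_cohort(bad)


class TestReferenceSummaries:
    """The published four-group cohort summaries reconstruct their printed statistics."""

    def test_sex_chi_squared(self):
        chi2, _ = chi_squared_independence(reference.sex_contingency().to_numpy())
        assert chi2 == pytest.approx(7.019, rel=0.005)

    @pytest.mark.parametrize(
        "variable,printed_f",
        [
            ("age", 0.867),
            ("education", 0.865),
            ("CTQ", 110.614),
            ("EA", 47.090),
            ("PA", 18.042),
            ("SA", 10.350),
            ("EN", 91.680),
            ("PN", 73.956),
        ],
    )
    def test_anova_rows(self, variable, printed_f):
        per_group = reference.SUMMARY[variable]
        means = [per_group[g][0] for g in reference.GROUPS]
        sds = [per_group[g][1] for g in reference.GROUPS]
        ns = [reference.GROUP_SIZES[g] for g in reference.GROUPS]
        f, _ = anova_from_summary(means, sds, ns)
        assert f == pytest.approx(printed_f, rel=0.02)

    @pytest.mark.parametrize("scale,printed_t", [("HAMD", 2.417), ("HAMA", 2.382)])
    def test_patient_t_rows(self, scale, printed_t):
        (m1, s1), (m2, s2) = (
            reference.SUMMARY[scale]["MDD-CM"],
            reference.SUMMARY[scale]["MDD-nCM"],
        )
        t, _ = two_sample_t_from_summary(
            m1, s1, reference.GROUP_SIZES["MDD-CM"], m2, s2, reference.GROUP_SIZES["MDD-nCM"]
        )
        assert t == pytest.approx(printed_t, rel=0.01)
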