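"""Group statistics: normalization, Grubbs, ANOVA/Tukey, chi-squared."""

import numpy as np
import pytest
from scipy import stats as sst

from blastmea import (
    chi_squared_counts,
    grubbs_exclude,
    one_way_anova_tukey,
    percent_difference,
    percent_of_control,
    summarize_group,
    two_sample_ttest,
)
from blastmea.stats import grubbs_critical_value


class TestPercentNormalization:
    def test_control_mean_maps_to_100(self):
        out = percent_of_control(np.array([20.0]), np.array([10.0, 30.0]))
        assert out[0] == pytest.approx(100.0)

    def test_arithmetic(self):
        out = percent_of_control(np.array([5.0]), np.array([10.0, 30.0]))
        assert out[0] == pytest.approx(25.0)

    def test_normalized_controls_average_100(self, rng):
        control = rng.uniform(1, 10, size=12)
        assert percent_of_control(control, control).mean() == pytest.approx(100.0)

    def test_zero_control_redirected(self):
        with pytest.raises(ValueError, match="chi_squared"):
            percent_of_control(np.array([1.0]), np.array([0.0]))

    def test_percent_difference_identity_and_arithmetic(self):
        assert percent_difference(np.array([4.0]), 4.0).values[0] == 0.0
        assert percent_difference(np.array([6.0]), 4.0).values[0] == pytest.approx(50.0)

    def test_zero_baseline_flags_chi_squared_route(self):
        with pytest.warns(UserWarning, match="chi-squared"):
            out = percent_difference(np.array([3.0, 0.0]), 0.0)
        assert out.use_chi_squared
        assert out.mode == "absolute_difference"
        np.testing.assert_allclose(out.values, [3.0, 0.0])


class TestGrubbs:
    def test_gross_outlier_excluded_once(self):
        retained, excluded = grubbs_exclude(np.array([1.0, 2, 3, 4, 100.0]))
        assert excluded == [4]
        np.testing.assert_allclose(retained, [1, 2, 3, 4])

    def test_clean_data_untouched(self):
        retained, excluded = grubbs_exclude(np.array([1.0, 2, 3, 4, 5]))
        assert excluded == []
        assert retained.size == 5

    def test_constant_vector_no_op(self):
        retained, excluded = grubbs_exclude(np.full(6, 3.0))
        assert excluded == []

    def test_too_few_values_warns(self):
        with pytest.warns(UserWarning, match="n >= 3"):
            retained, excluded = grubbs_exclude(np.array([1.0, 2.0]))
        assert excluded == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_g_statistic_oracle(self, seed):
        # brute-force: recompute G and the critical value by hand each round
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, size=10)
        if seed % 2:
            values[0] = 8.0  # plant an outlier half the time
        retained, excluded = grubbs_exclude(values, alpha=0.05)
        work = values.copy()
        expected_excluded = []
        while work.size >= 3 and work.std(ddof=1) > 0:
            g = np.max(np.abs(work - work.mean())) / work.std(ddof=1)
            n = work.size
            t = sst.t.ppf(1 - 0.05 / (2 * n), n - 2)
            crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
            if g <= crit:
                break
            drop = int(np.argmax(np.abs(work - work.mean())))
            orig_idx = [i for i in range(values.size) if i not in expected_excluded]
            expected_excluded.append(orig_idx[drop])
            work = np.delete(work, drop)
        assert excluded == expected_excluded
        np.testing.assert_allclose(np.sort(retained), np.sort(work))

    def test_false_positive_rate_near_alpha_under_null(self):
        # iid normal n=12: an exclusion should happen in roughly alpha of
        # datasets, certainly not far above it
        rng = np.random.default_rng(123)
        n_excluded = sum(
            bool(grubbs_exclude(rng.normal(0, 1, size=12))[1])
            for _ in range(2000)
        )
        assert n_excluded / 2000 < 0.10

    def test_critical_value_reference(self):
        # published two-sided Grubbs critical value for n=10, alpha=0.05
        assert grubbs_critical_value(10, 0.05) == pytest.approx(2.29, abs=0.01)


class TestAnovaTukey:
    def test_identical_groups_f_zero_p_one(self):
        report = one_way_anova_tukey([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert report.statistic == 0.0
        assert report.p_value == 1.0
        assert report.df == (1.0, 4.0)

    def test_f_matches_hand_computed_sums_of_squares(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([10.0, 11, 12])]
        report = one_way_anova_tukey(groups, labels=["a", "b", "c"])
        allv = np.concatenate(groups)
        ss_between = sum(g.size * (g.mean() - allv.mean()) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_expected = (ss_between / 2) / (ss_within / 6)
        assert report.statistic == pytest.approx(f_expected)
        # Tukey flags only pairs involving the distant third group
        flagged = {row["pair"] for row in report.tukey if row["p_adj"] < 0.05}
        assert flagged == {("a", "c"), ("b", "c")}

    def test_scale_invariance(self, rng):
        groups = [rng.normal(0, 1, 8), rng.normal(1, 1, 8), rng.normal(2, 1, 8)]
        r1 = one_way_anova_tukey(groups)
        r2 = one_way_anova_tukey([10.0 * g for g in groups])
        assert r2.statistic == pytest.approx(r1.statistic)
        for row1, row2 in zip(r1.tukey, r2.tukey):
            assert row2["p_adj"] == pytest.approx(row1["p_adj"], abs=1e-9)

    def test_undersized_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="tiny"):
            one_way_anova_tukey(
                [np.array([1.0, 2]), np.array([3.0])], labels=["ok", "tiny"]
            )

    def test_tukey_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 300
        for _ in range(reps):
            groups = [rng.normal(0, 1, size=12) for _ in range(4)]
            report = one_way_anova_tukey(groups)
            rejections += any(row["p_adj"] < 0.05 for row in report.tukey)
        rate = rejections / reps
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)


class TestTTest:
    def test_student_and_welch_agree_for_equal_variance(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        student = two_sample_ttest(a, b)
        welch = two_sample_ttest(a, b, welch=True)
        assert student.test == "student_ttest"
        assert student.df == 22.0
        assert welch.p_value == pytest.approx(student.p_value, rel=0.2)


class TestChiSquared:
    def test_identical_columns_give_zero(self):
        report = chi_squared_counts(np.array([[5, 5, 5], [3, 3, 3]]))
        assert report.statistic == pytest.approx(0.0)
        assert report.p_value == pytest.approx(1.0)

    def test_2x2_matches_brute_force_margins(self):
        table = np.array([[10, 0], [5, 5]])
        report = chi_squared_counts(table)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        brute = ((table - expected) ** 2 / expected).sum()
        assert report.statistic == pytest.approx(brute)
        assert report.df == 1.0

    def test_2x8_layout_has_df_7(self):
        rng = np.random.default_rng(0)
        table = rng.integers(1, 10, size=(2, 8))
        assert chi_squared_counts(table).df == 7.0

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="expected count"):
            chi_squared_counts(np.array([[0, 0], [1, 2]]))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            chi_squared_counts(np.array([[1.5, 2.0], [1.0, 2.0]]))


class TestSummarizeGroup:
    def test_mean_sem_over_retained_values(self):
        values = np.array([10.0, 12.0, 11.0, 13.0, 100.0])  # Grubbs drops 100
        result = summarize_group("g", values)
        assert result.excluded_indices == [4]
        assert result.n == 4
        retained = values[:4]
        assert result.mean == pytest.approx(retained.mean())
        assert result.sem == pytest.approx(retained.std(ddof=1) / 2.0)

    def test_percent_of_control_normalization(self):
        control = np.array([10.0, 10.0, 10.0])
        result = summarize_group("g", np.array([5.0, 15.0, 10.0]), control)
        assert result.mean == pytest.approx(100.0)
        np.testing.assert_allclose(result.normalized_values, [50.0, 150.0, 100.0])
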