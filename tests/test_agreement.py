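"""Agreement statistics against brute-force and reference-library oracles."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinemetry.agreement import (
    GroupSummary,
    agreement_report,
    bland_altman,
    classify_strength,
    format_p,
    icc_2_1,
    linreg_adjusted_r2,
    mdc_from_sem,
    n_for_pearson,
    pearson_r,
    pearson_test,
    rmse_pairs,
    sem_from_icc,
    ttest_unpaired,
)
from spinemetry.errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedStatisticError,
)


def brute_force_icc_2_1(m1, m2):
    """Independent oracle: explicit double-loop two-way ANOVA mean squares."""
    y = [[float(a), float(b)] for a, b in zip(m1, m2)]
    n, k = len(y), 2
    grand = sum(sum(row) for row in y) / (n * k)
    row_means = [sum(row) / k for row in y]
    col_means = [sum(y[i][j] for i in range(n)) / n for j in range(k)]
    ms_rows = k * sum((rm - grand) ** 2 for rm in row_means) / (n - 1)
    ms_cols = n * sum((cm - grand) ** 2 for cm in col_means) / (k - 1)
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (y[i][j] - row_means[i] - col_means[j] + grand) ** 2
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


class TestIcc:
    def test_perfect_agreement_is_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        icc, ci = icc_2_1(x, x)
        assert icc == pytest.approx(1.0, abs=1e-12)
        assert ci == (1.0, 1.0)

    def test_hand_built_table_matches_bruteforce(self):
        m1 = [10.0, 12.5, 9.0, 15.0, 11.0]
        m2 = [11.0, 12.0, 9.5, 14.0, 12.5]
        icc, _ = icc_2_1(m1, m2)
        assert icc == pytest.approx(brute_force_icc_2_1(m1, m2), abs=1e-10)

    @given(seed=st.integers(0, 200))
    def test_random_tables_match_bruteforce(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 13))
        m1 = r.normal(50, 15, n)
        m2 = m1 + r.normal(0, 5, n)
        icc, _ = icc_2_1(m1, m2)
        assert icc == pytest.approx(brute_force_icc_2_1(m1, m2), abs=1e-10)

    def test_independent_methods_icc_near_zero(self, rng):
        m1 = rng.normal(0, 1, 500)
        m2 = rng.normal(0, 1, 500)
        icc, _ = icc_2_1(m1, m2)
        assert abs(icc) < 0.15

    @given(shift=st.floats(-100, 100), scale=st.floats(0.1, 50))
    def test_invariant_under_common_shift_and_scale(self, shift, scale):
        r = np.random.default_rng(7)
        m1 = r.normal(40, 10, 12)
        m2 = m1 + r.normal(0, 3, 12)
        base, _ = icc_2_1(m1, m2)
        moved, _ = icc_2_1(scale * (m1 + shift), scale * (m2 + shift))
        assert moved == pytest.approx(base, abs=1e-8)

    def test_matches_reference_library_point_and_ci(self):
        import pandas as pd
        import pingouin as pg

        r = np.random.default_rng(11)
        m1 = r.normal(60, 20, 15)
        m2 = m1 + r.normal(2, 6, 15)
        icc, (lo, hi) = icc_2_1(m1, m2)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(15), 2),
            "raters": np.tile(["A", "B"], 15),
            "ratings": np.column_stack([m1, m2]).ravel(),
        })
        ref = pg.intraclass_corr(df, "targets", "raters", "ratings")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        row = ref[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        # the reference library reports the CI rounded to 2 decimals
        assert lo == pytest.approx(row[ci_col][0], abs=6e-3)
        assert hi == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_identical_constant_values_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            icc_2_1([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            icc_2_1([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_methods(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_pure_offset(self):
        x = [10.0, 20.0, 30.0]
        bias, lo, hi = bland_altman([v + 5.0 for v in x], x)
        assert bias == pytest.approx(5.0, abs=1e-12)
        assert lo == pytest.approx(5.0, abs=1e-9) and hi == pytest.approx(5.0, abs=1e-9)

    def test_limits_use_sample_sd(self, rng):
        d = rng.normal(0, 2.0, 50)
        bias, lo, hi = bland_altman(d, np.zeros(50))
        sd = d.std(ddof=1)
        assert lo == pytest.approx(d.mean() - 1.96 * sd, abs=1e-12)
        assert hi == pytest.approx(d.mean() + 1.96 * sd, abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(InvalidInputError):
            bland_altman([1.0], [2.0])


class TestRmseSemMdc:
    def test_rmse_trivial_cases(self):
        assert rmse_pairs([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse_pairs([4.0, 5.0, 6.0], [1.0, 2.0, 3.0]) == pytest.approx(3.0)

    @given(seed=st.integers(0, 50))
    def test_rmse_equals_explicit_loop(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(0, 5, 20), r.normal(0, 5, 20)
        acc = sum((x - y) ** 2 for x, y in zip(a, b)) / 20
        assert rmse_pairs(a, b) == pytest.approx(math.sqrt(acc), abs=1e-12)

    def test_sem_formula(self):
        assert sem_from_icc(2.0, 0.75) == pytest.approx(1.0, abs=1e-12)
        assert sem_from_icc(5.0, 1.0) == 0.0

    @given(sd=st.floats(0, 50), icc=st.floats(0, 1))
    def test_sem_matches_direct_formula(self, sd, icc):
        assert sem_from_icc(sd, icc) == pytest.approx(sd * math.sqrt(1 - icc), abs=1e-9)

    def test_mdc_formula_and_bounds(self):
        assert mdc_from_sem(0.0) == 0.0
        assert mdc_from_sem(1.0) == pytest.approx(1.96 * math.sqrt(2.0), abs=1e-12)
        with pytest.raises(InvalidParameterError):
            mdc_from_sem(-1.0)
        with pytest.raises(InvalidParameterError):
            sem_from_icc(2.0, 1.5)


class TestPearson:
    def test_exact_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_table_matches_covariance_loop(self):
        x = [2.0, 4.0, 5.0, 7.0, 9.0, 10.0]
        y = [3.0, 3.5, 6.0, 6.5, 8.0, 11.0]
        mx, my = sum(x) / 6, sum(y) / 6
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sx = math.sqrt(sum((a - mx) ** 2 for a in x))
        sy = math.sqrt(sum((b - my) ** 2 for b in y))
        assert pearson_r(x, y) == pytest.approx(cov / (sx * sy), abs=1e-12)

    def test_p_value_matches_scipy(self, rng):
        from scipy import stats

        x = rng.normal(0, 1, 25)
        y = 0.5 * x + rng.normal(0, 1, 25)
        r, p = pearson_test(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTTest:
    def test_equal_means_give_t_zero_p_one(self):
        res = ttest_unpaired(GroupSummary(10, 5.0, 2.0), GroupSummary(10, 5.0, 2.0))
        assert res.t == 0.0 and res.p == 1.0

    def test_raw_values_equal_their_summaries(self, rng):
        a = rng.normal(10, 3, 18)
        b = rng.normal(12, 4, 22)
        for variant in ("pooled", "welch"):
            raw = ttest_unpaired(a, b, variant)
            summ = ttest_unpaired(
                GroupSummary.from_values(a), GroupSummary.from_values(b), variant
            )
            assert raw.t == pytest.approx(summ.t, abs=1e-12)
            assert raw.p == pytest.approx(summ.p, abs=1e-12)
            assert raw.df == pytest.approx(summ.df, abs=1e-12)

    def test_matches_scipy_both_variants(self, rng):
        from scipy import stats

        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 2, 20)
        pooled = ttest_unpaired(a, b, "pooled")
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert pooled.t == pytest.approx(ref.statistic, abs=1e-10)
        assert pooled.p == pytest.approx(ref.pvalue, abs=1e-10)
        welch = ttest_unpaired(a, b, "welch")
        ref_w = stats.ttest_ind(a, b, equal_var=False)
        assert welch.t == pytest.approx(ref_w.statistic, abs=1e-10)
        assert welch.p == pytest.approx(ref_w.pvalue, abs=1e-10)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ttest_unpaired(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))


class TestRegression:
    def test_exact_line_gives_adjusted_one(self):
        x = np.arange(10.0)
        fit = linreg_adjusted_r2(x, 3.0 * x - 2.0)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(3.0) and fit.intercept == pytest.approx(-2.0)

    def test_r2_equals_r_squared_for_simple_regression(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.7 * x + rng.normal(0, 1, 40)
        fit = linreg_adjusted_r2(x, y)
        assert fit.r2 == pytest.approx(pearson_r(x, y) ** 2, abs=1e-12)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm_api

        x = rng.normal(0, 2, 30)
        y = 1.5 * x + rng.normal(0, 3, 30)
        fit = linreg_adjusted_r2(x, y)
        ref = sm_api.OLS(y, sm_api.add_constant(x)).fit()
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)

    def test_independent_data_adjusted_near_zero(self, rng):
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0, 1, 2000)
        assert abs(linreg_adjusted_r2(x, y).adj_r2) < 0.01

    def test_constant_x_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            linreg_adjusted_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPowerSampleSize:
    def test_smallest_n_satisfies_inequality_and_predecessor_does_not(self):
        # direct evaluation oracle for r = 0.5
        from scipy import stats

        r, alpha, power = 0.5, 0.05, 0.80
        n = n_for_pearson(r, alpha, power)
        z_req = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
        lhs = lambda m: math.sqrt(m - 3) * (math.atanh(r) + r / (2 * (m - 1)))
        assert lhs(n) >= z_req
        assert lhs(n - 1) < z_req

    def test_trivial_power_returns_minimum_supported_n(self):
        assert n_for_pearson(0.99, alpha=0.5, power=0.05) == 4

    def test_invalid_queries_rejected(self):
        for kwargs in (
            {"target_r": 0.0},
            {"target_r": 1.0},
            {"target_r": 0.5, "alpha": 0.0},
            {"target_r": 0.5, "power": 1.0},
        ):
            with pytest.raises(InvalidParameterError):
                n_for_pearson(**kwargs)


class TestClassification:
    @pytest.mark.parametrize(
        "value,kind,label",
        [
            (0.95, "icc", "excellent"),
            (0.8, "icc", "good"),       # documented closed upper bound
            (0.6, "icc", "good"),
            (0.59, "icc", "poor"),
            (0.5, "r", "weak to moderate"),
            (-0.5, "r", "weak to moderate"),
            (0.7, "r", "weak to moderate"),
            (0.71, "r", "good"),
            (0.1, "r", "negligible"),
        ],
    )
    def test_threshold_labels(self, value, kind, label):
        assert classify_strength(value, kind) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_strength(1.2, "icc")

    def test_p_value_formatting(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.038) == "0.038"
        assert format_p(0.0006) == "0.001"


class TestAgreementReportPanel:
    def test_internal_consistency(self, rng):
        m1 = rng.normal(60, 15, 20)
        m2 = m1 + rng.normal(1, 4, 20)
        rep = agreement_report(m1, m2, "demo", "deg")
        assert rep.loa_lower <= rep.bias <= rep.loa_upper
        assert rep.mdc >= rep.sem >= 0
        assert -1 <= rep.r <= 1
        assert rep.icc == pytest.approx(brute_force_icc_2_1(m1, m2), abs=1e-10)
        assert rep.sem == pytest.approx(
            math.sqrt((m1.std(ddof=1) ** 2 + m2.std(ddof=1) ** 2) / 2)
            * math.sqrt(1 - min(max(rep.icc, 0), 1)),
            abs=1e-10,
        )
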