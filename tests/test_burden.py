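"""Burden regression, slope Z-test, variance F-test, Wilcoxon and Shapiro."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutaccum.burden import (
    BurdenRegression,
    RegressionFit,
    context_load_tests,
    fit_burden_regression,
    normality_check,
    slope_z_test,
    variance_f_test,
)
from mutaccum.io import CloneMeta
from mutaccum.simulate import SimConfig, simulate_cohort


def make_fit(m=46.0, se=2.0, var=900.0, n_clones=14, n_patients=7, group="g"):
    return RegressionFit(group, m, se, 1.96 * se, var, n_clones, n_patients)


class TestRegression:
    def test_noiseless_line_recovered_exactly(self):
        cfg = SimConfig(
            patient_sd={"SBS": 0.0, "INDEL": 0.0, "DBS": 0.0, "SV": 0.0},
            count_noise="none", seed=5,
        )
        truth = simulate_cohort(cfg)
        fit = fit_burden_regression(truth.class_counts("SBS"), truth.meta)
        assert fit.m == pytest.approx(46.0, abs=1e-6)

    def test_all_zero_counts_flagged(self):
        meta = [CloneMeta(f"c{i}", f"p{i}", 40.0, "g") for i in range(4)]
        fit = fit_burden_regression({m.clone_id: 0.0 for m in meta}, meta)
        assert fit.all_zero and fit.m == 0.0

    def test_single_patient_falls_back_to_ols(self):
        meta = [CloneMeta(f"c{i}", "p1", 50.0, "g") for i in range(3)]
        counts = {"c0": 2290.0, "c1": 2310.0, "c2": 2300.0}
        fit = fit_burden_regression(counts, meta)
        assert fit.method == "ols"
        assert fit.m == pytest.approx(2300.0 / 50.0, rel=1e-6)

    def test_prediction_at_birth_is_zero(self):
        # zero-intercept contract: fitted burden is m*age, so age=0 -> 0
        cfg = SimConfig(seed=2)
        truth = simulate_cohort(cfg)
        fit = fit_burden_regression(truth.class_counts("SBS"), truth.meta)
        assert fit.m * 0.0 == 0.0
        assert fit.se > 0 and fit.ci95 > 0

    def test_group_filter_and_min_clones(self):
        meta = [CloneMeta("c1", "p1", 40.0, "g")]
        with pytest.raises(ValueError, match="at least 2"):
            BurdenRegression({"c1": 100.0}, meta)

    def test_from_dataframe(self):
        df = pd.DataFrame({
            "clone_id": ["a", "b", "c", "d"],
            "patient_id": ["p1", "p1", "p2", "p2"],
            "age": [30.0, 30.0, 60.0, 60.0],
            "group": ["g"] * 4,
            "count": [1400.0, 1360.0, 2700.0, 2760.0],
        })
        fit = BurdenRegression.from_dataframe(df, group="g").fit()
        assert fit.m == pytest.approx(46, rel=0.05)


class TestSlopeZTest:
    def test_equal_slopes_give_zero_and_one(self):
        z, p = slope_z_test(make_fit(), make_fit())
        assert (z, p) == (0.0, 1.0)

    def test_unit_z_closed_form(self):
        # m1 - m2 == sqrt(SE1^2 + SE2^2)  ->  Z = 1, p = 2*Phi(-1)
        a = make_fit(m=46.0 + np.sqrt(8.0), se=2.0)
        b = make_fit(m=46.0, se=2.0)
        z, p = slope_z_test(a, b)
        assert z == pytest.approx(1.0)
        assert p == pytest.approx(0.3173105078629141, abs=1e-12)

    def test_antisymmetry(self):
        a, b = make_fit(m=50.0), make_fit(m=46.0)
        z_ab, p_ab = slope_z_test(a, b)
        z_ba, p_ba = slope_z_test(b, a)
        assert z_ab == -z_ba and p_ab == p_ba

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            slope_z_test(make_fit(se=0.0), make_fit(se=0.0))

    def test_strict_minus_mode_matches_printed_form(self):
        a, b = make_fit(m=50.0, se=3.0), make_fit(m=46.0, se=1.0)
        z, _ = slope_z_test(a, b, strict_minus=True)
        assert z == pytest.approx(4.0 / np.sqrt(9.0 - 1.0))
        with pytest.raises(ValueError):
            slope_z_test(b, a, strict_minus=True)  # imaginary denominator


class TestVarianceFTest:
    def test_equal_variances_give_unit_f(self):
        f, p, _ = variance_f_test(make_fit(), make_fit())
        assert f == 1.0

    def test_ratio_four_df_twelve(self):
        a = make_fit(var=4000.0, n_clones=13)
        b = make_fit(var=1000.0, n_clones=13)
        f, p, df = variance_f_test(a, b)
        assert f == pytest.approx(4.0)
        assert df == (12, 12)
        assert p == pytest.approx(0.0116542054, abs=1e-8)

    def test_smaller_disease_variance_gives_p_above_half(self):
        f, p, _ = variance_f_test(make_fit(var=500.0), make_fit(var=1000.0))
        assert f < 1 and p > 0.5

    def test_too_few_clones_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test(make_fit(n_clones=1), make_fit())


class TestNormality:
    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(100, 10, size=14)
            res = normality_check({"g": x})
            hits += res.loc[0, "p"] > 0.05
        assert hits >= 90

    def test_exponential_samples_usually_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(10, size=50)
            res = normality_check({"g": x})
            hits += res.loc[0, "p"] < 0.05
        assert hits >= 90

    def test_constant_vector_not_testable(self):
        res = normality_check({"g": [5.0, 5.0, 5.0, 5.0]})
        assert not res.loc[0, "testable"]

    def test_tiny_group_not_testable(self):
        res = normality_check({"g": [1.0, 2.0]})
        assert not res.loc[0, "testable"]


class TestContextLoadTests:
    def _matrix(self, a_cols, b_cols, data):
        cols = a_cols + b_cols
        return (
            pd.DataFrame(data, columns=cols),
            {c: ("A" if c in a_cols else "B") for c in cols},
        )

    def test_identical_groups_give_adjusted_p_one(self):
        data = np.tile([[3, 7, 3, 7]], (5, 1))
        matrix, groups = self._matrix(["a1", "a2"], ["b1", "b2"], data)
        res = context_load_tests(matrix, groups, "A", "B")
        assert (res["p_bonferroni"] == 1.0).all()

    def test_bonferroni_is_family_size_times_raw(self):
        rng = np.random.default_rng(0)
        data = rng.integers(5, 15, size=(10, 12)).astype(float)
        data[3, :6] += 200  # one context strongly shifted in group A
        cols_a = [f"a{i}" for i in range(6)]
        cols_b = [f"b{i}" for i in range(6)]
        matrix, groups = self._matrix(cols_a, cols_b, data)
        res = context_load_tests(matrix, groups, "A", "B")
        family = len(res)
        row = res.iloc[3]
        assert row["p_bonferroni"] == pytest.approx(
            min(1.0, family * row["p_raw"]))
        assert row["p_bonferroni"] < 0.05

    def test_single_category_family_of_one(self):
        matrix, groups = self._matrix(
            ["a1", "a2", "a3"], ["b1", "b2", "b3"],
            [[1.0, 2.0, 3.0, 9.0, 10.0, 11.0]],
        )
        res = context_load_tests(matrix, groups, "A", "B")
        assert res.iloc[0]["p_bonferroni"] == pytest.approx(res.iloc[0]["p_raw"])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(8)
        data = rng.poisson(6, size=(20, 8)).astype(float)
        matrix, groups = self._matrix(
            [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)], data)
        res = context_load_tests(matrix, groups, "A", "B")
        assert (res["p_bonferroni"] >= res["p_raw"] - 1e-12).all()
        assert res["p_bonferroni"].between(0, 1).all()

    def test_all_zero_contexts_excluded_from_family(self):
        data = np.zeros((4, 6))
        data[0] = [1, 2, 3, 7, 8, 9]
        matrix, groups = self._matrix(
            [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)], data)
        res = context_load_tests(matrix, groups, "A", "B")
        assert len(res) == 1

    def test_empty_group_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0]], columns=["a1", "a2"])
        with pytest.raises(ValueError):
            context_load_tests(matrix, {"a1": "A", "a2": "A"}, "A", "B")
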