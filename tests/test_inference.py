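"""Inferential statistics: design construction, weighted least squares
against brute-force and statsmodels oracles, ANOVA, t test, correlation."""

import math

import numpy as np
import pytest

from headconduct import (
    Corpus,
    InsufficientDataError,
    build_design,
    one_way_anova,
    pearson_correlation,
    t_test_two_tailed,
    weight_records,
    weighted_regression,
)
from headconduct.inference import DesignMatrix, benjamini_hochberg, InferenceError
from headconduct.corpus import TissueLabel
from conftest import make_record


def design_from_arrays(y, X, columns, weights):
    return DesignMatrix(
        tissue=TissueLabel.from_name("gm"),
        y=np.asarray(y, float),
        X=np.asarray(X, float),
        columns=list(columns),
        weights=np.asarray(weights, float),
        n_total=len(y),
        n_masked=0,
    )


def brute_force_wls(y, X, w):
    """Independent normal-equations solve: β = (XᵀWX)⁻¹XᵀWy."""
    W = np.diag(w)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


class TestBuildDesign:
    def _corpus(self, n_eit=4, n_dac=4):
        records = []
        for i in range(n_eit):
            records.append(make_record(f"s{i}", "gm", 0.4 + 0.01 * i, method="EIT",
                                       condition="in_vivo", frequency_hz=10.0 + 5 * i,
                                       age_mean_years=25.0 + i))
        for i in range(n_dac):
            records.append(make_record(f"t{i}", "gm", 0.5 + 0.01 * i, method="DAC",
                                       condition="in_vitro", frequency_hz=100.0 + 5 * i,
                                       age_mean_years=10.0 + i))
        corpus = Corpus(records=records)
        qas = {r.study_id: 0.9 for r in records}
        return corpus, weight_records(corpus, qas)

    def test_too_few_records_rejected(self):
        corpus, scores = self._corpus(n_eit=1, n_dac=1)
        with pytest.raises(InsufficientDataError, match="insufficient data"):
            build_design(corpus, scores, "gm", predictors=("method", "condition"))

    def test_reference_coding_counts(self):
        corpus, scores = self._corpus(n_eit=5, n_dac=3)
        design = build_design(corpus, scores, "gm", predictors=("method", "condition"))
        # 2 observed method levels → 1 indicator; same for condition; + const
        assert design.columns == ["const", "method[DAC]", "condition[in_vitro]"]
        assert design.coding["method"]["reference"] == "EIT"  # most frequent

    def test_single_level_predictor_dropped(self):
        corpus, scores = self._corpus()
        design = build_design(
            corpus, scores, "gm",
            predictors=("method", "condition", "temperature_class"),
        )
        assert "temperature_class" in design.dropped_predictors

    def test_masking_counts_missing_covariates(self):
        corpus, scores = self._corpus(n_eit=4, n_dac=4)
        corpus.records[0].frequency_hz = None
        design = build_design(
            corpus, scores, "gm", predictors=("method", "frequency_hz")
        )
        assert design.n_masked == 1
        assert design.n == 7

    def test_age_falls_back_to_class_when_sparse(self):
        corpus, scores = self._corpus(n_eit=4, n_dac=4)
        for rec in corpus.records[:6]:
            rec.age_mean_years = None  # keep class labels, drop numeric age
        design = build_design(corpus, scores, "gm", predictors=("method", "age"))
        assert design.substitutions == {"age": "age_class"}


class TestWeightedRegression:
    def test_brute_force_oracle_small_designs(self, rng):
        """WLS equals an independent normal-equations solve to 1e-8 on
        random designs up to 10×4."""
        for _ in range(30):
            n = int(rng.integers(6, 11))
            p = int(rng.integers(2, 5))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 1.0, size=n)
            design = design_from_arrays(y, X, ["const"] + [f"x{j}" for j in range(p - 1)], w)
            result = weighted_regression(design)
            expected = brute_force_wls(y, X, w)
            assert np.allclose(result.coefficients, expected, atol=1e-8)

    def test_statsmodels_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([0.3, 1.2, -0.7]) + rng.normal(scale=0.5, size=n)
        w = rng.uniform(0.2, 1.0, size=n)
        design = design_from_arrays(y, X, ["const", "x1", "x2"], w)
        ours = weighted_regression(design)
        theirs = sm.WLS(y, X, weights=w).fit()
        assert np.allclose(ours.coefficients, theirs.params, atol=1e-10)
        assert np.allclose(ours.standard_errors, theirs.bse, atol=1e-10)
        assert ours.r_squared == pytest.approx(theirs.rsquared, abs=1e-10)
        assert ours.f_stat == pytest.approx(theirs.fvalue, rel=1e-10)
        assert ours.p_value == pytest.approx(theirs.f_pvalue, abs=1e-12)

    def test_unit_weights_equal_ols(self, rng):
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        d1 = design_from_arrays(y, X, ["const", "a", "b"], np.ones(n))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(weighted_regression(d1).coefficients, beta_ols, atol=1e-10)

    def test_weight_rescaling_leaves_fit_unchanged(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        w = rng.uniform(0.1, 1.0, size=n)
        r1 = weighted_regression(design_from_arrays(y, X, ["const", "x"], w))
        r2 = weighted_regression(design_from_arrays(y, X, ["const", "x"], 7.0 * w))
        assert np.allclose(r1.coefficients, r2.coefficients, atol=1e-12)
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-12)

    def test_noiseless_response_r2_one(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = 2.0 + 3.0 * np.arange(6.0)
        result = weighted_regression(
            design_from_arrays(y, X, ["const", "x"], np.ones(6))
        )
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)
        assert result.p_value == pytest.approx(0.0, abs=1e-12)

    def test_collinear_column_dropped_fit_unchanged(self, rng):
        n = 8
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        Xdup = np.column_stack([np.ones(n), x, x])  # exact duplicate
        y = rng.normal(size=n)
        w = np.ones(n)
        clean = weighted_regression(design_from_arrays(y, X, ["const", "x"], w))
        repaired = weighted_regression(
            design_from_arrays(y, Xdup, ["const", "x", "x_dup"], w)
        )
        assert repaired.dropped_columns == ("x_dup",)
        assert np.allclose(repaired.coefficients, clean.coefficients, atol=1e-10)

    def test_shift_and_scale_of_response_leave_r2_unchanged(self, rng):
        n = 15
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(scale=0.3, size=n)
        w = rng.uniform(0.2, 1.0, size=n)
        base = weighted_regression(design_from_arrays(y, X, ["const", "x"], w)).r_squared
        shifted = weighted_regression(design_from_arrays(y + 10, X, ["const", "x"], w)).r_squared
        scaled = weighted_regression(design_from_arrays(3 * y, X, ["const", "x"], w)).r_squared
        assert shifted == pytest.approx(base, abs=1e-10)
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_zero_residual_df_rejected(self):
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        with pytest.raises(InsufficientDataError):
            weighted_regression(design_from_arrays([1.0, 2.0], X, ["const", "x"], [1, 1]))


class TestANOVA:
    def test_identical_groups(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(loc=0.5, size=6)
        f = one_way_anova([a, b])
        t = t_test_two_tailed(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-10)

    def test_hand_anova_table(self):
        """Groups {1,2,3},{2,3,4},{3,4,5}: SSB=6, SSW=6, F(2,6)=3, p=0.125."""
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0, abs=1e-12)
        assert res.df == (2, 6)
        assert res.p_value == pytest.approx(0.125, abs=1e-6)

    def test_ss_decomposition_conserved(self, rng):
        """Total SS = between SS + within SS to 1e-9 on random inputs."""
        for _ in range(20):
            groups = [rng.normal(loc=rng.normal(), size=int(rng.integers(3, 10)))
                      for _ in range(int(rng.integers(2, 5)))]
            allv = np.concatenate(groups)
            ss_tot = float(((allv - allv.mean()) ** 2).sum())
            ss_w = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
            ss_b = sum(g.size * (g.mean() - allv.mean()) ** 2 for g in groups)
            assert ss_tot == pytest.approx(ss_b + ss_w, abs=1e-9)
            res = one_way_anova(groups)
            k, n = len(groups), allv.size
            assert res.statistic == pytest.approx(
                (ss_b / (k - 1)) / (ss_w / (n - k)), rel=1e-9
            )

    def test_scipy_cross_check(self, rng):
        from scipy import stats as ss

        groups = [rng.normal(size=7), rng.normal(loc=1, size=5), rng.normal(size=6)]
        ours = one_way_anova(groups)
        theirs = ss.f_oneway(*groups)
        assert ours.statistic == pytest.approx(theirs.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(theirs.pvalue, rel=1e-10)

    def test_needs_two_groups(self):
        with pytest.raises(InferenceError):
            one_way_anova([[1, 2, 3]])


class TestTTest:
    def test_identical_groups(self):
        res = t_test_two_tailed([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_formula(self):
        """{1,2,3} vs {2,4,6}: pooled var 2.5, t(4) = −1.5492, p = 0.1963."""
        res = t_test_two_tailed([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(-1.5491933, abs=1e-6)
        assert res.df == (4,)
        assert res.p_value == pytest.approx(0.1962612, abs=1e-6)

    def test_shift_monotonicity(self):
        base = [1.0, 2.0, 3.0]
        t_small = abs(t_test_two_tailed(base, [v + 1 for v in base]).statistic)
        t_large = abs(t_test_two_tailed(base, [v + 10 for v in base]).statistic)
        assert t_large > t_small

    def test_scipy_cross_check(self, rng):
        from scipy import stats as ss

        a = rng.normal(size=9)
        b = rng.normal(loc=0.7, size=12)
        ours = t_test_two_tailed(a, b)
        theirs = ss.ttest_ind(a, b, equal_var=True)
        assert ours.statistic == pytest.approx(theirs.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(theirs.pvalue, rel=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(InferenceError):
            t_test_two_tailed([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson_correlation(x, [2 * v + 1 for v in x])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_correlation(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_hand_covariance(self):
        """x={1,2,3,4}, y={2,1,4,3}: r = 3/5 = 0.6, df = 2, p = 0.4."""
        res = pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6, abs=1e-12)
        assert res.df == (2,)
        assert res.p_value == pytest.approx(0.4, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(InferenceError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_scipy_cross_check(self, rng):
        from scipy import stats as ss

        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        ours = pearson_correlation(x, y)
        r, p = ss.pearsonr(x, y)
        assert ours.statistic == pytest.approx(r, rel=1e-10)
        assert ours.p_value == pytest.approx(p, rel=1e-8)


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = [0.001, 0.02, 0.04, 0.8]
        adj = benjamini_hochberg(p)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= raw for a, raw in zip(adj, p))

    def test_statsmodels_cross_check(self, rng):
        smm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=20)
        ours = benjamini_hochberg(p)
        theirs = smm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)
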