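"""Statistical stages against hand computations and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from layerdig import (
    correlation_matrix,
    fit_dc_model,
    fit_performance_model,
    iqr_filter,
    line_ttest,
    pca_summary,
)
from layerdig.stats import p_value_band


def _table(values_by_line: dict, trait: str = "x") -> pd.DataFrame:
    rows = []
    for line, vals in values_by_line.items():
        for i, v in enumerate(vals):
            rows.append({"bird_id": f"{line}{i}", "line": line, trait: v})
    return pd.DataFrame(rows)


class TestIqrFilter:
    def test_single_far_point_removed(self):
        """{1..9, 100}: fences from Q1=3.25, Q3=7.75 remove only the 100."""
        df = _table({"A": list(range(1, 10)) + [100]})
        retained, removed = iqr_filter(df, k=1.5, traits=["x"])
        assert removed["A"] == ["A9"]
        assert len(retained) == 9

    def test_degenerate_identical_values_keep_all(self):
        df = _table({"A": [5.0] * 8})
        retained, removed = iqr_filter(df, k=1.5, traits=["x"])
        assert removed["A"] == [] and len(retained) == 8

    def test_fences_per_line_not_pooled(self):
        """A value ordinary for one line is not judged by the other line's fences."""
        df = _table({"A": [1, 2, 3, 4, 5], "B": [101, 102, 103, 104, 105]})
        _, removed = iqr_filter(df, k=1.5, traits=["x"])
        assert removed == {"A": [], "B": []}

    def test_missing_values_do_not_trigger_removal(self):
        df = _table({"A": [1.0, 2.0, 3.0, 4.0, np.nan]})
        retained, removed = iqr_filter(df, k=1.5, traits=["x"])
        assert removed["A"] == [] and len(retained) == 5

    def test_all_removed_aborts(self):
        # with k=0 the fences collapse to the quartile box; x flags the two
        # extremes, y flags the two records x leaves in
        df = _table({"A": [1, 2, 3, 1000]})
        df["y"] = [5, 1, 1000, 6]
        with pytest.raises(ValueError, match="every record"):
            iqr_filter(df, k=0.0, traits=["x", "y"])

    def test_small_line_rejected(self):
        df = _table({"A": [1, 2, 3]})
        with pytest.raises(ValueError, match=">= 4"):
            iqr_filter(df, k=1.5, traits=["x"])


class TestLineTtest:
    def test_identical_groups_null_identity(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        lc = line_ttest(vals, vals, "x")
        assert lc.p_value == pytest.approx(1.0)
        assert lc.t_statistic == pytest.approx(0.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        a = 0 + rng.normal(0, 1e-6, 4)
        b = 1 + rng.normal(0, 1e-6, 4)
        assert line_ttest(a, b, "x").p_value < 0.001

    def test_constant_equal_groups_convention(self):
        lc = line_ttest([2.0] * 4, [2.0] * 4, "x")
        assert (lc.t_statistic, lc.p_value) == (0.0, 1.0)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
        assert line_ttest(a, b).p_value == pytest.approx(line_ttest(b, a).p_value)

    def test_reports_se_as_sd_over_sqrt_n(self):
        a = [1.0, 2.0, 3.0, 4.0]
        lc = line_ttest(a, a)
        assert lc.se_a == pytest.approx(np.std(a, ddof=1) / 2)

    def test_welch_vs_pooled_flag(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 5, 40)
        welch = line_ttest(a, b).p_value
        pooled = line_ttest(a, b, equal_var=True).p_value
        assert welch != pooled
        assert pooled == pytest.approx(sps.ttest_ind(a, b).pvalue)

    def test_affine_invariance_of_p(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1, 15)
        assert line_ttest(2 * a + 3, 2 * b + 3).p_value == pytest.approx(
            line_ttest(a, b).p_value
        )


class TestCorrelationMatrix:
    def _df(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        return pd.DataFrame({
            "x": x, "y": 2 * x, "z": rng.normal(size=n),
        })

    def test_perfect_linearity(self):
        cm = correlation_matrix(self._df(), ["x", "y"])
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert bool(cm.significant.loc["x", "y"])

    def test_symmetric_unit_diagonal(self):
        cm = correlation_matrix(self._df(), ["x", "y", "z"])
        assert np.allclose(cm.r, cm.r.T)
        assert np.allclose(np.diag(cm.r), 1.0)

    def test_mask_matches_scipy_p(self):
        df = self._df(seed=2)
        cm = correlation_matrix(df, ["x", "z"], alpha=0.05)
        r, p = sps.pearsonr(df.x, df.z)
        assert cm.r.loc["x", "z"] == pytest.approx(r)
        assert bool(cm.significant.loc["x", "z"]) == (p < 0.05)

    def test_pairwise_complete_with_missing(self):
        df = self._df()
        df.loc[:4, "z"] = np.nan
        cm = correlation_matrix(df, ["x", "z"])
        r, _ = sps.pearsonr(df.x[5:], df.z[5:])
        assert cm.r.loc["x", "z"] == pytest.approx(r)

    def test_constant_trait_masked(self):
        df = self._df()
        df["c"] = 1.0
        cm = correlation_matrix(df, ["x", "c"])
        assert np.isnan(cm.r.loc["x", "c"])
        assert not bool(cm.significant.loc["x", "c"])

    def test_null_type_i_error_rate(self):
        """Independent traits at n = 44: ~5 % of seeds cross the 0.05 mask."""
        hits = 0
        n_rep = 1000
        rng = np.random.default_rng(123)
        for _ in range(n_rep):
            df = pd.DataFrame(rng.normal(size=(44, 2)), columns=["x", "z"])
            hits += bool(correlation_matrix(df, ["x", "z"]).significant.loc["x", "z"])
        assert 0.03 < hits / n_rep < 0.07


class TestPCA:
    def _df(self, n=60, seed=1):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 5))
        return pd.DataFrame(base, columns=list("abcde"))

    def test_rank_one_structure(self):
        """Two perfectly correlated standardized traits: dim1 explains 100 %."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        pr = pca_summary(pd.DataFrame({"a": x, "b": 3 * x + 1}), standardize=True)
        assert pr.explained_pct[0] == pytest.approx(100.0)

    def test_explained_variance_sums_to_100(self):
        pr = pca_summary(self._df())
        assert pr.explained_pct.sum() == pytest.approx(100.0)

    def test_contributions_sum_to_100_per_dimension(self):
        pr = pca_summary(self._df())
        assert np.allclose(pr.contributions.sum(axis=0), 100.0)

    def test_loadings_orthonormal(self):
        pr = pca_summary(self._df())
        L = pr.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_matches_direct_eigendecomposition_oracle(self):
        """Explained variances and loadings agree with eigh of the correlation matrix."""
        df = self._df(seed=7)
        pr = pca_summary(df, standardize=True)
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        evals = evals[::-1]
        evecs = evecs[:, ::-1]
        assert np.allclose(pr.explained_pct, evals / evals.sum() * 100, atol=1e-8)
        for j in range(5):  # eigenvectors defined up to sign
            got = pr.loadings.to_numpy()[:, j]
            assert np.allclose(got, evecs[:, j], atol=1e-8) or np.allclose(
                got, -evecs[:, j], atol=1e-8
            )

    def test_dominant_factor_recovered(self):
        """A factor built to explain a known share of variance is found by dim1."""
        rng = np.random.default_rng(11)
        n, m = 10_000, 5
        f = rng.normal(size=n)
        lam = 1.5  # per-trait factor loading; share = lam^2/(lam^2+1)
        x = lam * f[:, None] + rng.normal(size=(n, m))
        pr = pca_summary(pd.DataFrame(x, columns=list("abcde")), standardize=True)
        # equicorrelated traits at rho = lam^2/(lam^2+1): top eigenvalue share
        # of the correlation matrix is (1 + (m-1) rho) / m
        rho = lam**2 / (lam**2 + 1)
        expected = (1 + (m - 1) * rho) / m * 100
        assert abs(pr.explained_pct[0] - expected) < 1.0

    def test_needs_more_rows_than_traits(self):
        with pytest.raises(ValueError, match="more observations"):
            pca_summary(self._df(n=4))


class TestModels:
    def _df(self, n=44, seed=0):
        rng = np.random.default_rng(seed)
        em = rng.normal(50, 5, n)
        dbw = rng.normal(1700, 100, n)
        dc = rng.normal(70, 4, n)
        return pd.DataFrame({"em": em, "dbw": dbw, "dc_dm": dc})

    def test_noiseless_performance_recovery(self):
        df = self._df()
        df["fcr"] = 5 - 0.06 * df.em + 1e-9 * np.random.default_rng(1).normal(size=len(df))
        fit = fit_performance_model(df, "fcr")
        b1 = fit.coefficients.set_index("coefficient").loc["em", "estimate"]
        assert b1 == pytest.approx(-0.06, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_dc_recovery(self):
        df = self._df()
        df["rfc"] = 50 * df.dc_dm + np.random.default_rng(2).normal(0, 1e-6, len(df))
        fit = fit_dc_model(df, "rfc", "dc_dm")
        slope = fit.coefficients.set_index("coefficient").loc["dc_dm", "estimate"]
        assert slope == pytest.approx(50.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_single_predictor_r2_equals_squared_pearson_r(self):
        df = self._df(seed=5)
        df["rfc"] = 10 * df.dc_dm + np.random.default_rng(5).normal(0, 100, len(df))
        fit = fit_dc_model(df, "rfc", "dc_dm")
        r, _ = sps.pearsonr(df.rfc, df.dc_dm)
        assert fit.r_squared == pytest.approx(r**2, rel=1e-12)

    def test_null_model_r2_near_expectation(self):
        """Response independent of predictors: mean R^2 ~ p/(n-1)."""
        rng = np.random.default_rng(42)
        r2 = []
        for _ in range(300):
            df = self._df(seed=int(rng.integers(2**31)))
            df["fcr"] = rng.normal(size=len(df))
            r2.append(fit_performance_model(df, "fcr").r_squared)
        assert np.mean(r2) == pytest.approx(2 / 43, abs=0.02)

    def test_permutation_null_slope(self):
        """Permuted response: slope significant in ~5 % of permutations."""
        rng = np.random.default_rng(9)
        df = self._df(seed=9)
        df["rfc"] = 30 * df.dc_dm + rng.normal(0, 50, len(df))
        hits = 0
        n_perm = 400
        for _ in range(n_perm):
            sh = df.copy()
            sh["rfc"] = rng.permutation(sh["rfc"].to_numpy())
            fit = fit_dc_model(sh, "rfc", "dc_dm")
            hits += fit.coefficients.set_index("coefficient").loc["dc_dm", "p"] < 0.05
        assert 0.02 < hits / n_perm < 0.09

    def test_affine_rescaling_of_predictor(self):
        """Rescaling a predictor rescales its slope, leaves R^2 and p unchanged."""
        df = self._df(seed=3)
        df["rfc"] = 20 * df.dc_dm + np.random.default_rng(3).normal(0, 30, len(df))
        fit1 = fit_dc_model(df, "rfc", "dc_dm")
        df2 = df.assign(dc_dm=df.dc_dm * 10 + 7)
        fit2 = fit_dc_model(df2, "rfc", "dc_dm")
        s1 = fit1.coefficients.set_index("coefficient").loc["dc_dm"]
        s2 = fit2.coefficients.set_index("coefficient").loc["dc_dm"]
        assert s2.estimate == pytest.approx(s1.estimate / 10)
        assert s2.p == pytest.approx(s1.p)
        assert fit2.r_squared == pytest.approx(fit1.r_squared)

    def test_constant_predictor_rejected(self):
        df = self._df()
        df["dc_dm"] = 70.0
        df["rfc"] = df.em
        with pytest.raises(ValueError, match="constant"):
            fit_dc_model(df, "rfc", "dc_dm")


@pytest.mark.parametrize(
    "p,band",
    [(0.0005, "<0.001"), (0.005, "<0.01"), (0.03, "<0.05"), (0.07, "<0.1"), (0.5, "0.50")],
)
def test_p_value_bands(p, band):
    assert p_value_band(p) == band
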