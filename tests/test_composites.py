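"""Composite construction, reliability, PCA decomposition, age trends."""

import numpy as np
import pandas as pd
import pytest

from agediff.composites import (
    GeneralFactorPCA,
    composite_mean,
    correlation_table,
    cronbach_alpha,
    cubic_age_trend,
    general_specific_decomposition,
    pca_general_factor,
    zscore_by_task,
)


class TestZscore:
    def test_three_point_example(self):
        z = zscore_by_task(pd.DataFrame({"t": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["t"], [-1.0, 0.0, 1.0])

    def test_moments(self, rng):
        z = zscore_by_task(pd.DataFrame(rng.normal(5, 3, size=(50, 4))))
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_missing_entries_preserved(self, rng):
        x = pd.Series(rng.normal(size=20))
        x[3] = np.nan
        z = zscore_by_task(x.to_frame("t"))["t"]
        # oracle: z-scores recomputed on the observed subset agree
        obs = x.dropna()
        expected = (obs - obs.mean()) / obs.std(ddof=1)
        assert np.isnan(z[3])
        np.testing.assert_allclose(z.dropna(), expected)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_by_task(pd.DataFrame({"t": [1.0, 1.0, 1.0]}))


class TestCompositeMean:
    def test_complete_row_mean(self, rng):
        z = pd.DataFrame(rng.normal(size=(10, 18)))
        np.testing.assert_allclose(composite_mean(z), z.mean(axis=1))

    def test_available_task_rule(self, rng):
        z = pd.DataFrame(rng.normal(size=(5, 6)))
        z.iloc[0, 0] = np.nan
        comp = composite_mean(z, list(z.columns))
        assert comp[0] == pytest.approx(z.iloc[0, 1:].mean())

    def test_all_missing_row_is_nan(self):
        z = pd.DataFrame({"a": [np.nan, 1.0], "b": [np.nan, 2.0]})
        comp = composite_mean(z)
        assert np.isnan(comp[0]) and comp[1] == 1.5

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            composite_mean(pd.DataFrame(rng.normal(size=(4, 3))), [])

    def test_invariant_to_all_missing_column(self, rng):
        z = pd.DataFrame(rng.normal(size=(8, 5)))
        z_plus = z.copy()
        z_plus["ghost"] = np.nan
        np.testing.assert_allclose(composite_mean(z), composite_mean(z_plus))

    def test_matches_pca_scores_on_one_factor_data(self, rng):
        f = rng.normal(size=300)
        X = pd.DataFrame(
            {f"t{j}": 0.8 * f + 0.3 * rng.normal(size=300) for j in range(8)}
        )
        comp = composite_mean(zscore_by_task(X))
        scores, _ = pca_general_factor(X)
        assert abs(np.corrcoef(comp, scores)[0, 1]) >= 0.99


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        # equal-variance items correlated at 1 (essential tau-equivalence)
        x = np.arange(10, dtype=float)
        X = np.column_stack([x, x + 1, x - 3])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_uncorrelated_items_near_zero(self, rng):
        X = rng.standard_normal((5000, 4))
        assert abs(cronbach_alpha(X)) < 0.1

    def test_hand_computed_small_matrix(self):
        X = np.array(
            [[1.0, 2.0, 1.5], [2.0, 3.0, 2.5], [3.0, 5.0, 4.0], [4.0, 5.5, 5.0]]
        )
        k = 3
        expected = k / (k - 1) * (
            1 - X.var(axis=0, ddof=1).sum() / X.sum(axis=1).var(ddof=1)
        )
        assert cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)

    def test_compound_symmetry_closed_form(self, rng):
        """alpha equals k*cbar / (vbar + (k-1)*cbar) computed from the sample
        covariance matrix."""
        k, n = 6, 400
        f = rng.normal(size=n)
        X = 0.6 * f[:, None] + 0.8 * rng.standard_normal((n, k))
        S = np.cov(X, rowvar=False)
        vbar = np.diag(S).mean()
        cbar = (S.sum() - np.trace(S)) / (k * (k - 1))
        closed = k * cbar / (vbar + (k - 1) * cbar)
        assert cronbach_alpha(X) == pytest.approx(closed, abs=1e-10)

    def test_spearman_brown_floor_for_battery(self, rng):
        """18 items sharing r >= 0.3 push alpha beyond 0.6."""
        n, k, r = 200, 18, 0.3
        f = rng.normal(size=n)
        X = np.sqrt(r) * f[:, None] + np.sqrt(1 - r) * rng.standard_normal((n, k))
        assert cronbach_alpha(X) > 0.6

    def test_input_floors(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 1)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((2, 3)))


class TestGeneralFactorPCA:
    def test_two_identical_columns(self, rng):
        x = rng.normal(size=60)
        X = np.column_stack([x, x])
        est = GeneralFactorPCA().fit(X)
        assert est.loadings_[0] == pytest.approx(est.loadings_[1])
        assert abs(np.corrcoef(est.scores_, x)[0, 1]) > 0.9999

    def test_orthogonal_noise_explains_1_over_k(self, rng):
        X = rng.standard_normal((4000, 5))
        est = GeneralFactorPCA().fit(X)
        assert est.explained_variance_ratio_ == pytest.approx(1 / 5, abs=0.02)

    def test_recovers_generative_loadings(self, rng):
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        n = 3000
        f = rng.normal(size=n)
        X = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 4))
        est = GeneralFactorPCA().fit(X)
        # first-PC loadings carry the known upward bias relative to the
        # factor loadings, but track their pattern closely
        np.testing.assert_allclose(est.loadings_, lam, atol=0.2)
        assert np.all(np.diff(est.loadings_) < 0)  # ordering preserved

    def test_scores_standardized_sign_fixed(self, rng):
        X = rng.standard_normal((100, 3)) + rng.normal(size=100)[:, None]
        est = GeneralFactorPCA().fit(X)
        assert est.scores_.std(ddof=1) == pytest.approx(1.0)
        assert est.loadings_.mean() > 0

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        with pytest.raises(ValueError):
            GeneralFactorPCA().fit(X)


class TestGeneralSpecificDecomposition:
    def test_residuals_orthogonal_to_general(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("fnv"))
        g, resid = general_specific_decomposition(X)
        for col in resid:
            assert abs(np.corrcoef(g, resid[col])[0, 1]) < 1e-10

    def test_pure_one_factor_leaves_no_residual(self, rng):
        f = rng.normal(size=500)
        X = pd.DataFrame({c: f * s for c, s in zip("fnv", (1.0, 0.8, 1.2))})
        _, resid = general_specific_decomposition(X)
        assert resid.to_numpy().var() < 1e-20

    def test_age_links_to_general_not_residuals(self, rng):
        """When only the shared factor carries the age signal, the
        domain-specific residuals are age-flat."""
        n = 2000
        age = rng.uniform(18, 62, n)
        shared = 0.6 * (age - age.mean()) / age.std() + 0.8 * rng.normal(size=n)
        X = pd.DataFrame(
            {c: 0.9 * shared + 0.45 * rng.normal(size=n) for c in "fnv"}
        )
        g, resid = general_specific_decomposition(X)
        assert abs(np.corrcoef(age, g)[0, 1]) > 0.4
        for col in resid:
            assert abs(np.corrcoef(age, resid[col])[0, 1]) < 0.08


class TestCubicAgeTrend:
    def test_exact_cubic_recovered(self):
        age = np.linspace(18, 62, 40)
        x = age - age.mean()
        y = 1.0 + 0.5 * x - 0.02 * x**2 + 0.001 * x**3
        fit = cubic_age_trend(age, y)
        np.testing.assert_allclose(
            fit["coefficients"], [1.0, 0.5, -0.02, 0.001], atol=1e-9
        )

    def test_linear_truth_covered_by_ci(self):
        rng = np.random.default_rng(7)
        age = rng.uniform(18, 62, 300)
        y = 0.3 * age + rng.normal(0, 1.0, 300)
        fit = cubic_age_trend(age, y)
        lo, hi = fit["conf_int"][2], fit["conf_int"][3]
        assert lo[0] <= 0 <= lo[1]
        assert hi[0] <= 0 <= hi[1]

    def test_peak_near_thirty_located(self, rng):
        """Drift rising to a peak around 30 then declining."""
        n = 500
        age = rng.uniform(18, 62, n)
        y = -((age - 30.0) / 15.0) ** 2 + rng.normal(0, 0.3, n)
        fit = cubic_age_trend(age, y)
        peaks = fit["turning_points"]
        assert any(abs(t - 30) <= 5 for t in peaks)

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            cubic_age_trend(np.arange(4), np.arange(4))


class TestCorrelationTable:
    def test_self_correlation(self, rng):
        df = pd.DataFrame({"age": rng.normal(size=30)})
        df["copy"] = df["age"]
        out = correlation_table(df, "age")
        assert out.loc["copy", "r"] == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        df = pd.DataFrame(
            {"age": [20.0, 30.0, 40.0, 50.0, 60.0, 25.0, 35.0, 45.0, 55.0, 22.0],
             "y": [1.0, 2.0, 2.5, 3.5, 5.0, 1.5, 2.2, 3.0, 4.2, 1.2]}
        )
        out = correlation_table(df, "age")
        x, y = df["age"], df["y"]
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out.loc["y", "r"] == pytest.approx(expected, abs=1e-12)

    def test_type_one_error_rate_strict_alpha(self, rng):
        """Independent columns reject at ~alpha = 0.005."""
        from scipy import stats as st

        n, n_rep, alpha = 123, 4000, 0.005
        x = rng.standard_normal((n_rep, n))
        y = rng.standard_normal((n_rep, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * st.t.sf(np.abs(t), n - 2)
        rate = (p < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) < 4 * se

    def test_star_convention(self, rng):
        n = 200
        x = rng.normal(size=n)
        df = pd.DataFrame({"age": x, "strong": x + 0.5 * rng.normal(size=n),
                           "null": rng.normal(size=n)})
        out = correlation_table(df, "age")
        assert out.loc["strong", "sig"] == "**"
        assert out.loc["null", "sig"] == ""

    def test_minimum_pairwise_n(self):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            correlation_table(df, "age")
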