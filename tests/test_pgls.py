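import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from phyloxylem import bivariate_battery, pgls_fit, r2_phy
from phyloxylem.pgls import CollinearityError

from conftest import brownian_traits


class TestAgainstOLS:
    def test_star_tree_equals_ols_hand_example(self):
        fit = pgls_fit(np.array([1.0, 2, 3]), np.array([0.0, 1, 2])[:, None], 2 * np.eye(3))
        assert fit.intercept_ == pytest.approx(1.0)
        assert fit.coef_[0] == pytest.approx(1.0)

    def test_identity_covariance_matches_statsmodels(self):
        """With C = I the fit must reproduce OLS coefficients and the ML
        log-likelihood (statsmodels as the independent route)."""
        rng = np.random.default_rng(0)
        n = 40
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(n)
        fit = pgls_fit(y, X, None)
        sm_fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.beta_, sm_fit.params, atol=1e-8)
        assert fit.log_likelihood_ == pytest.approx(sm_fit.llf, abs=1e-8)
        assert np.allclose(fit.se_, sm_fit.bse, atol=1e-8)
        assert np.allclose(fit.p_values_, sm_fit.pvalues, atol=1e-10)

    def test_scaled_identity_same_coefficients(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(20)
        x = rng.standard_normal((20, 1))
        a = pgls_fit(y, x, None)
        b = pgls_fit(y, x, 7.3 * np.eye(20))
        assert np.allclose(a.beta_, b.beta_, atol=1e-10)
        assert a.r2_phy_ == pytest.approx(b.r2_phy_, abs=1e-12)


class TestLikelihoodOracle:
    def test_logl_matches_dense_mvn_density(self, cov150):
        """Brute-force oracle: evaluate the MVN density with an explicit
        determinant and inverse at the fitted parameters."""
        sub = cov150.subset(list(cov150.species[:10]))
        rng = np.random.default_rng(2)
        y = rng.standard_normal(10)
        x = rng.standard_normal((10, 2))
        fit = pgls_fit(y, x, sub)
        M = np.column_stack([np.ones(10), x])
        mean = M @ fit.beta_
        V = fit.sigma2_ml_ * sub.matrix
        sign, logdet = np.linalg.slogdet(V)
        r = y - mean
        oracle = -0.5 * (10 * np.log(2 * np.pi) + logdet + r @ np.linalg.inv(V) @ r)
        assert fit.log_likelihood_ == pytest.approx(oracle, abs=1e-8)

    def test_beta_equals_gls_normal_equations(self, cov150):
        sub = cov150.subset(list(cov150.species[:12]))
        rng = np.random.default_rng(3)
        y = rng.standard_normal(12)
        x = rng.standard_normal((12, 1))
        fit = pgls_fit(y, x, sub)
        M = np.column_stack([np.ones(12), x])
        Ci = np.linalg.inv(sub.matrix)
        beta = np.linalg.solve(M.T @ Ci @ M, M.T @ Ci @ y)
        assert np.allclose(fit.beta_, beta, atol=1e-10)

    def test_aic_definition(self, cov150):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(cov150.n)
        x = rng.standard_normal((cov150.n, 2))
        fit = pgls_fit(y, x, cov150)
        k = 3  # intercept + 2 slopes
        assert fit.aic_ == pytest.approx(-2 * fit.log_likelihood_ + 2 * (k + 1))
        assert fit.df_resid_ == cov150.n - k


class TestProperties:
    def test_whitened_residual_orthogonality(self, cov150):
        rng = np.random.default_rng(5)
        y = brownian_traits(cov150, 1.0, 0.02, rng)[:, 0]
        x = rng.standard_normal((cov150.n, 2))
        fit = pgls_fit(y, x, cov150)
        L = np.linalg.cholesky(cov150.matrix)
        from scipy.linalg import solve_triangular

        M = np.column_stack([np.ones(cov150.n), x])
        W = solve_triangular(L, M, lower=True)
        rw = solve_triangular(L, y, lower=True) - W @ fit.beta_
        assert np.max(np.abs(W.T @ rw)) < 1e-8

    def test_aic_ranking_invariant_to_predictor_rescaling(self, cov150):
        rng = np.random.default_rng(6)
        y = brownian_traits(cov150, 1.0, 0.02, rng)[:, 0]
        x = rng.standard_normal((cov150.n, 2))
        a = pgls_fit(y, x, cov150)
        b = pgls_fit(y, x * [100.0, 0.001] + [5.0, -3.0], cov150)
        assert a.aic_ == pytest.approx(b.aic_, abs=1e-6)
        assert a.log_likelihood_ == pytest.approx(b.log_likelihood_, abs=1e-6)

    def test_adding_predictor_never_decreases_logl(self, cov150):
        rng = np.random.default_rng(7)
        y = brownian_traits(cov150, 0.8, 0.02, rng)[:, 0]
        x = rng.standard_normal((cov150.n, 4))
        lls = [pgls_fit(y, x[:, :k], cov150).log_likelihood_ for k in range(1, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_marginal_f_is_t_squared(self, cov150):
        rng = np.random.default_rng(8)
        y = brownian_traits(cov150, 1.0, 0.02, rng)[:, 0]
        x = rng.standard_normal((cov150.n, 2))
        fit = pgls_fit(y, x, cov150)
        assert np.allclose(fit.f_values_, fit.t_values_ ** 2)
        p_from_t = 2 * stats.t.sf(np.abs(fit.t_values_), fit.df_resid_)
        assert np.allclose(fit.p_values_, p_from_t, atol=1e-12)


class TestErrors:
    def test_collinearity_names_aliased_column(self, cov150):
        rng = np.random.default_rng(9)
        x0 = rng.standard_normal(cov150.n)
        X = pd.DataFrame({"a": x0, "b": 2 * x0})
        with pytest.raises(CollinearityError, match="b"):
            pgls_fit(rng.standard_normal(cov150.n), X, cov150)

    def test_non_psd_covariance(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        C = np.kron(np.eye(5), C)
        with pytest.raises(np.linalg.LinAlgError):
            pgls_fit(np.arange(10.0), np.ones((10, 1)) * np.arange(10)[:, None], C)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            pgls_fit(np.arange(3.0), np.eye(3), np.eye(3))


class TestR2Phy:
    def test_null_model_gives_zero(self, cov150):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(cov150.n)
        null = pgls_fit(y, np.empty((cov150.n, 0)), cov150)
        assert null.r2_phy_ == pytest.approx(0.0, abs=1e-12)
        assert r2_phy(null, null) == pytest.approx(0.0, abs=1e-12)

    def test_exact_fit_gives_one(self, cov150):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(cov150.n)
        y = 2.0 + 3.0 * x  # zero residual
        fit = pgls_fit(y, x[:, None], cov150)
        null = pgls_fit(y, np.empty((cov150.n, 0)), cov150)
        assert r2_phy(fit, null) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_structures_rejected(self, cov150):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(cov150.n)
        x = rng.standard_normal((cov150.n, 1))
        fit = pgls_fit(y, x, cov150)
        null_wrong = pgls_fit(y, np.empty((cov150.n, 0)), None)
        with pytest.raises(ValueError):
            r2_phy(fit, null_wrong)


class TestBivariateBattery:
    def test_generative_slope_recovery(self, dataset200):
        """A trait built as 2*MAT + Brownian noise must yield a positive,
        significant MAT slope."""
        tree, table = dataset200.tree, dataset200.table
        C = tree.vcv(tree.tip_labels)
        rng = np.random.default_rng(13)
        y = 2.0 * table["MAT"].to_numpy() + brownian_traits(C, 1.0, 0.05, rng)[:, 0]
        traits = pd.DataFrame({"Y": y}, index=table.index)
        out = bivariate_battery(traits, table[["MAT", "MAP"]], C)
        row = out[(out.trait == "Y") & (out.climate == "MAT")].iloc[0]
        assert row.slope > 0 and row.p < 0.01
        assert row.ols_slope > 0

    def test_constant_column_flagged_not_fatal(self, dataset200):
        tree, table = dataset200.tree, dataset200.table
        C = tree.vcv(tree.tip_labels)
        clim = table[["MAT"]].copy()
        clim["K"] = 1.0
        traits = pd.DataFrame({"VF": table["VF"]})
        out = bivariate_battery(traits, clim, C)
        assert (out[out.climate == "K"].flag == "degenerate").all()
        assert (out[out.climate == "MAT"].flag == "").all()

    def test_missing_values_dropped_listwise(self, dataset200):
        tree, table = dataset200.tree, dataset200.table
        C = tree.vcv(tree.tip_labels)
        traits = pd.DataFrame({"VF": table["VF"].copy()})
        traits.iloc[:5, 0] = np.nan
        out = bivariate_battery(traits, table[["MAT"]], C)
        assert out.iloc[0]["n"] == len(table) - 5
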