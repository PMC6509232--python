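"""Phylogenetic generalized least squares with a Brownian-motion
correlation structure, fitted by maximum likelihood.

Observations are whitened by the Cholesky factor of the phylogenetic
covariance matrix C (never by explicit inversion); the GLS estimate is then
ordinary least squares on the whitened data.  The pseudo-R^2 for the
phylogenetic model, R2_phy, is one minus the ratio of whitened residual
sums of squares between the fitted model and the intercept-only null with
the same correlation structure.  With C = I everything reduces exactly to
ordinary least squares, which is how the non-phylogenetic companion models
are obtained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin

from .tree import PhyloCovariance

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


def _covariance_matrix(covariance, n: int) -> np.ndarray:
    if covariance is None:
        return np.eye(n)
    if isinstance(covariance, PhyloCovariance):
        m = covariance.matrix
    else:
        m = np.asarray(covariance, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"covariance shape {m.shape} does not match n={n}")
    return m


def _design(X, fit_intercept: bool):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = [f"x{i}" for i in range(M.shape[1])]
    if fit_intercept:
        M = np.column_stack([np.ones(len(M)), M])
        names = ["(Intercept)"] + names
    return M, names


class PGLS(RegressorMixin, BaseEstimator):
    """Generalized least squares regression whose residual covariance is
    proportional to a phylogenetic covariance matrix.

    Parameters
    ----------
    covariance : PhyloCovariance, (n, n) array, or None
        Brownian-motion covariance among observations; ``None`` means the
        identity, i.e. ordinary least squares.
    fit_intercept : bool
        Prepend an intercept column to the design.

    Attributes
    ----------
    coef_ : (p,) array
        Slope coefficients (excluding the intercept).
    intercept_ : float
    beta_ : (k,) array
        All coefficients in design order (intercept first when fitted).
    se_ : (k,) array
        Standard errors (unbiased residual variance).
    f_values_, p_values_ : (k,) arrays
        Marginal single-df F statistics (t^2) and their p-values, per term.
    log_likelihood_ : float
        Multivariate-normal log-likelihood at the ML optimum.
    aic_ : float
        -2 logL + 2 (k + 1); the +1 counts the residual variance.
    r2_phy_ : float
        1 - RSS_w(model) / RSS_w(intercept-only null), whitened space,
        clipped to [0, 1].
    """

    def __init__(self, covariance=None, fit_intercept: bool = True):
        self.covariance = covariance
        self.fit_intercept = fit_intercept

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        M, names = _design(X, self.fit_intercept)
        if M.shape[0] != n:
            raise ValueError("X and y have different lengths")
        k = M.shape[1]
        if n <= k:
            raise ValueError(f"need n > number of coefficients ({n} <= {k})")
        C = _covariance_matrix(self.covariance, n)

        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance not positive definite "
                f"(condition number {np.linalg.cond(C):.3g})"
            ) from exc
        logdet_C = 2.0 * np.sum(np.log(np.diag(L)))

        W = solve_triangular(L, M, lower=True)
        z = solve_triangular(L, y, lower=True)

        # rank check via QR so aliased columns can be named
        Qm, Rm = np.linalg.qr(W, mode="reduced")
        rdiag = np.abs(np.diag(Rm))
        tol = max(W.shape) * np.finfo(float).eps * (rdiag.max() if rdiag.size else 0.0)
        if np.any(rdiag <= tol):
            aliased = [names[i] for i in np.where(rdiag <= tol)[0]]
            raise CollinearityError(f"rank-deficient design; aliased terms: {aliased}")

        beta = np.linalg.solve(Rm, Qm.T @ z)
        resid_w = z - W @ beta
        rss_w = float(resid_w @ resid_w)
        sigma2_ml = rss_w / n
        logL = -0.5 * (n * _LOG2PI + n * np.log(sigma2_ml) + logdet_C + n)

        df_resid = n - k
        sigma2_unbiased = rss_w / df_resid
        Rinv = solve_triangular(Rm, np.eye(k), lower=False)
        cov_beta = sigma2_unbiased * (Rinv @ Rinv.T)
        se = np.sqrt(np.diag(cov_beta))
        tvals = beta / se
        fvals = tvals**2
        pvals = stats.f.sf(fvals, 1, df_resid)

        # intercept-only null with the same correlation structure
        ones_w = solve_triangular(L, np.ones(n), lower=True)
        mu_w = (ones_w @ z) / (ones_w @ ones_w)
        null_resid = z - mu_w * ones_w
        rss_w_null = float(null_resid @ null_resid)
        sigma2_null = rss_w_null / n
        logL_null = -0.5 * (n * _LOG2PI + n * np.log(sigma2_null) + logdet_C + n)

        self.feature_names_in_ = names[1:] if self.fit_intercept else names
        self.term_names_ = names
        self.beta_ = beta
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.se_ = se
        self.t_values_ = tvals
        self.f_values_ = fvals
        self.p_values_ = pvals
        self.sigma2_ml_ = sigma2_ml
        self.sigma2_ = sigma2_unbiased
        self.log_likelihood_ = float(logL)
        self.aic_ = float(-2.0 * logL + 2.0 * (k + 1))
        self.df_resid_ = df_resid
        self.n_ = n
        self.rss_whitened_ = rss_w
        self.rss_whitened_null_ = rss_w_null
        self.log_likelihood_null_ = float(logL_null)
        self.aic_null_ = float(-2.0 * logL_null + 2.0 * 2)
        self.r2_phy_ = float(np.clip(1.0 - rss_w / rss_w_null, 0.0, 1.0))
        self.residuals_ = y - M @ beta
        self._cov_signature = (id(self.covariance), n)
        return self

    def predict(self, X):
        M, _ = _design(X, self.fit_intercept)
        return M @ self.beta_

    def summary(self) -> pd.DataFrame:
        """Tidy per-term table: coefficient, SE, F (1 df, marginal), p."""
        return pd.DataFrame(
            {
                "term": self.term_names_,
                "beta": self.beta_,
                "se": self.se_,
                "F": self.f_values_,
                "p": self.p_values_,
            }
        ).set_index("term")


# -- functional wrappers ---------------------------------------------------


def pgls_fit(y, X, C=None, fit_intercept: bool = True) -> PGLS:
    """Fit a PGLS regression of ``y`` on ``X`` under covariance ``C``.

    ``C=None`` gives the ordinary (non-phylogenetic) least-squares fit.
    """
    return PGLS(covariance=C, fit_intercept=fit_intercept).fit(X, y)


def r2_phy(fit: PGLS, null_fit: PGLS) -> float:
    """Pseudo-R^2: 1 - RSS_w(model)/RSS_w(null) in the whitened space.

    ``null_fit`` must be the intercept-only model under the same
    correlation structure.
    """
    if null_fit.n_ != fit.n_:
        raise ValueError("model and null fitted to different data sizes")
    if len(null_fit.beta_) != 1:
        raise ValueError("null model must be intercept-only")
    if not np.isclose(null_fit.rss_whitened_, fit.rss_whitened_null_, rtol=1e-8):
        raise ValueError("null model does not share the model's correlation structure")
    return float(np.clip(1.0 - fit.rss_whitened_ / null_fit.rss_whitened_, 0.0, 1.0))


def bivariate_battery(
    traits: pd.DataFrame,
    climate: pd.DataFrame,
    C: PhyloCovariance,
    trait_columns=None,
    climate_columns=None,
) -> pd.DataFrame:
    """Fit every (trait, climate index) PGLS pair plus the matching OLS.

    Missing values are dropped listwise per pair (covariance subset to the
    complete cases).  Degenerate cells (constant predictor or trait) are
    flagged rather than fatal.  Returns a tidy frame with one row per pair:
    slope, p, R2_phy and AIC for the phylogenetic model and slope, p, AIC
    for the ordinary one.
    """
    trait_columns = list(trait_columns or traits.columns)
    climate_columns = list(climate_columns or climate.columns)
    species = list(traits.index)
    rows = []
    for trait in trait_columns:
        for clim in climate_columns:
            rec = {"trait": trait, "climate": clim, "flag": ""}
            y = traits[trait].astype(float)
            x = climate.loc[species, clim].astype(float)
            mask = y.notna() & x.notna()
            yv, xv = y[mask].to_numpy(), x[mask].to_numpy()
            if len(yv) < 4 or np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rec["flag"] = "degenerate"
                rows.append(rec)
                continue
            sub = C.subset(list(y[mask].index))
            try:
                phy = pgls_fit(yv, xv[:, None], sub)
                ols = pgls_fit(yv, xv[:, None], None)
            except (np.linalg.LinAlgError, CollinearityError) as exc:
                rec["flag"] = f"failed: {exc}"
                rows.append(rec)
                continue
            rec.update(
                n=len(yv),
                slope=phy.coef_[0],
                p=phy.p_values_[1],
                r2_phy=phy.r2_phy_,
                aic=phy.aic_,
                ols_slope=ols.coef_[0],
                ols_p=ols.p_values_[1],
                ols_r2=ols.r2_phy_,
                ols_aic=ols.aic_,
            )
            rows.append(rec)
    return pd.DataFrame(rows)
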