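"""Phylogenetic signal: maximum-likelihood estimation of Pagel's lambda.

The trait vector y over n species is modelled as multivariate normal with
mean mu * 1 and covariance sigma^2 * C(lambda), where C(lambda) scales the
off-diagonal (shared-history) entries of the phylogenetic covariance matrix
by lambda in [0, 1].  lambda = 1 is pure Brownian motion, lambda = 0 an
independent (star-phylogeny) model.  For each lambda, mu and sigma^2 have
closed-form GLS profiles, leaving a one-dimensional likelihood maximized by
a grid pre-scan plus bounded Brent search.

For an ultrametric tree the diagonal of C is constant, so C(lambda) shares
the eigenvectors of C for every lambda; a single symmetric eigendecomposition
then makes each profile evaluation O(n) instead of a fresh O(n^3) Cholesky.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator

from .tree import PhyloCovariance, lambda_transform

_LOG2PI = np.log(2.0 * np.pi)


class DegenerateTraitError(ValueError):
    """Trait vector has (numerically) zero variance."""


def _as_matrix(C) -> np.ndarray:
    if isinstance(C, PhyloCovariance):
        return C.matrix
    return np.asarray(C, dtype=float)


def _profile_loglik_general(lam: float, y: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood at lambda via Cholesky of the transformed C."""
    n = len(y)
    V = lambda_transform(C, lam)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"lambda-transformed covariance not positive definite at "
            f"lambda={lam:g} (condition number {cond:.3g})"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    yw = solve_triangular(L, y, lower=True)
    ow = solve_triangular(L, np.ones(n), lower=True)
    mu = (ow @ yw) / (ow @ ow)
    r = yw - mu * ow
    sigma2 = (r @ r) / n
    return -0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + n)


class _UltrametricProfile:
    """O(n) profile evaluations after one eigendecomposition of C."""

    def __init__(self, y: np.ndarray, C: np.ndarray):
        self.n = len(y)
        self.T = float(C[0, 0])
        evals, evecs = np.linalg.eigh(C)
        self.evals = np.clip(evals, 0.0, None)
        self.y_rot = evecs.T @ y
        self.one_rot = evecs.T @ np.ones(self.n)

    def __call__(self, lam: float) -> float:
        w = lam * self.evals + (1.0 - lam) * self.T
        if w.min() <= 1e-12 * w.max():
            # singular at lambda -> 1 (e.g. zero-length terminal branches)
            raise np.linalg.LinAlgError(
                f"covariance singular at lambda={lam:g} "
                f"(eigenvalue ratio {w.min() / w.max():.3g})"
            )
        yw, ow = self.y_rot, self.one_rot
        mu = np.sum(ow * yw / w) / np.sum(ow * ow / w)
        r = yw - mu * ow
        sigma2 = np.sum(r * r / w) / self.n
        return -0.5 * (
            self.n * _LOG2PI + self.n * np.log(sigma2) + np.sum(np.log(w)) + self.n
        ), mu, sigma2

    def loglik(self, lam: float) -> float:
        return self(lam)[0]


@dataclass(frozen=True)
class LambdaFit:
    """Result of a Pagel's lambda maximum-likelihood fit."""

    lambda_hat: float
    sigma2_hat: float
    mu_hat: float
    logL: float
    logL_lambda0: float
    p_value: float
    n_species: int
    method: str = "profile-ML, LR test vs lambda=0 on chi2(1)"


class PagelLambda(BaseEstimator):
    """Maximum-likelihood estimator of Pagel's lambda for one trait.

    Parameters
    ----------
    grid_points : int
        Size of the pre-scan grid over [0, 1] used to bracket the optimum
        before the bounded scalar search (guards against local optima).
    xtol : float
        Absolute tolerance of the bounded search on lambda.
    min_species : int
        Minimum number of species required for a fit.

    Attributes
    ----------
    lambda_ : float
        ML estimate of lambda in [0, 1].
    sigma2_ : float
        ML Brownian rate (trait variance per My).
    mu_ : float
        ML root state.
    log_likelihood_ : float
        Profile log-likelihood at ``lambda_``.
    log_likelihood_lambda0_ : float
        Profile log-likelihood of the no-signal model (lambda = 0).
    p_value_ : float
        Likelihood-ratio p-value against lambda = 0 (chi-square, 1 df).
    """

    def __init__(self, grid_points: int = 21, xtol: float = 1e-8, min_species: int = 10):
        self.grid_points = grid_points
        self.xtol = xtol
        self.min_species = min_species

    def fit(self, X, y):
        """Fit lambda by profile ML.

        Parameters
        ----------
        X : (n, n) array or PhyloCovariance
            Phylogenetic covariance matrix aligned with ``y``.
        y : (n,) array
            Trait values, one per species.
        """
        C = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if C.shape != (n, n):
            raise ValueError(f"covariance shape {C.shape} does not match n={n}")
        if n < self.min_species:
            raise ValueError(f"need at least {self.min_species} species, got {n}")
        if not np.all(np.isfinite(y)):
            raise ValueError("trait vector contains non-finite values")
        if np.ptp(y) == 0 or np.var(y) < 1e-30:
            raise DegenerateTraitError("trait has zero variance")

        diag = np.diag(C)
        ultrametric = np.allclose(diag, diag[0], rtol=1e-8)
        if ultrametric:
            profile = _UltrametricProfile(y, C)
            loglik = profile.loglik
        else:
            loglik = lambda lam: _profile_loglik_general(lam, y, C)  # noqa: E731

        grid = np.linspace(0.0, 1.0, self.grid_points)
        grid_ll = np.array([loglik(g) for g in grid])
        best = int(np.argmax(grid_ll))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda lam: -loglik(lam),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": self.xtol},
            )
            lam_hat, ll_hat = float(res.x), -float(res.fun)
        else:
            lam_hat, ll_hat = float(grid[best]), float(grid_ll[best])
        # the bounded search can land a hair off a boundary optimum
        for cand, cand_ll in ((grid[best], grid_ll[best]),):
            if cand_ll > ll_hat:
                lam_hat, ll_hat = float(cand), float(cand_ll)

        ll0 = float(grid_ll[0])
        lr = max(0.0, 2.0 * (ll_hat - ll0))
        p = float(stats.chi2.sf(lr, df=1))

        if ultrametric:
            _, mu, sigma2 = profile(lam_hat)
        else:
            mu, sigma2 = _gls_profile_at(lam_hat, y, C)

        self.lambda_ = lam_hat
        self.sigma2_ = float(sigma2)
        self.mu_ = float(mu)
        self.log_likelihood_ = ll_hat
        self.log_likelihood_lambda0_ = ll0
        self.lr_statistic_ = lr
        self.p_value_ = p
        self.n_species_ = n
        return self

    def result(self) -> LambdaFit:
        return LambdaFit(
            lambda_hat=self.lambda_,
            sigma2_hat=self.sigma2_,
            mu_hat=self.mu_,
            logL=self.log_likelihood_,
            logL_lambda0=self.log_likelihood_lambda0_,
            p_value=self.p_value_,
            n_species=self.n_species_,
        )


def _gls_profile_at(lam: float, y: np.ndarray, C: np.ndarray):
    from scipy.linalg import cho_factor, cho_solve

    V = lambda_transform(C, lam)
    cf = cho_factor(V, lower=True)
    one = np.ones(len(y))
    Vi_y = cho_solve(cf, y)
    Vi_1 = cho_solve(cf, one)
    mu = (one @ Vi_y) / (one @ Vi_1)
    r = y - mu
    sigma2 = (r @ cho_solve(cf, r)) / len(y)
    return mu, sigma2


def fit_lambda(y, C, **kwargs) -> LambdaFit:
    """Functional wrapper: fit Pagel's lambda for one trait.

    Parameters
    ----------
    y : (n,) array
        Trait values aligned with ``C``.
    C : PhyloCovariance or (n, n) array
        Phylogenetic covariance matrix.
    """
    est = PagelLambda(**kwargs).fit(C, y)
    return est.result()


def lambda_table(table, traits, C, **kwargs):
    """Fit lambda for several trait columns; returns a tidy DataFrame."""
    import pandas as pd

    rows = []
    for trait in traits:
        y = np.asarray(table[trait], dtype=float)
        mask = np.isfinite(y)
        if isinstance(C, PhyloCovariance):
            sub = C.subset([s for s, m in zip(C.species, mask) if m]).matrix
        else:
            sub = np.asarray(C)[np.ix_(mask, mask)]
        fit = fit_lambda(y[mask], sub, **kwargs)
        rows.append(
            {
                "trait": trait,
                "lambda": fit.lambda_hat,
                "sigma2": fit.sigma2_hat,
                "logL": fit.logL,
                "logL_lambda0": fit.logL_lambda0,
                "p_value": fit.p_value,
                "n": fit.n_species,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
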