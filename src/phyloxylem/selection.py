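"""Three-step climate-variable selection for multivariate PGLS models.

Thirteen candidate climate indices are strongly inter-correlated, so the
predictor pool is reduced in three steps before a final model is fitted:

1. screen: drop indices whose bivariate PGLS pseudo-R^2 against the trait
   falls below a threshold (default 0.02);
2. within-group elimination: AIC-based backward elimination separately
   inside the thermal, moisture and integrative index groups;
3. pooled elimination: the survivors of all groups enter one model and
   backward elimination runs once more, yielding the final model.

Backward elimination accepts the best single-variable removal whenever the
resulting AIC is within ``parsimony_delta`` of the current model's (default
2.0: a smaller model nearly as good is preferred; 0 gives strict AIC
descent).  Ties (AIC differences below 1e-6) are broken by dropping the
variable that appears later in the canonical index ordering, which makes
the procedure invariant to column order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .pgls import PGLS, pgls_fit
from .traits import CLIMATE_GROUPS, CLIMATE_INDICES

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-6


def _canonical_rank(name: str) -> int:
    try:
        return CLIMATE_INDICES.index(name)
    except ValueError:
        return len(CLIMATE_INDICES)


def _aic_of(y, X: pd.DataFrame, cols, C) -> float:
    if cols:
        return pgls_fit(y, X[list(cols)], C).aic_
    return pgls_fit(y, np.empty((len(y), 0)), C).aic_


def _backward_eliminate(y, X: pd.DataFrame, cols, C, delta: float, trace: list):
    """Greedy backward elimination on AIC; returns the surviving columns."""
    current = list(cols)
    aic = _aic_of(y, X, current, C)
    trace.append({"model": list(current), "aic": aic, "action": "start"})
    while current:
        candidates = []
        for var in current:
            reduced = [v for v in current if v != var]
            candidates.append((var, _aic_of(y, X, reduced, C)))
        best_aic = min(a for _, a in candidates)
        tied = [v for v, a in candidates if a <= best_aic + _TIE_TOL]
        drop = max(tied, key=_canonical_rank)
        drop_aic = dict(candidates)[drop]
        if drop_aic <= aic + delta:
            current.remove(drop)
            aic = drop_aic
            trace.append({"model": list(current), "aic": aic, "action": f"drop {drop}"})
        else:
            break
    return current, aic


class ClimateModelSelector(BaseEstimator):
    """Select the most parsimonious multivariate PGLS climate model.

    Parameters
    ----------
    covariance : PhyloCovariance or array
        Brownian phylogenetic covariance aligned with the rows of X.
    groups : dict[str, list[str]] or None
        Partition of the candidate indices; defaults to the
        thermal/moisture/integrative grouping.
    r2_threshold : float
        Step-1 bivariate pseudo-R^2 screen (default 0.02).
    parsimony_delta : float
        AIC slack within which a smaller model is preferred (default 2.0;
        0 disables the parsimony preference).

    Attributes
    ----------
    selected_ : list[str]
        Predictors of the final model.
    support_ : (n_features,) bool array
        Mask over the columns of the fitted X.
    final_model_ : PGLS
        The fitted final model (intercept-only if nothing survives).
    trace_ : dict
        Full selection trace (step-1 R^2 values and exclusions, per-group
        elimination paths, pooled path, examined candidates with AIC).
    """

    def __init__(
        self,
        covariance=None,
        groups: dict | None = None,
        r2_threshold: float = 0.02,
        parsimony_delta: float = 2.0,
    ):
        self.covariance = covariance
        self.groups = groups
        self.r2_threshold = r2_threshold
        self.parsimony_delta = parsimony_delta

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        groups = self.groups
        if groups is None:
            groups = {
                g: [v for v in vars_ if v in X.columns]
                for g, vars_ in CLIMATE_GROUPS.items()
            }
            ungrouped = [
                c for c in X.columns if not any(c in v for v in groups.values())
            ]
            if ungrouped:
                groups["other"] = ungrouped
        C = self.covariance

        # step 1: bivariate pseudo-R^2 screen
        step1_r2, step1_survivors, step1_excluded = {}, [], []
        for var in X.columns:
            x = X[var].to_numpy()
            if np.ptp(x) == 0:
                step1_r2[var] = np.nan
                step1_excluded.append(var)
                continue
            r2 = pgls_fit(y, x[:, None], C).r2_phy_
            step1_r2[var] = r2
            (step1_survivors if r2 >= self.r2_threshold else step1_excluded).append(var)

        # step 2: backward elimination within each climate group
        step2_survivors, step2_trace = [], {}
        for gname, gvars in groups.items():
            gvars = [v for v in gvars if v in step1_survivors]
            if not gvars:
                step2_trace[gname] = []
                continue
            path: list = []
            kept, _ = _backward_eliminate(y, X, gvars, C, self.parsimony_delta, path)
            step2_survivors.extend(kept)
            step2_trace[gname] = path
        step2_survivors = sorted(step2_survivors, key=_canonical_rank)

        # step 3: pooled backward elimination
        step3_trace: list = []
        if step2_survivors:
            final_vars, final_aic = _backward_eliminate(
                y, X, step2_survivors, C, self.parsimony_delta, step3_trace
            )
        else:
            logger.warning("no climate variable survived step 1; intercept-only model")
            final_vars, final_aic = [], _aic_of(y, X, [], C)

        if final_vars:
            final = pgls_fit(y, X[final_vars], C)
        else:
            final = pgls_fit(y, np.empty((len(y), 0)), C)

        self.feature_names_in_ = list(X.columns)
        self.selected_ = final_vars
        self.support_ = np.array([c in final_vars for c in X.columns])
        self.final_model_ = final
        self.final_aic_ = final_aic
        self.trace_ = {
            "threshold": self.r2_threshold,
            "parsimony_delta": self.parsimony_delta,
            "step1_r2": step1_r2,
            "step1_excluded": step1_excluded,
            "step1_survivors": step1_survivors,
            "step2_trace": step2_trace,
            "step2_survivors": step2_survivors,
            "step3_trace": step3_trace,
            "final": {"model": final_vars, "aic": final.aic_},
        }
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_]
        return np.asarray(X)[:, self.support_]


def select_model(trait, climate_table: pd.DataFrame, C, **kwargs):
    """Run the three-step selection for one trait vector.

    Returns ``(trace, final_model)`` where ``trace`` is the selection trace
    dict and ``final_model`` the fitted PGLS.
    """
    sel = ClimateModelSelector(covariance=C, **kwargs).fit(climate_table, trait)
    return sel.trace_, sel.final_model_
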