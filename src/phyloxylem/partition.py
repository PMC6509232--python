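"""Partition of trait variation into phylogeny-only, climate-only, shared
and unexplained components.

Phylogeny enters as a categorical factor whose levels are the clades
obtained by cutting the ultrametric tree at a divergence time; climate
enters as continuous covariates.  Ordinary (not REML) least squares keeps
the sums of squares additive, so the classical commonality identities
apply.  With SS_E(M) the explained (model) sum of squares of the OLS model
M, and "full" the model containing both the group factor and the climate
covariates:

    phylo_only   = SS_E(full) - SS_E(climate)
    climate_only = SS_E(full) - SS_E(groups)
    shared       = SS_E(groups) + SS_E(climate) - SS_E(full)
    unexplained  = SS_total - SS_E(full)

The four components sum to the total sum of squares exactly.  The shared
component is the variation jointly attributable to phylogeny and climate
(clades differing in the climate space they occupy); it can be negative in
suppression situations and is reported as computed.  F ratios for the two
unique components use their rank-increment degrees of freedom over the
full-model residual mean square; the shared component has no testable df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .tree import Phylogeny, PhyloGrouping

logger = logging.getLogger(__name__)


class ConfoundedDesignError(ValueError):
    """Group factor and climate covariates are exactly aliased."""


@dataclass(frozen=True)
class PartitionResult:
    """Sums-of-products partition for one trait under one tree cut."""

    trait: str
    cut_time: float
    n_groups: int
    n: int
    ss: dict[str, float]
    percent: dict[str, float]
    df: dict[str, int]
    f_ratio: dict[str, float]
    p_value: dict[str, float]
    negative_shared: bool = field(default=False)

    def to_row(self) -> dict:
        row = {
            "trait": self.trait,
            "cut_time": self.cut_time,
            "n_groups": self.n_groups,
            "n": self.n,
        }
        for comp in ("phylo_only", "climate_only", "shared", "unexplained"):
            row[f"pct_{comp}"] = self.percent[comp]
        for comp in ("phylo_only", "climate_only"):
            row[f"F_{comp}"] = self.f_ratio.get(comp, np.nan)
            row[f"p_{comp}"] = self.p_value.get(comp, np.nan)
        row["negative_shared"] = self.negative_shared
        return row


def _explained_ss(y: np.ndarray, X: np.ndarray | None):
    """Explained (centered) sum of squares and design rank of the OLS fit
    of y on [1, X]."""
    n = len(y)
    if X is None or X.shape[1] == 0:
        return 0.0, 1
    design = np.column_stack([np.ones(n), X])
    fit = sm.OLS(y, design).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(fit.ssr)
    rank = int(np.linalg.matrix_rank(design))
    return tss - rss, rank


def _group_dummies(labels: np.ndarray) -> np.ndarray:
    codes, _ = pd.factorize(labels)
    k = codes.max() + 1
    if k < 2:
        raise ValueError("need at least 2 groups")
    D = np.zeros((len(codes), k - 1))
    for j in range(1, k):  # treatment coding, first level as reference
        D[codes == j, j - 1] = 1.0
    return D


def partition(
    y,
    climate_X: pd.DataFrame | np.ndarray | None,
    grouping: PhyloGrouping | np.ndarray,
    trait: str = "trait",
    species: list[str] | None = None,
) -> PartitionResult:
    """Partition one trait's variance between a tree-cut group factor and
    climate covariates.

    Parameters
    ----------
    y : (n,) array
        Trait values.
    climate_X : DataFrame/array of climate covariates, or None/empty
        With no climate columns the partition reduces to the one-way
        ANOVA R^2 of the group factor.
    grouping : PhyloGrouping or (n,) label array
        Group memberships; a PhyloGrouping requires ``species`` for
        alignment.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if isinstance(grouping, PhyloGrouping):
        if species is None:
            raise ValueError("species order required with a PhyloGrouping")
        labels = grouping.labels(list(species))
        cut_time = grouping.cut_time
    else:
        labels = np.asarray(grouping)
        cut_time = np.nan
    if len(labels) != n:
        raise ValueError("grouping length does not match y")

    if climate_X is None:
        Xc = np.empty((n, 0))
    elif isinstance(climate_X, pd.DataFrame):
        Xc = climate_X.to_numpy(dtype=float)
    else:
        Xc = np.asarray(climate_X, dtype=float)
        if Xc.ndim == 1:
            Xc = Xc[:, None]
    if Xc.shape[1]:
        # constant covariates carry no information and alias the intercept
        keep = np.ptp(Xc, axis=0) > 0
        if not keep.all():
            logger.warning("dropping %d constant climate column(s)", (~keep).sum())
            Xc = Xc[:, keep]

    G = _group_dummies(labels)
    n_groups = G.shape[1] + 1
    if n <= n_groups + Xc.shape[1]:
        raise ValueError("too few observations for the requested partition")

    full_design = np.column_stack([np.ones(n), G, Xc])
    rank_full_design = np.linalg.matrix_rank(full_design)
    if rank_full_design < full_design.shape[1]:
        # identify which block carries the exact dependence
        aliased = []
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), G])) < 1 + G.shape[1]:
            aliased.append("group factor")
        grp_rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), G]))
        if rank_full_design < grp_rank + Xc.shape[1]:
            aliased.append("climate covariates (constant within groups?)")
        raise ConfoundedDesignError(
            f"full design rank deficient; aliased terms: {aliased or ['unknown']}"
        )

    tss = float(np.sum((y - y.mean()) ** 2))
    ss_g, rank_g = _explained_ss(y, G)
    ss_c, rank_c = _explained_ss(y, Xc)
    ss_full, rank_full = _explained_ss(y, np.column_stack([G, Xc]))

    comp = {
        "phylo_only": ss_full - ss_c,
        "climate_only": ss_full - ss_g,
        "shared": ss_g + ss_c - ss_full,
        "unexplained": tss - ss_full,
    }
    percent = {k: 100.0 * v / tss for k, v in comp.items()}

    df_phylo = rank_full - rank_c
    df_climate = rank_full - rank_g
    df_resid = n - rank_full
    df_shared = (rank_g - 1) + (rank_c - 1) - (df_phylo + df_climate)
    dfs = {
        "phylo_only": df_phylo,
        "climate_only": df_climate,
        "shared": df_shared,
        "unexplained": df_resid,
    }
    ms_resid = comp["unexplained"] / df_resid
    f_ratio, p_value = {}, {}
    for key in ("phylo_only", "climate_only"):
        if dfs[key] > 0 and ms_resid > 0:
            f = (comp[key] / dfs[key]) / ms_resid
            f_ratio[key] = float(f)
            p_value[key] = float(stats.f.sf(f, dfs[key], df_resid))
        else:
            f_ratio[key] = np.nan
            p_value[key] = np.nan

    negative_shared = comp["shared"] < -1e-8 * max(tss, 1.0)
    if negative_shared:
        logger.warning(
            "negative shared component (%.3g%% of total) for %s", percent["shared"], trait
        )
    return PartitionResult(
        trait=trait,
        cut_time=float(cut_time),
        n_groups=int(n_groups),
        n=n,
        ss={**comp, "total": tss},
        percent=percent,
        df=dfs,
        f_ratio=f_ratio,
        p_value=p_value,
        negative_shared=negative_shared,
    )


class VariancePartition(BaseEstimator):
    """Estimator wrapper around :func:`partition`.

    Parameters
    ----------
    grouping : PhyloGrouping or label array
    species : list[str] or None
        Row order of the data (required with a PhyloGrouping).
    """

    def __init__(self, grouping=None, species=None):
        self.grouping = grouping
        self.species = species

    def fit(self, X, y):
        res = partition(y, X, self.grouping, species=self.species)
        self.result_ = res
        self.percent_phylogeny_ = res.percent["phylo_only"]
        self.percent_climate_ = res.percent["climate_only"]
        self.percent_shared_ = res.percent["shared"]
        self.percent_unexplained_ = res.percent["unexplained"]
        return self


def partition_suite(
    traits: pd.DataFrame,
    climate: pd.DataFrame,
    tree: Phylogeny,
    cut_times=(59.0, 28.0),
    predictors: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Run the partition for every trait x cut-time cell.

    ``predictors`` maps trait name -> climate columns (e.g. each trait's
    selected top-model predictors); ``None`` uses all climate columns for
    every trait.  Failures are recorded per cell, not fatal.
    """
    species = list(traits.index)
    rows = []
    for cut in cut_times:
        grouping = tree.cut(cut)
        for trait in traits.columns:
            cols = (
                predictors.get(trait, list(climate.columns))
                if predictors
                else list(climate.columns)
            )
            y = traits[trait].astype(float)
            mask = y.notna()
            try:
                res = partition(
                    y[mask].to_numpy(),
                    climate.loc[y[mask].index, cols] if cols else None,
                    np.array([grouping.group_id[s] for s in y[mask].index]),
                    trait=trait,
                )
                row = res.to_row()
                row["cut_time"] = cut
            except (ValueError, ConfoundedDesignError) as exc:
                logger.warning("partition failed for %s at cut %s: %s", trait, cut, exc)
                row = {"trait": trait, "cut_time": cut, "error": str(exc)}
            rows.append(row)
    return pd.DataFrame(rows)
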