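"""Felsenstein's phylogenetically independent contrasts.

A postorder pruning pass computes, at each internal node with child values
x1, x2 on (adjusted) branch lengths b1, b2:

* raw contrast x1 - x2 and standardized contrast (x1 - x2)/sqrt(b1 + b2),
* the node's ancestral value (x1/b1 + x2/b2)/(1/b1 + 1/b2),
* the parent-edge adjustment b_node + b1 b2/(b1 + b2).

Under Brownian motion the standardized contrasts are i.i.d. normal, so
ordinary correlation between the contrasts of two traits estimates their
evolutionary correlation.  Polytomies are resolved on the fly by folding
children pairwise in a fixed order (children sorted by their smallest
descendant tip label, lexicographically) through zero-length internal
edges, so every tree yields exactly n_tips - 1 contrasts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .tree import Phylogeny, _normalize_label

logger = logging.getLogger(__name__)


class ContrastError(ValueError):
    """Raised when contrasts are undefined (missing tips, zero branches)."""


def contrasts(y, tree: Phylogeny) -> pd.DataFrame:
    """Compute independent contrasts of one trait on ``tree``.

    Parameters
    ----------
    y : mapping, pandas Series, or array aligned with ``tree.tip_labels``
        Trait value per tip.
    tree : Phylogeny

    Returns
    -------
    DataFrame with one row per contrast (n_tips - 1 rows), columns
    ``node`` (postorder id; ``*`` suffix marks polytomy fold steps),
    ``raw`` (x1 - x2), ``contrast`` (standardized), ``bl_sum`` (b1 + b2)
    and ``node_value`` (the ancestral estimate at the combined node).
    """
    labels = tree.tip_labels
    if isinstance(y, pd.Series):
        values = {str(k).strip(): float(v) for k, v in y.items()}
    elif isinstance(y, dict):
        values = {str(k).strip(): float(v) for k, v in y.items()}
    else:
        arr = np.asarray(y, dtype=float).ravel()
        if len(arr) != len(labels):
            raise ContrastError("trait vector length does not match tip count")
        values = dict(zip(labels, arr))
    missing = [l for l in labels if l not in values or not np.isfinite(values[l])]
    if missing:
        raise ContrastError(f"missing trait values for tips: {missing[:10]}")

    dt = tree.dendropy_tree
    state: dict = {}  # node -> (value, pending extra length, min tip label)
    records = []
    node_ids = {n: i for i, n in enumerate(dt.postorder_node_iter())}

    for node in dt.postorder_node_iter():
        if node.is_leaf():
            label = _normalize_label(str(node.taxon.label))
            state[node] = (values[label], 0.0, label)
            continue
        children = sorted(
            node.child_nodes(), key=lambda c: state[c][2]
        )
        stack = []
        for c in children:
            v, extra, ml = state[c]
            stack.append((v, float(c.edge.length) + extra, ml))
        fold = 0
        while len(stack) > 1:
            (v1, b1, m1), (v2, b2, m2) = stack[0], stack[1]
            s = b1 + b2
            if s <= 0:
                raise ContrastError(
                    f"zero combined branch length at node {node_ids[node]}"
                )
            raw = v1 - v2
            vnew = (v1 * b2 + v2 * b1) / s
            records.append(
                {
                    "node": f"{node_ids[node]}" + ("*" * fold),
                    "raw": raw,
                    "contrast": raw / np.sqrt(s),
                    "bl_sum": s,
                    "node_value": vnew,
                }
            )
            stack = [(vnew, b1 * b2 / s, min(m1, m2))] + stack[2:]
            fold += 1
        state[node] = stack[0]

    return pd.DataFrame(records)


class IndependentContrasts(TransformerMixin, BaseEstimator):
    """Transformer mapping tip trait values to standardized contrasts.

    ``transform`` accepts a species x traits DataFrame (index = tip labels)
    and returns a contrasts x traits DataFrame on a shared node set, ready
    for :func:`pic_correlation`.
    """

    def __init__(self, tree: Phylogeny = None):
        self.tree = tree

    def fit(self, X=None, y=None):
        if self.tree is None:
            raise ValueError("a tree is required")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.tree is None:
            raise ValueError("a tree is required")
        out = {}
        index = None
        for col in X.columns:
            cs = contrasts(X[col], self.tree)
            out[col] = cs["contrast"].to_numpy()
            index = cs["node"]
        return pd.DataFrame(out, index=index)


def pic_correlation(contrast_table: pd.DataFrame):
    """Pairwise correlations among standardized contrasts.

    Both the plain Pearson correlation (two-sided t test, n - 2 df) and the
    through-origin correlation r0 = sum(xy)/sqrt(sum x^2 sum y^2) (t test
    with n - 1 df; the convention under which contrasts' arbitrary sign
    does not matter) are returned.

    Returns
    -------
    dict with DataFrames ``r`` and ``p`` (plain Pearson, the primary
    result) and ``r_origin`` and ``p_origin`` (through the origin).
    Constant contrast vectors give NaN cells with a logged warning.
    """
    cols = list(contrast_table.columns)
    k = len(cols)
    n = len(contrast_table)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    r0 = np.full((k, k), np.nan)
    p0 = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(r0, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            x = contrast_table[cols[i]].to_numpy()
            yv = contrast_table[cols[j]].to_numpy()
            if np.ptp(x) == 0 or np.ptp(yv) == 0:
                logger.warning("constant contrasts for %s/%s", cols[i], cols[j])
                continue
            rr, pp = stats.pearsonr(x, yv)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
            denom = np.sqrt(np.sum(x**2) * np.sum(yv**2))
            rr0 = float(np.sum(x * yv) / denom)
            df0 = n - 1
            if abs(rr0) < 1.0:
                t0 = rr0 * np.sqrt(df0 / (1.0 - rr0**2))
                pp0 = 2.0 * stats.t.sf(abs(t0), df0)
            else:
                pp0 = 0.0
            r0[i, j] = r0[j, i] = rr0
            p0[i, j] = p0[j, i] = pp0
    mk = lambda m: pd.DataFrame(m, index=cols, columns=cols)  # noqa: E731
    return {"r": mk(r), "p": mk(p), "r_origin": mk(r0), "p_origin": mk(p0)}
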