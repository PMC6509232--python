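"""Phylogeny handling: Newick I/O, phylogenetic covariance matrices,
Pagel's lambda branch-length transform, and divergence-time groupings.

The tree is consumed as given (a time-calibrated ultrametric phylogeny with
branch lengths in millions of years); no inference or dating happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

#: relative tolerance on root-to-tip depth used to declare a tree ultrametric
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a Newick source cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass(frozen=True)
class PhyloCovariance:
    """Species x species matrix of shared root-to-MRCA path lengths (My).

    ``matrix[i, j]`` is the branch length shared by species ``i`` and ``j``
    from the root down to their most recent common ancestor; the diagonal
    holds root-to-tip depths.  Under Brownian motion this matrix, scaled by
    the evolutionary rate, is the covariance of tip trait values.
    """

    species: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.species):
            raise ValueError("covariance matrix must be square and match species")
        if not np.allclose(m, m.T, rtol=1e-10, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.species)

    def subset(self, species: list[str]) -> "PhyloCovariance":
        """Restrict to and reorder by ``species``."""
        index = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in index]
        if missing:
            raise KeyError(f"species not in covariance matrix: {missing}")
        idx = np.array([index[s] for s in species])
        return PhyloCovariance(tuple(species), self.matrix[np.ix_(idx, idx)])

    def __array__(self, dtype=None, copy=None):
        return np.array(self.matrix, dtype=dtype)


@dataclass(frozen=True)
class PhyloGrouping:
    """Assignment of tips to clades obtained by cutting the tree at a
    divergence time (My before present).

    Two tips share a group iff their MRCA is at or more recent than
    ``cut_time`` (inclusive cut).
    """

    cut_time: float
    group_id: dict[str, int]
    n_groups: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n_groups", len(set(self.group_id.values())))

    def labels(self, species: list[str]) -> np.ndarray:
        return np.array([self.group_id[s] for s in species])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"species": list(self.group_id), "group_id": list(self.group_id.values())}
        )


def _normalize_label(label: str) -> str:
    return " ".join(label.replace("'", "").replace('"', "").split())


class Phylogeny:
    """A rooted, ultrametric (within tolerance) phylogeny with branch
    lengths in millions of years, wrapping a :class:`dendropy.Tree`.
    """

    def __init__(self, tree: dendropy.Tree, ultrametric_rtol: float = ULTRAMETRIC_RTOL):
        self._tree = tree
        self._rtol = ultrametric_rtol
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path, **kwargs) -> "Phylogeny":
        """Parse a Newick file (or literal string containing ';')."""
        text = str(source)
        looks_like_path = "(" not in text and "\n" not in text
        if looks_like_path or (len(text) < 4096 and Path(text).exists()):
            text = Path(text).read_text()
        return cls.from_string(text, **kwargs)

    @classmethod
    def from_string(cls, newick: str, **kwargs) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except (dendropy.utility.error.DataParseError, Exception) as exc:
            name = type(exc).__name__
            if "Duplicate" in name:
                raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree, **kwargs)

    # -- validation --------------------------------------------------------

    def _validate(self):
        leaves = list(self._tree.leaf_node_iter())
        if not leaves:
            raise TreeValidationError("tree has no tips")
        labels = []
        for leaf in leaves:
            if leaf.taxon is None or not str(leaf.taxon.label).strip():
                raise TreeValidationError("tip with empty label")
            labels.append(_normalize_label(str(leaf.taxon.label)))
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dups}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            bl = node.edge.length
            if bl is None:
                raise TreeValidationError("branch without length")
            if not np.isfinite(bl) or bl < 0:
                raise TreeValidationError(f"invalid branch length {bl!r}")

        # cache root distances and tip ordering
        self._root_dist: dict = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                # a root edge, if present in the source, is not shared history
                self._root_dist[node] = 0.0
            else:
                self._root_dist[node] = self._root_dist[parent] + float(node.edge.length)
        self._leaves = leaves
        self._labels = labels
        depths = np.array([self._root_dist[l] for l in leaves])
        self._depth = float(depths.mean())
        self._ultrametric = bool(
            np.all(np.abs(depths - self._depth) <= self._rtol * max(self._depth, 1.0))
        )

    # -- basic properties --------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def depth(self) -> float:
        """Mean root-to-tip distance (My)."""
        return self._depth

    @property
    def is_ultrametric(self) -> bool:
        return self._ultrametric

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def node_age(self, node) -> float:
        """Time before present of ``node`` (0 for tips of an ultrametric tree)."""
        return self._depth - self._root_dist[node]

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- covariance --------------------------------------------------------

    def vcv(self, species_subset: list[str] | None = None) -> PhyloCovariance:
        """Phylogenetic variance-covariance matrix: shared path length from
        the root to each pair's MRCA, tip depth on the diagonal."""
        labels = self._labels
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        tips_below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tips_below[node] = np.array(
                    [index[_normalize_label(str(node.taxon.label))]]
                )
                continue
            child_sets = [tips_below[c] for c in node.child_nodes()]
            d = self._root_dist[node]
            for i in range(len(child_sets)):
                for j in range(i + 1, len(child_sets)):
                    C[np.ix_(child_sets[i], child_sets[j])] = d
                    C[np.ix_(child_sets[j], child_sets[i])] = d
            tips_below[node] = np.concatenate(child_sets)
        for leaf in self._leaves:
            i = index[_normalize_label(str(leaf.taxon.label))]
            C[i, i] = self._root_dist[leaf]
        cov = PhyloCovariance(tuple(labels), C)
        if species_subset is not None:
            cov = cov.subset(list(species_subset))
        return cov

    # -- grouping ----------------------------------------------------------

    def cut(self, cut_time: float) -> PhyloGrouping:
        """Group tips by cutting the tree at ``cut_time`` My before present.

        A group is a maximal clade whose root is at or more recent than the
        cut (inclusive); a terminal edge spanning the cut yields a singleton.
        """
        if not self.is_ultrametric:
            raise TreeValidationError("grouping undefined on a non-ultrametric tree")
        if not (0 < cut_time < self._depth):
            raise ValueError(
                f"cut_time must lie in (0, {self._depth:g}), got {cut_time!r}"
            )
        tol = self._rtol * max(self._depth, 1.0)
        group_id: dict[str, int] = {}
        next_id = [0]

        stack = [self._tree.seed_node]
        while stack:
            node = stack.pop()
            if self.node_age(node) <= cut_time + tol:
                gid = next_id[0]
                next_id[0] += 1
                for leaf in node.leaf_iter():
                    group_id[_normalize_label(str(leaf.taxon.label))] = gid
            else:
                stack.extend(node.child_nodes())
        return PhyloGrouping(cut_time, group_id)

    # -- pruning -----------------------------------------------------------

    def prune(self, species: list[str]) -> "Phylogeny":
        """Return the subtree induced by ``species`` (branch lengths kept)."""
        keep = set(species)
        unknown = keep - set(self._labels)
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        tree = self._tree.extract_tree(
            node_filter_fn=lambda nd: (not nd.is_leaf())
            or _normalize_label(str(nd.taxon.label)) in keep,
            suppress_unifurcations=True,
        )
        return Phylogeny(tree, ultrametric_rtol=self._rtol)


# -- functional wrappers ---------------------------------------------------


def read_newick(path: str | Path) -> Phylogeny:
    """Read and validate a Newick phylogeny."""
    return Phylogeny.from_newick(path)


def vcv_matrix(tree: Phylogeny, species_subset: list[str] | None = None) -> PhyloCovariance:
    return tree.vcv(species_subset)


def lambda_transform(C: PhyloCovariance | np.ndarray, lam: float):
    """Scale the off-diagonal of a phylogenetic covariance by Pagel's lambda.

    lambda = 1 leaves the matrix unchanged (pure Brownian motion); lambda = 0
    removes all shared history (star phylogeny).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam!r}")
    if isinstance(C, PhyloCovariance):
        m = C.matrix
    else:
        m = np.asarray(C, dtype=float)
    out = lam * m + (1.0 - lam) * np.diag(np.diag(m))
    if isinstance(C, PhyloCovariance):
        return PhyloCovariance(C.species, out)
    return out


def cut_tree(tree: Phylogeny, cut_time: float) -> PhyloGrouping:
    return tree.cut(cut_time)
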