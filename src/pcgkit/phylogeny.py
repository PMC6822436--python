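"""Rooted phylogenies, tree/table alignment, p-distances and threshold-ladder
dendrograms.

A :class:`Phylogeny` wraps a scikit-bio ``TreeNode`` and adds the small
amount of bookkeeping the core-group machinery needs: validated unique
leaf labels, default branch lengths, and node heights (the maximum
path length from a node down to any of its descendant leaves).

The same class represents agglomerative "ladder" dendrograms built from a
pairwise distance matrix: there, a node's height is the distance at which
its children merged, so cutting the tree at a threshold ``t`` reproduces
the flat clustering at distance ``t``.  This embodies a whole continuum of
similarity clustering thresholds in a single tree, which is how
operational taxonomic units of varying depth can be screened for coreness
without committing to one fixed similarity cutoff.
"""

from __future__ import annotations

import io as _io
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .table import AbundanceTable

__all__ = [
    "Phylogeny",
    "TreeFormatError",
    "align_tree_and_table",
    "p_distance_matrix",
    "ladder_dendrogram",
    "cut_dendrogram",
]

logger = logging.getLogger(__name__)


class TreeFormatError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


class Phylogeny:
    """A rooted (possibly multifurcating) phylogeny with node heights.

    Branch lengths missing from the input default to 1.0, so trees given
    as bare topologies still yield meaningful clade depths.
    """

    def __init__(self, tree: TreeNode):
        names = [t.name for t in tree.tips()]
        if tree.is_tip():
            raise TreeFormatError("tree must have at least 2 leaves")
        if any(n is None or n == "" for n in names):
            raise TreeFormatError("all leaves must be labeled")
        if len(set(names)) != len(names):
            seen, dups = set(), set()
            for n in names:
                if n in seen:
                    dups.add(n)
                seen.add(n)
            raise TreeFormatError(f"duplicate leaf label(s): {sorted(dups)[:10]}")
        for node in tree.traverse(include_self=True):
            if node.is_root():
                node.length = None
            elif node.length is None:
                node.length = 1.0
            elif node.length < 0:
                raise TreeFormatError("negative branch length")
        self._tree = tree
        self._heights: dict[int, float] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                self._heights[id(node)] = 0.0
            else:
                self._heights[id(node)] = max(
                    self._heights[id(c)] + c.length for c in node.children
                )

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a Newick string or a path to a Newick file."""
        text = source
        if "(" not in source:  # looks like a path
            with open(source) as fh:
                text = fh.read()
        try:
            tree = TreeNode.read(_io.StringIO(text))
        except Exception as exc:  # skbio raises several parser error types
            raise TreeFormatError(f"could not parse Newick input: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self._tree.write(buf)
        return buf.getvalue().strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    # ------------------------------------------------------------------
    @property
    def root(self) -> TreeNode:
        return self._tree

    @property
    def taxa(self) -> list[str]:
        """Leaf labels in tree (left-to-right) order."""
        return [t.name for t in self._tree.tips()]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def height(self, node: TreeNode) -> float:
        return self._heights[id(node)]

    @property
    def root_height(self) -> float:
        return self.height(self._tree)

    def postorder(self) -> Iterable[TreeNode]:
        return self._tree.postorder(include_self=True)

    def leaf_set(self, node: TreeNode) -> frozenset[str]:
        if node.is_tip():
            return frozenset([node.name])
        return frozenset(node.subset())

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every node (leaves included), in postorder."""
        return [self.leaf_set(n) for n in self.postorder()]

    def shear(self, labels: Iterable[str]) -> "Phylogeny":
        """Restrict to the given leaves, collapsing unary internal nodes
        (branch lengths are summed through collapsed nodes)."""
        labels = set(labels)
        missing = labels - set(self.taxa)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)[:10]}")
        if len(labels) < 2:
            raise TreeFormatError("cannot shear to fewer than 2 leaves")
        return Phylogeny(self._tree.copy().shear(labels))

    def patristic_distances(self) -> pd.DataFrame:
        """All pairwise tip-to-tip path lengths, as a labeled square frame."""
        dm = self._tree.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))

    def __repr__(self) -> str:
        return f"Phylogeny({self.n_taxa} leaves, root height {self.root_height:g})"


# ----------------------------------------------------------------------
def align_tree_and_table(
    tree: Phylogeny,
    table: AbundanceTable,
    on_mismatch: str = "error",
) -> tuple[Phylogeny, AbundanceTable]:
    """Make the tree's leaf set and the table's taxon set identical.

    With ``on_mismatch="error"`` any asymmetric difference raises.  With
    ``"prune_and_drop"`` the tree is sheared and the table subset to the
    intersection of the two label sets; dropped identifiers are logged.
    Returned taxa follow the (sheared) tree's leaf order.
    """
    tree_set = set(tree.taxa)
    table_set = set(table.taxon_ids)
    common = tree_set & table_set
    if not common:
        raise ValueError("tree and table share no taxon identifiers")
    only_tree = sorted(tree_set - table_set)
    only_table = sorted(table_set - tree_set)
    if on_mismatch == "error":
        if only_tree or only_table:
            raise ValueError(
                "tree/table taxon mismatch; "
                f"tree-only: {only_tree[:10]}, table-only: {only_table[:10]}"
            )
    elif on_mismatch == "prune_and_drop":
        if only_tree:
            logger.warning("pruning %d leaves absent from table", len(only_tree))
            tree = tree.shear(common)
        if only_table:
            logger.warning("dropping %d table taxa absent from tree", len(only_table))
    else:
        raise ValueError(f"unknown on_mismatch policy: {on_mismatch!r}")
    order = [t for t in tree.taxa if t in common]
    table = table.select_taxa(order)
    return tree, table


# ----------------------------------------------------------------------
_GAPS = (ord("-"), ord("."))


def p_distance_matrix(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise p-distances (mismatches / compared positions) for aligned
    sequences, with pairwise deletion of gapped columns.

    Columns where either sequence has a gap ('-' or '.') are excluded for
    that pair.  A pair with zero comparable positions is an error.  The
    result is a symmetric matrix in [0, 1] with zero diagonal; note that
    p-distances need not satisfy the triangle inequality.
    """
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.frombuffer(
        "".join(seqs[l].upper() for l in labels).encode("ascii"), dtype=np.uint8
    ).reshape(len(labels), lengths.pop())
    is_gap = (arr == _GAPS[0]) | (arr == _GAPS[1])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_gap[i] | is_gap[j])
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no "
                    "comparable (ungapped) positions"
                )
            mism = int((arr[i, ok] != arr[j, ok]).sum())
            d[i, j] = d[j, i] = mism / comparable
    return pd.DataFrame(d, index=labels, columns=labels)


# ----------------------------------------------------------------------
def _validate_square(dist: pd.DataFrame) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("distance matrix must be square with >= 2 items")
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix row and column labels differ")
    if np.any(d < 0):
        raise ValueError("negative distance")
    if np.max(np.abs(d - d.T)) > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond tolerance 1e-9")
    if np.any(np.abs(np.diag(d)) > 1e-9):
        raise ValueError("distance matrix diagonal must be zero")
    return (d + d.T) / 2.0


def ladder_dendrogram(dist: pd.DataFrame, linkage: str = "average") -> Phylogeny:
    """Agglomerative dendrogram over a labeled distance matrix, returned as
    a :class:`Phylogeny` whose node heights equal merge distances.

    Average (UPGMA-style) or complete linkage; both are monotone, so
    heights never decrease from leaves to root.  Ties are broken by the
    smallest pair of original item indices, making the construction
    deterministic for a given input order.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage: {linkage!r}")
    labels = [str(l) for l in dist.index]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in distance matrix")
    d = _validate_square(dist).copy()
    n = len(labels)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    heights = [0.0] * n
    sizes = [1] * n
    reps = list(range(n))  # smallest original item index per cluster
    active = [True] * n
    np.fill_diagonal(d, np.inf)
    for _ in range(n - 1):
        idx = [i for i in range(n) if active[i]]
        sub = d[np.ix_(idx, idx)]
        m = sub.min()
        cand = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if sub[a, b] == m:
                    i, j = idx[a], idx[b]
                    lo, hi = sorted((reps[i], reps[j]))
                    cand.append((lo, hi, i, j))
        lo, hi, i, j = min(cand)
        h = float(m)
        parent = TreeNode()
        for child in (nodes[i], nodes[j]):
            parent.append(child)
        nodes[i].length = max(h - heights[i], 0.0)
        nodes[j].length = max(h - heights[j], 0.0)
        # Lance-Williams update into slot i
        for k in range(n):
            if active[k] and k not in (i, j):
                if linkage == "average":
                    new = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (
                        sizes[i] + sizes[j]
                    )
                else:
                    new = max(d[i, k], d[j, k])
                d[i, k] = d[k, i] = new
        nodes[i] = parent
        heights[i] = h
        sizes[i] += sizes[j]
        reps[i] = min(reps[i], reps[j])
        active[j] = False
        d[j, :] = np.inf
        d[:, j] = np.inf
    root = nodes[[i for i in range(n) if active[i]][0]]
    return Phylogeny(root)


def cut_dendrogram(dendro: Phylogeny, threshold: float) -> list[frozenset[str]]:
    """Flat clusters at a distance threshold: the leaf sets of the maximal
    nodes whose height is <= threshold (within a 1e-12 guard)."""
    tol = 1e-12
    clusters: list[frozenset[str]] = []

    def descend(node: TreeNode) -> None:
        if dendro.height(node) <= threshold + tol:
            clusters.append(dendro.leaf_set(node))
        else:
            for c in node.children:
                descend(c)

    descend(dendro.root)
    return sorted(clusters, key=lambda s: sorted(s)[0])
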