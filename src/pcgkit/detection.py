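"""Detection of phylogenetic core groups (PCGs).

A PCG is a discrete portion of the phylogeny — a clade of any depth, down
to a single leaf — whose pooled abundance is present in all (or a stated
fraction of) samples of an ecosystem.  Operationally a PCG is a *minimal
core node*: a tree node whose clade-pooled counts pass the presence
thresholds in at least ``ceil(prevalence * n_samples)`` samples, and none
of whose proper descendants does.

Presence is pooled-then-thresholded: a clade is present in a sample when
the summed counts of its member taxa reach ``min_count`` reads and
``min_relabund`` relative abundance.  Pooling makes coreness monotone
rootward (a node's pooled counts are never less than a child's), which is
what makes "minimal core node" well defined: minimal core nodes of a tree
are automatically pairwise disjoint.

The defaults (``min_count=1``, ``min_relabund=0``, ``prevalence=1.0``)
encode the strict reading "present in every sample"; raising the
thresholds gives depth-robust variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .phylogeny import Phylogeny, align_tree_and_table
from .table import AbundanceTable

__all__ = [
    "PresenceParams",
    "PCG",
    "PCGSet",
    "PCGSummary",
    "presence_matrix",
    "core_nodes",
    "find_pcgs",
    "pcg_summary",
    "PCGDetector",
]

NO_PCG = "none"


@dataclass(frozen=True)
class PresenceParams:
    """Thresholds defining when a clade counts as present in a sample.

    min_count: minimum pooled reads; min_relabund: minimum pooled relative
    abundance in [0, 1); prevalence: fraction of samples, in (0, 1], that
    must show the clade for it to be core.
    """

    min_count: int = 1
    min_relabund: float = 0.0
    prevalence: float = 1.0

    def __post_init__(self):
        if self.min_count < 0 or self.min_count != int(self.min_count):
            raise ValueError("min_count must be a non-negative integer")
        if not (0 <= self.min_relabund < 1):
            raise ValueError("min_relabund must be in [0, 1)")
        if not (0 < self.prevalence <= 1):
            raise ValueError("prevalence must be in (0, 1]")
        if self.min_count < 1 and self.min_relabund <= 0:
            raise ValueError(
                "at least one of min_count >= 1 or min_relabund > 0 is required; "
                "a clade with zero pooled signal is never present"
            )

    def n_required(self, n_samples: int) -> int:
        """Integral prevalence threshold, ceil(prevalence * S) with a guard
        against float representation pushing e.g. 0.9*10 above 9."""
        return max(1, math.ceil(self.prevalence * n_samples - 1e-9))


@dataclass(frozen=True)
class PCG:
    """One detected phylogenetic core group (a minimal core clade)."""

    member_taxa: tuple[str, ...]  # lexicographically sorted
    depth: float
    prevalence: float
    pooled_relabund: pd.Series = field(compare=False)  # per sample

    @property
    def n_taxa(self) -> int:
        return len(self.member_taxa)

    @property
    def mean_relabund(self) -> float:
        return float(self.pooled_relabund.mean())


@dataclass(frozen=True)
class PCGSet:
    """Detected PCGs, sorted by their first (smallest) member label."""

    pcgs: tuple[PCG, ...]
    params: PresenceParams

    def __len__(self) -> int:
        return len(self.pcgs)

    def __iter__(self):
        return iter(self.pcgs)

    def __getitem__(self, i) -> PCG:
        return self.pcgs[i]

    @property
    def ids(self) -> list[str]:
        return [f"pcg_{i + 1}" for i in range(len(self.pcgs))]

    def member_sets(self) -> list[frozenset[str]]:
        return [frozenset(p.member_taxa) for p in self.pcgs]

    def membership(self, taxon_ids: Sequence[str]) -> pd.Series:
        """Map each taxon to its PCG id, or to "none"."""
        lookup = {}
        for pid, p in zip(self.ids, self.pcgs):
            for t in p.member_taxa:
                lookup[t] = pid
        return pd.Series(
            [lookup.get(t, NO_PCG) for t in taxon_ids], index=list(taxon_ids), name="pcg_id"
        )


# ----------------------------------------------------------------------
def presence_matrix(table: AbundanceTable, params: PresenceParams) -> pd.DataFrame:
    """Per-taxon boolean presence: counts >= min_count AND relative
    abundance >= min_relabund.  Samples with zero total are an error (drop
    or reject them upstream)."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"sample(s) with zero total count: {empty[:10]}")
    c = table.counts
    present = (c >= params.min_count) & (
        c / totals[:, None] >= params.min_relabund
    )
    return pd.DataFrame(present, index=table.sample_ids, columns=table.taxon_ids)


def _check_aligned(tree: Phylogeny, table: AbundanceTable) -> None:
    if list(tree.taxa) != list(table.taxon_ids):
        raise ValueError(
            "tree and table are not aligned (run align_tree_and_table first)"
        )


def _pooled_presence(tree, table, params):
    """Postorder sweep accumulating clade-pooled counts; yields for every
    node its (pooled counts vector, per-sample presence vector, core flag,
    child core flags)."""
    totals = table.sample_totals().astype(float)
    if np.any(totals == 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"sample(s) with zero total count: {empty[:10]}")
    col = {t: i for i, t in enumerate(table.taxon_ids)}
    counts = table.counts
    need = params.n_required(table.n_samples)
    pooled: dict[int, np.ndarray] = {}
    info = []
    for node in tree.postorder():
        if node.is_tip():
            vec = counts[:, col[node.name]].astype(np.int64)
        else:
            vec = np.sum([pooled[id(c)] for c in node.children], axis=0)
        pooled[id(node)] = vec
        present = (vec >= params.min_count) & (vec / totals >= params.min_relabund)
        is_core = int(present.sum()) >= need
        info.append((node, vec, present, is_core))
    return info, totals


def core_nodes(tree: Phylogeny, table: AbundanceTable, params: PresenceParams) -> list:
    """All tree nodes whose clade-pooled counts pass the presence
    thresholds in at least ceil(prevalence * S) samples."""
    _check_aligned(tree, table)
    info, _ = _pooled_presence(tree, table, params)
    return [node for node, _, _, is_core in info if is_core]


def find_pcgs(
    tree: Phylogeny, table: AbundanceTable, params: PresenceParams | None = None
) -> PCGSet:
    """Detect PCGs: the minimal core nodes of the phylogeny.

    One postorder pass pools counts up the tree (O(S * n_nodes)); a node
    is reported iff it is core and none of its children is (by coreness
    monotonicity that is equivalent to no proper descendant being core).
    Structural guarantees — monotonicity of coreness, minimality and
    pairwise disjointness of the result — are re-checked on every run.
    """
    if params is None:
        params = PresenceParams()
    _check_aligned(tree, table)
    info, totals = _pooled_presence(tree, table, params)
    core_flag = {id(node): is_core for node, _, _, is_core in info}
    pcgs = []
    for node, vec, present, is_core in info:
        # coreness must be monotone rootward; violation would mean the
        # pooling logic is broken
        if not node.is_root() and is_core and not core_flag[id(node.parent)]:
            raise RuntimeError("internal error: coreness not monotone rootward")
        if is_core and not any(core_flag[id(c)] for c in node.children):
            members = tuple(sorted(tree.leaf_set(node)))
            pcgs.append(
                PCG(
                    member_taxa=members,
                    depth=float(tree.height(node)),
                    prevalence=float(present.mean()),
                    pooled_relabund=pd.Series(
                        vec / totals, index=table.sample_ids, name="pooled_relabund"
                    ),
                )
            )
    pcgs.sort(key=lambda p: p.member_taxa[0])
    seen: set[str] = set()
    for p in pcgs:
        if seen.intersection(p.member_taxa):
            raise RuntimeError("internal error: PCG member sets overlap")
        seen.update(p.member_taxa)
    return PCGSet(pcgs=tuple(pcgs), params=params)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PCGSummary:
    """Per-PCG summary plus the community fraction the PCGs jointly cover."""

    per_pcg: pd.DataFrame  # pcg_id, n_taxa, depth, prevalence, mean_relabund
    per_sample_relabund: pd.DataFrame  # samples x pcg ids
    dominants: pd.DataFrame  # samples x pcg ids, dominant member label
    coverage_per_sample: pd.Series
    coverage: float  # mean over samples of the union's pooled fraction
    taxon_ids: tuple[str, ...] = ()  # full taxon universe of the source table


def pcg_summary(pcgs: PCGSet, table: AbundanceTable, tree: Phylogeny) -> PCGSummary:
    """Summarize a detected PCG set against the table it came from.

    The per-sample dominant member of a PCG is the member taxon with the
    highest count (ties broken by the lexicographically smallest label —
    member lists are stored sorted, so the first argmax wins).
    """
    totals = table.sample_totals().astype(float)
    ids = pcgs.ids
    rel = pd.DataFrame(index=table.sample_ids, columns=ids, dtype=float)
    dom = pd.DataFrame(index=table.sample_ids, columns=ids, dtype=object)
    rows = []
    union: set[str] = set()
    for pid, p in zip(ids, pcgs):
        members = list(p.member_taxa)
        union.update(members)
        sub = table.data.loc[:, members]
        rel[pid] = sub.sum(axis=1) / totals
        dom[pid] = [members[i] for i in np.argmax(sub.to_numpy(), axis=1)]
        rows.append(
            {
                "pcg_id": pid,
                "n_taxa": p.n_taxa,
                "depth": p.depth,
                "prevalence": p.prevalence,
                "mean_relabund": p.mean_relabund,
                "member_taxa": ";".join(members),
            }
        )
    if union:
        cov = table.data.loc[:, sorted(union)].sum(axis=1) / totals
    else:
        cov = pd.Series(0.0, index=table.sample_ids)
    cov.name = "coverage"
    per_pcg = pd.DataFrame(
        rows,
        columns=["pcg_id", "n_taxa", "depth", "prevalence", "mean_relabund", "member_taxa"],
    )
    return PCGSummary(
        per_pcg=per_pcg,
        per_sample_relabund=rel,
        dominants=dom,
        coverage_per_sample=cov,
        coverage=float(cov.mean()),
        taxon_ids=tuple(table.taxon_ids),
    )


# ----------------------------------------------------------------------
def _coerce_table(X, tree: Phylogeny | None) -> AbundanceTable:
    if isinstance(X, AbundanceTable):
        return X
    if isinstance(X, pd.DataFrame):
        return AbundanceTable.from_dataframe(X)
    arr = np.asarray(X)
    if tree is not None and arr.ndim == 2 and arr.shape[1] == tree.n_taxa:
        return AbundanceTable(
            arr, [f"s{i + 1}" for i in range(arr.shape[0])], tree.taxa
        )
    raise TypeError(
        "X must be an AbundanceTable, a samples x taxa DataFrame, or an array "
        "whose columns match the tree's leaves"
    )


class PCGDetector(TransformerMixin, BaseEstimator):
    """Scikit-learn style detector of phylogenetic core groups.

    Parameters
    ----------
    tree : Phylogeny
        Rooted phylogeny (or ladder dendrogram) over the table's taxa.
    min_count, min_relabund, prevalence
        Presence thresholds; see :class:`PresenceParams`.
    on_mismatch : {"error", "prune_and_drop"}
        How to reconcile tree leaves with table taxa.
    allow_empty_samples : bool
        Drop all-zero samples instead of raising.

    After ``fit``, ``pcgs_`` holds the detected :class:`PCGSet`,
    ``membership_`` maps every taxon to its PCG (or "none"),
    ``summary_`` is the :class:`PCGSummary`, and ``transform`` projects a
    count table onto per-PCG pooled relative abundances.

    Examples
    --------
    >>> det = PCGDetector(tree=tree).fit(counts_df)
    >>> det.n_pcgs_, det.coverage_
    """

    def __init__(
        self,
        tree: Phylogeny | None = None,
        min_count: int = 1,
        min_relabund: float = 0.0,
        prevalence: float = 1.0,
        on_mismatch: str = "error",
        allow_empty_samples: bool = False,
    ):
        self.tree = tree
        self.min_count = min_count
        self.min_relabund = min_relabund
        self.prevalence = prevalence
        self.on_mismatch = on_mismatch
        self.allow_empty_samples = allow_empty_samples

    def _params(self) -> PresenceParams:
        return PresenceParams(
            min_count=self.min_count,
            min_relabund=self.min_relabund,
            prevalence=self.prevalence,
        )

    def fit(self, X, y=None):
        if self.tree is None:
            raise ValueError("PCGDetector requires a tree")
        table = _coerce_table(X, self.tree)
        if self.allow_empty_samples:
            table, dropped = table.drop_empty_samples()
            self.dropped_samples_ = dropped
        else:
            self.dropped_samples_ = []
        tree, table = align_tree_and_table(self.tree, table, self.on_mismatch)
        self.tree_ = tree
        self.table_ = table
        self.pcgs_ = find_pcgs(tree, table, self._params())
        self.summary_ = pcg_summary(self.pcgs_, table, tree)
        self.membership_ = self.pcgs_.membership(table.taxon_ids)
        self.n_pcgs_ = len(self.pcgs_)
        self.coverage_ = self.summary_.coverage
        return self

    def transform(self, X) -> pd.DataFrame:
        """Pooled relative abundance of each fitted PCG in each sample."""
        if not hasattr(self, "pcgs_"):
            raise ValueError("PCGDetector is not fitted yet")
        table = _coerce_table(X, self.tree_)
        totals = table.sample_totals().astype(float)
        if np.any(totals == 0):
            raise ValueError("cannot transform samples with zero total count")
        out = pd.DataFrame(index=table.sample_ids, columns=self.pcgs_.ids, dtype=float)
        for pid, p in zip(self.pcgs_.ids, self.pcgs_):
            members = [t for t in p.member_taxa if t in table.data.columns]
            out[pid] = (
                table.data.loc[:, members].sum(axis=1) / totals if members else 0.0
            )
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.pcgs_.ids, dtype=object)
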