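"""Independent oracles and random-instance generators for the test suite.

Everything here deliberately avoids the code paths under test: coreness is
evaluated clade-by-clade from raw column sums, minimality by explicit
subset checks, flat clustering by naive threshold agglomeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from pcgkit import AbundanceTable, Phylogeny, PresenceParams, simulate_tree


def clade_is_core(table: AbundanceTable, members, params: PresenceParams) -> bool:
    """Direct per-clade core criterion from raw counts."""
    cols = [table.taxon_ids.index(t) for t in members]
    pooled = table.counts[:, cols].sum(axis=1)
    totals = table.counts.sum(axis=1)
    present = (pooled >= params.min_count) & (pooled / totals >= params.min_relabund)
    need = max(1, math.ceil(params.prevalence * table.n_samples - 1e-9))
    return int(present.sum()) >= need


def brute_force_pcgs(tree: Phylogeny, table: AbundanceTable, params: PresenceParams):
    """All minimal core clades by exhaustive enumeration over every tree
    node: keep core clades having no core proper-subset clade."""
    clades = sorted(set(tree.clades()), key=lambda c: (len(c), sorted(c)))
    core = [c for c in clades if clade_is_core(table, c, params)]
    minimal = [
        c for c in core if not any(d < c for d in core)  # d proper subset of c
    ]
    return set(minimal)


def random_instance(seed: int):
    """Random bifurcating tree (<=12 taxa), sparse counts (<=8 samples) and
    randomized presence thresholds, per the detection-oracle protocol."""
    rng = np.random.default_rng(seed)
    n_taxa = int(rng.integers(3, 13))
    n_samples = int(rng.integers(2, 9))
    tree = simulate_tree(n_taxa, int(rng.integers(2**31)))
    counts = rng.integers(0, 6, size=(n_samples, n_taxa)) * (
        rng.random((n_samples, n_taxa)) < 0.5
    )
    for i in range(n_samples):  # presence logic requires nonzero sample totals
        if counts[i].sum() == 0:
            counts[i, int(rng.integers(n_taxa))] = int(rng.integers(1, 6))
    table = AbundanceTable(counts, [f"s{i}" for i in range(n_samples)], tree.taxa)
    min_count = int(rng.integers(0, 4))
    min_relabund = float(rng.choice([0.0, 0.01, 0.05, 0.2]))
    if min_count == 0 and min_relabund == 0.0:
        min_count = 1
    prevalence = float(rng.choice([0.5, 0.75, 1.0]))
    params = PresenceParams(
        min_count=min_count, min_relabund=min_relabund, prevalence=prevalence
    )
    return tree, table, params


def brute_force_flat_clusters(dist: np.ndarray, labels, threshold: float, linkage: str):
    """Naive threshold agglomeration: repeatedly merge the closest pair of
    clusters while the linkage distance is <= threshold."""
    clusters = [frozenset([l]) for l in labels]
    pos = {l: i for i, l in enumerate(labels)}

    def d(a, b):
        vals = [dist[pos[x], pos[y]] for x in a for y in b]
        return float(np.mean(vals) if linkage == "average" else np.max(vals))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dd = d(clusters[i], clusters[j])
                key = (dd, min(pos[x] for x in clusters[i] | clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dd, _), i, j = best
        if dd > threshold + 1e-12:
            break
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return set(clusters)


def exhaustive_mpd_null(dmat: np.ndarray, n_present: int):
    """Exact null mean/sd of unweighted MPD over all same-size subsets of
    the taxon pool (the label-shuffle null, enumerated)."""
    n_taxa = dmat.shape[0]
    vals = []
    for subset in itertools.combinations(range(n_taxa), n_present):
        sub = dmat[np.ix_(subset, subset)]
        iu = np.triu_indices(n_present, 1)
        vals.append(sub[iu].mean())
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=0))
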