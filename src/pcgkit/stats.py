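"""Community-level statistics: phylogenetic clustering signal and
intra-group occupant turnover.

The framework behind this package makes two observable predictions about
communities assembled through phylogenetically conserved niches:

* samples should be *phylogenetically clustered* — co-occurring taxa are
  more related than a random draw from the taxon pool.  This is measured
  by the standardized effect size of the mean pairwise patristic distance
  (SES-MPD) against a taxon-label-shuffle null; negative SES indicates
  clustering, positive indicates overdispersion.
* within each phylogenetic core group, *which* member occupies a sample
  should be stochastic (neutral within-niche lotteries), so the identity
  of the dominant member should turn over across samples.  This is
  measured as 1 minus the modal frequency of the per-sample dominant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .detection import PCGSet
from .phylogeny import Phylogeny
from .table import AbundanceTable

__all__ = ["ses_mpd", "pcg_turnover", "PhylogeneticSignal"]


def _mpd(dists: np.ndarray, weights: np.ndarray | None) -> float:
    iu = np.triu_indices(dists.shape[0], 1)
    vals = dists[iu]
    if weights is None:
        return float(vals.mean())
    pw = weights[iu[0]] * weights[iu[1]]
    return float((vals * pw).sum() / pw.sum())


def ses_mpd(
    table: AbundanceTable,
    tree: Phylogeny,
    permutations: int = 999,
    weighted: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample SES of mean pairwise patristic distance.

    The null shuffles taxon labels on the patristic distance matrix: each
    permutation maps the sample's set of present taxa to a uniformly
    random same-sized subset of the full taxon pool (abundance weights, if
    used, travel with the original taxa).  Sample richness is preserved by
    construction.  SES = (observed - null mean) / null sd; when the null
    sd is zero (e.g. a sample containing every taxon, unweighted) SES is
    defined as 0 and flagged degenerate.  Samples with fewer than two
    present taxa are flagged undefined rather than raising.

    Returns a frame indexed by sample with columns ``n_present``,
    ``mpd_obs``, ``null_mean``, ``null_sd``, ``ses``, ``flag``; the
    permutation count and seed are stored in ``.attrs``.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if list(tree.taxa) != list(table.taxon_ids):
        raise ValueError("tree and table are not aligned")
    dmat = tree.patristic_distances().loc[table.taxon_ids, table.taxon_ids].to_numpy()
    n_taxa = table.n_taxa
    counts = table.counts
    totals = table.sample_totals().astype(float)
    rng = np.random.default_rng(seed)
    rows = []
    for s_idx, sample in enumerate(table.sample_ids):
        present = np.flatnonzero(counts[s_idx] > 0)
        n = present.size
        if n < 2:
            rows.append((sample, n, np.nan, np.nan, np.nan, np.nan, "undefined"))
            continue
        w = None
        if weighted:
            w = counts[s_idx, present] / totals[s_idx]
        sub = dmat[np.ix_(present, present)]
        obs = _mpd(sub, w)
        # vectorized label shuffle: each row is a random n-subset (ordered
        # draw without replacement) of the taxon pool
        perm = np.tile(np.arange(n_taxa), (permutations, 1))
        perm = rng.permuted(perm, axis=1)[:, :n]
        iu0, iu1 = np.triu_indices(n, 1)
        vals = dmat[perm[:, iu0], perm[:, iu1]]
        if w is None:
            null = vals.mean(axis=1)
        else:
            pw = w[iu0] * w[iu1]
            null = (vals * pw).sum(axis=1) / pw.sum()
        mu = float(null.mean())
        sd = float(null.std(ddof=1))
        # identical pair sets summed in different orders leave sd at the
        # float-rounding floor; that is still a degenerate null
        if sd <= 1e-12 * max(1.0, abs(mu)):
            rows.append((sample, n, obs, mu, 0.0, 0.0, "degenerate"))
        else:
            rows.append((sample, n, obs, mu, sd, (obs - mu) / sd, "ok"))
    out = pd.DataFrame(
        rows,
        columns=["sample_id", "n_present", "mpd_obs", "null_mean", "null_sd", "ses", "flag"],
    ).set_index("sample_id")
    out.attrs["permutations"] = permutations
    out.attrs["seed"] = seed
    out.attrs["weighted"] = weighted
    return out


def pcg_turnover(pcgs: PCGSet, table: AbundanceTable) -> pd.DataFrame:
    """Occupant turnover within each PCG.

    For each PCG and each sample with nonzero pooled member counts, the
    dominant member is the member taxon with the highest count (ties go to
    the lexicographically smallest label).  ``f_mode`` is the highest
    frequency any single dominant achieves across those samples, and
    turnover = 1 - f_mode, so turnover lies in [0, 1 - 1/S].  Turnover is
    invariant to rescaling any sample's counts by a positive constant.
    """
    if len(pcgs) == 0:
        raise ValueError("PCG set is empty")
    rows = []
    for pid, p in zip(pcgs.ids, pcgs):
        members = list(p.member_taxa)  # sorted, so first argmax = smallest label
        sub = table.data.loc[:, members].to_numpy()
        pooled = sub.sum(axis=1)
        eff = np.flatnonzero(pooled > 0)
        if eff.size == 0:
            raise ValueError(
                f"PCG {pid} has zero pooled counts in every sample of this table"
            )
        dominants = [members[int(np.argmax(sub[i]))] for i in eff]
        freq = pd.Series(dominants).value_counts()
        f_mode = float(freq.iloc[0]) / len(dominants)
        rows.append(
            {
                "pcg_id": pid,
                "s_effective": int(eff.size),
                "f_mode": f_mode,
                "turnover": 1.0 - f_mode,
                "dominants": ";".join(dominants),
            }
        )
    return pd.DataFrame(rows).set_index("pcg_id")


class PhylogeneticSignal(BaseEstimator):
    """Scikit-learn style wrapper around :func:`ses_mpd`.

    After ``fit(X)``, ``results_`` holds the per-sample SES-MPD frame and
    ``mean_ses_`` the mean SES over samples with a defined value.
    """

    def __init__(
        self,
        tree: Phylogeny | None = None,
        permutations: int = 999,
        weighted: bool = False,
        random_state: int | None = None,
    ):
        self.tree = tree
        self.permutations = permutations
        self.weighted = weighted
        self.random_state = random_state

    def fit(self, X, y=None):
        from .detection import _coerce_table

        if self.tree is None:
            raise ValueError("PhylogeneticSignal requires a tree")
        table = _coerce_table(X, self.tree)
        self.results_ = ses_mpd(
            table,
            self.tree,
            permutations=self.permutations,
            weighted=self.weighted,
            seed=self.random_state,
        )
        ok = self.results_["flag"] != "undefined"
        self.mean_ses_ = float(self.results_.loc[ok, "ses"].mean())
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Per-sample SES values."""
        return self.fit(X).results_["ses"].to_numpy()
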