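"""Sample-by-taxon count tables.

The central in-memory container is :class:`AbundanceTable`, a thin,
validated wrapper around a pandas DataFrame whose rows are samples and
whose columns are taxa.  Counts are non-negative integers (reads from a
16S-style amplicon survey, or simulated reads).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "TableFormatError"]


class TableFormatError(ValueError):
    """Raised when an on-disk or in-memory table violates the format contract."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise TableFormatError(f"duplicate {what} identifier(s): {sorted(set(dups))[:10]}")
    return ids


class AbundanceTable:
    """A samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        2-D array-like of shape (n_samples, n_taxa); must be non-negative
        and integral.
    sample_ids, taxon_ids
        Unique string identifiers for rows and columns.
    metadata
        Optional free-form per-sample key -> value strings.
    """

    def __init__(
        self,
        counts,
        sample_ids: Iterable[str],
        taxon_ids: Iterable[str],
        metadata: Mapping[str, Mapping[str, str]] | None = None,
    ):
        sample_ids = _check_unique(sample_ids, "sample")
        taxon_ids = _check_unique(taxon_ids, "taxon")
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if arr.shape != (len(sample_ids), len(taxon_ids)):
            raise TableFormatError(
                f"counts shape {arr.shape} does not match "
                f"{len(sample_ids)} samples x {len(taxon_ids)} taxa"
            )
        if arr.size == 0:
            raise TableFormatError("table must have at least 1 sample and 1 taxon")
        if not np.issubdtype(arr.dtype, np.number):
            raise TableFormatError("counts must be numeric")
        if np.any(~np.isfinite(arr.astype(float))):
            raise TableFormatError("counts contain non-finite values")
        if np.any(arr < 0):
            raise TableFormatError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr.astype(float))):
            raise TableFormatError("counts must be integral read counts")
        self._df = pd.DataFrame(
            arr.astype(np.int64), index=sample_ids, columns=taxon_ids
        )
        self.metadata = dict(metadata) if metadata else {}

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metadata=None) -> "AbundanceTable":
        return cls(df.to_numpy(), df.index, df.columns, metadata=metadata)

    @property
    def data(self) -> pd.DataFrame:
        """The counts as a DataFrame (samples as rows, taxa as columns)."""
        return self._df

    @property
    def counts(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_samples(self) -> int:
        return self._df.shape[0]

    @property
    def n_taxa(self) -> int:
        return self._df.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; samples with zero total become NaN."""
        totals = self.sample_totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals[:, None]
        return pd.DataFrame(rel, index=self._df.index, columns=self._df.columns)

    def select_taxa(self, taxa: Iterable[str]) -> "AbundanceTable":
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self._df.columns]
        if missing:
            raise KeyError(f"taxa not in table: {missing[:10]}")
        return AbundanceTable.from_dataframe(self._df.loc[:, taxa], self.metadata)

    def select_samples(self, samples: Iterable[str]) -> "AbundanceTable":
        samples = list(samples)
        missing = [s for s in samples if s not in self._df.index]
        if missing:
            raise KeyError(f"samples not in table: {missing[:10]}")
        md = {s: self.metadata[s] for s in samples if s in self.metadata}
        return AbundanceTable.from_dataframe(self._df.loc[samples, :], md)

    def drop_empty_samples(self) -> tuple["AbundanceTable", list[str]]:
        """Drop samples whose total count is zero; returns (table, dropped ids)."""
        totals = self.sample_totals()
        keep = [s for s, t in zip(self.sample_ids, totals) if t > 0]
        dropped = [s for s, t in zip(self.sample_ids, totals) if t == 0]
        if not keep:
            raise TableFormatError("all samples have zero total count")
        if not dropped:
            return self, []
        return self.select_samples(keep), dropped

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"AbundanceTable({self.n_samples} samples x {self.n_taxa} taxa)"
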