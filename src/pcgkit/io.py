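"""Readers and writers for the on-disk formats.

TSV is the canonical table format (samples as rows by default); BIOM-JSON
v1.0 (dense or sparse) is accepted as a convenience when the file ends in
``.biom``.  Trees are Newick; aligned sequences are FASTA; distance
matrices are square labeled TSV.  All numeric output is serialized with 6
significant digits.
"""

from __future__ import annotations

import json
import os
from typing import Mapping

import numpy as np
import pandas as pd

from .detection import NO_PCG, PCGSet, PCGSummary
from .phylogeny import Phylogeny
from .table import AbundanceTable, TableFormatError

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_newick_tree",
    "read_aligned_fasta",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_outputs",
]


def _sig6(x) -> float:
    return float(f"{float(x):.6g}")


# ----------------------------------------------------------------------
def _read_biom_json(path) -> AbundanceTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        taxa = [str(r["id"]) for r in doc["rows"]]
        samples = [str(c["id"]) for c in doc["columns"]]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise TableFormatError(f"not a BIOM-JSON v1.0 table: missing {exc}") from exc
    mat = np.zeros((len(taxa), len(samples)))
    if mtype == "dense":
        mat = np.asarray(data, dtype=float)
        if mat.shape != (len(taxa), len(samples)):
            raise TableFormatError("BIOM dense data shape mismatch")
    elif mtype == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = v
    else:
        raise TableFormatError(f"unknown BIOM matrix_type: {mtype!r}")
    # BIOM stores observations (taxa) as rows; our convention is samples as rows
    return AbundanceTable(mat.T, samples, taxa)


def read_abundance_table(path, orientation: str = "samples_as_rows") -> AbundanceTable:
    """Read a count table from TSV (or BIOM-JSON v1.0 for ``.biom`` files).

    ``orientation`` says what the TSV rows are; ``taxa_as_rows`` input is
    transposed so the returned table is always samples x taxa.  BIOM input
    is orientation-free (the format fixes observations as rows).
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if str(path).endswith(".biom"):
        return _read_biom_json(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:
        raise TableFormatError(f"could not parse TSV table: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise TableFormatError("empty table")
    # duplicate column labels survive pandas parsing only via mangling; detect
    # duplicates from the raw header line instead
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise TableFormatError(f"duplicate column identifier(s): {dups[:10]}")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise TableFormatError(f"duplicate row identifier(s): {dups[:10]}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric cell in table: {exc}") from exc
    if orientation == "taxa_as_rows":
        values = values.T
    return AbundanceTable(values.to_numpy(), values.index, values.columns)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_newick_tree(path) -> Phylogeny:
    """One rooted Newick tree; missing branch lengths default to 1.0."""
    return Phylogeny.from_newick(str(path))


def read_aligned_fasta(path) -> dict[str, str]:
    """Aligned FASTA as an ordered label -> sequence mapping.

    Sequences are uppercased; gap characters '-' and '.' are preserved.
    Unequal lengths or duplicate labels are errors.
    """
    seqs: dict[str, str] = {}
    label, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if label is not None:
                    seqs[label] = "".join(chunks)
                label = line[1:].split()[0]
                if label in seqs:
                    raise ValueError(f"duplicate FASTA label: {label!r}")
                chunks = []
            else:
                if label is None:
                    raise ValueError("FASTA file does not start with a '>' header")
                chunks.append(line.upper())
        if label is not None:
            if label in seqs:
                raise ValueError(f"duplicate FASTA label: {label!r}")
            seqs[label] = "".join(chunks)
    if not seqs:
        raise ValueError("empty FASTA file")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences have unequal lengths {sorted(lengths)}; "
            "align them first (inputs must be pre-aligned)"
        )
    return seqs


def read_distance_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df


def write_distance_matrix(dist: pd.DataFrame, path) -> None:
    dist.to_csv(path, sep="\t", index_label="id")


# ----------------------------------------------------------------------
def write_outputs(pcgs: PCGSet, summary: PCGSummary, report, out_dir) -> dict[str, str]:
    """Write the standard detection output bundle into ``out_dir``:

    - ``pcgs.tsv``: one row per PCG (id, size, depth, prevalence, mean
      pooled relative abundance, semicolon-joined members);
    - ``membership.tsv``: taxon -> pcg id, "none" for taxa in no PCG;
    - ``report.json``: machine-readable mirror of all numbers, plus any
      extra ``report`` object (must be JSON-serializable) under "extra".

    Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    pcgs_path = os.path.join(out_dir, "pcgs.tsv")
    cols = ["pcg_id", "n_taxa", "depth", "prevalence", "mean_relabund", "member_taxa"]
    with open(pcgs_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in summary.per_pcg.iterrows():
            fh.write(
                "\t".join(
                    [
                        row["pcg_id"],
                        str(int(row["n_taxa"])),
                        f"{row['depth']:.6g}",
                        f"{row['prevalence']:.6g}",
                        f"{row['mean_relabund']:.6g}",
                        row["member_taxa"],
                    ]
                )
                + "\n"
            )
    paths["pcgs"] = pcgs_path

    membership = pcgs.membership(summary.taxon_ids)
    mem_path = os.path.join(out_dir, "membership.tsv")
    with open(mem_path, "w") as fh:
        fh.write("taxon_id\tpcg_id\n")
        for taxon, pid in membership.items():
            fh.write(f"{taxon}\t{pid}\n")
    paths["membership"] = mem_path

    doc = {
        "params": {
            "min_count": pcgs.params.min_count,
            "min_relabund": _sig6(pcgs.params.min_relabund),
            "prevalence": _sig6(pcgs.params.prevalence),
        },
        "n_pcgs": len(pcgs),
        "coverage": _sig6(summary.coverage),
        "coverage_per_sample": {
            s: _sig6(v) for s, v in summary.coverage_per_sample.items()
        },
        "pcgs": [
            {
                "pcg_id": row["pcg_id"],
                "n_taxa": int(row["n_taxa"]),
                "depth": _sig6(row["depth"]),
                "prevalence": _sig6(row["prevalence"]),
                "mean_relabund": _sig6(row["mean_relabund"]),
                "member_taxa": row["member_taxa"].split(";"),
            }
            for _, row in summary.per_pcg.iterrows()
        ],
    }
    if report is not None:
        doc["extra"] = report
    json_path = os.path.join(out_dir, "report.json")
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["report"] = json_path
    return paths


def read_detected_pcgs(path) -> list[frozenset[str]]:
    """Member sets from a ``pcgs.tsv`` written by :func:`write_outputs`."""
    sets = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            col = header.index("member_taxa")
        except ValueError:
            raise TableFormatError("pcgs.tsv lacks a member_taxa column")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) > col and parts[col]:
                sets.append(frozenset(parts[col].split(";")))
    return sets
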