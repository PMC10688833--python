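"""Readers and writers for the pipeline's on-disk formats.

Four formats are supported: multi-record FASTA for genome sequences,
tab-separated metadata tables (``phage_id  cluster  subcluster  genus``),
tab-separated percent-similarity matrices, and Newick trees with branch
lengths and optional internal-node support labels.
"""

from __future__ import annotations

import logging
from os import PathLike
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import ClusterRow, ClusterTable, GenomeRecord, SimilarityMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_cluster_table",
    "write_cluster_table",
    "read_matrix",
    "write_matrix",
    "read_newick",
    "write_newick",
    "FastaError",
]

logger = logging.getLogger(__name__)

# IUPAC one-letter ambiguity codes canonicalized to N on input; U is
# accepted as well since RNA-style records occasionally appear.
_AMBIGUITY = set("RYSWKMBDHVU")


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


def _canonicalize(seq: str, record_id: str) -> tuple[str, int]:
    seq = seq.upper()
    out = []
    replaced = 0
    for ch in seq:
        if ch in "ACGTN":
            out.append(ch)
        elif ch in _AMBIGUITY:
            out.append("N")
            replaced += 1
        else:
            raise FastaError(
                f"record {record_id!r}: invalid sequence character {ch!r}"
            )
    return "".join(out), replaced


def read_fasta(path: str | PathLike) -> list[GenomeRecord]:
    """Read a multi-record FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased; IUPAC ambiguity codes outside A/C/G/T/N
    are replaced by N (the total replacement count is logged).  Duplicate
    ids, empty sequences and non-FASTA content raise :class:`FastaError`.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaError(f"{path}: empty file")

    records: list[GenomeRecord] = []
    seen: set[str] = set()
    total_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
        seq, replaced = _canonicalize(seq, rec.id)
        total_replaced += replaced
        records.append(GenomeRecord(rec.id, seq))
    if total_replaced:
        logger.info(
            "read_fasta(%s): replaced %d ambiguity-code bases with N", path, total_replaced
        )
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


_META_COLUMNS = ["phage_id", "cluster", "subcluster", "genus"]


def read_cluster_table(path: str | PathLike) -> ClusterTable:
    """Read the tab-separated phage metadata table.

    The header must contain ``phage_id``, ``cluster``, ``subcluster`` and
    ``genus``; empty subcluster/genus cells are stored as absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    table = ClusterTable()
    for i, row in df.iterrows():
        try:
            table.add(
                ClusterRow(
                    phage_id=row["phage_id"],
                    cluster=row["cluster"],
                    subcluster=row["subcluster"] or None,
                    genus=row["genus"] or None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return table


def write_cluster_table(table: ClusterTable, path: str | PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "phage_id": r.phage_id,
                "cluster": r.cluster,
                "subcluster": r.subcluster or "",
                "genus": r.genus or "",
            }
            for r in table
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_matrix(m: SimilarityMatrix, path: str | PathLike) -> None:
    """Write a similarity matrix as TSV with two-decimal percent values."""
    for gid in m.ids:
        if "\t" in gid:
            raise ValueError(f"genome id {gid!r} contains a tab character")
    df = pd.DataFrame(m.values, index=m.ids, columns=m.ids)
    df.to_csv(path, sep="\t", float_format="%.2f", index_label=m.kind)


def read_matrix(path: str | PathLike, kind: str | None = None) -> SimilarityMatrix:
    """Read a similarity matrix TSV produced by :func:`write_matrix`.

    The matrix kind is taken from the corner header cell unless given
    explicitly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if kind is None:
        corner = df.index.name
        kind = corner if corner in SimilarityMatrix.KINDS else "nucleotide"
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError(f"{path}: row and column ids differ")
    values = df.to_numpy(dtype=float)
    if kind == "nucleotide":
        # 2-decimal printing may leave sub-0.01 asymmetry; resymmetrize.
        values = (values + values.T) / 2.0
    np.fill_diagonal(values, 100.0)
    return SimilarityMatrix(ids, values, kind)


def write_newick(tree: dendropy.Tree, path: str | PathLike) -> None:
    """Write a tree as Newick with branch lengths; internal-node labels
    (bootstrap supports) are preserved."""
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )


def read_newick(path: str | PathLike) -> dendropy.Tree:
    """Parse a Newick tree; malformed input raises with the error position."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
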