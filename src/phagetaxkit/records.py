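"""Core domain types shared across the pipeline.

The analysis operates on four kinds of objects: whole phage genome
sequences (:class:`GenomeRecord`), the cluster/subcluster/genus metadata
attached to each phage (:class:`ClusterTable`), percent-similarity
matrices produced by the nucleotide and proteome comparison stages
(:class:`SimilarityMatrix`), and rank-labelled partitions of the genome
set (:class:`TaxonPartition`).  Trees are represented directly as
:class:`dendropy.Tree` objects (see :mod:`phagetaxkit.phylogeny`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GenomeRecord",
    "ClusterRow",
    "ClusterTable",
    "SimilarityMatrix",
    "TaxonPartition",
    "Thresholds",
    "SINGLETON",
    "UNKNOWN",
]

#: Sentinel cluster labels for phages that cannot be clustered.
SINGLETON = "SINGLETON"
UNKNOWN = "UNKNOWN"

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """One phage genome: a unique id and an uppercase A/C/G/T/N sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains invalid characters {sorted(bad)}; "
                "canonicalize ambiguity codes to N first (see io.read_fasta)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClusterRow:
    """Cluster/subcluster/genus assignment of a single phage."""

    phage_id: str
    cluster: str
    subcluster: str | None = None
    genus: str | None = None

    def __post_init__(self) -> None:
        if not self.phage_id:
            raise ValueError("phage_id must be non-empty")
        if not self.cluster:
            raise ValueError(f"{self.phage_id}: cluster label must be non-empty")
        if self.cluster in (SINGLETON, UNKNOWN):
            if self.subcluster:
                raise ValueError(
                    f"{self.phage_id}: {self.cluster} rows cannot carry a subcluster"
                )
        elif self.subcluster is not None and not self.subcluster.startswith(self.cluster):
            raise ValueError(
                f"{self.phage_id}: subcluster {self.subcluster!r} is not prefixed "
                f"by its cluster {self.cluster!r}"
            )


class ClusterTable:
    """Per-phage metadata table keyed by phage id.

    Subcluster labels must extend their cluster label (subcluster ``A2``
    lives in cluster ``A``); rows whose cluster is the ``SINGLETON`` or
    ``UNKNOWN`` sentinel carry no subcluster.
    """

    def __init__(self, rows: Iterable[ClusterRow] = ()) -> None:
        self._rows: dict[str, ClusterRow] = {}
        for row in rows:
            self.add(row)

    def add(self, row: ClusterRow) -> None:
        if row.phage_id in self._rows:
            raise ValueError(f"duplicate phage_id {row.phage_id!r}")
        self._rows[row.phage_id] = row

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows.values())

    def __contains__(self, phage_id: str) -> bool:
        return phage_id in self._rows

    def __getitem__(self, phage_id: str) -> ClusterRow:
        return self._rows[phage_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, ClusterTable) and self._rows == other._rows

    @property
    def ids(self) -> list[str]:
        return list(self._rows)

    def clusters(self) -> dict[str, list[str]]:
        """Mapping cluster label -> phage ids, sentinels included."""
        out: dict[str, list[str]] = {}
        for row in self:
            out.setdefault(row.cluster, []).append(row.phage_id)
        return out

    def replace(self, phage_id: str, **changes) -> None:
        """Replace fields of one row in place (used by the reorganization editor)."""
        self._rows[phage_id] = dataclasses.replace(self._rows[phage_id], **changes)

    def copy(self) -> "ClusterTable":
        return ClusterTable(self)

    def subset(self, ids: Iterable[str]) -> "ClusterTable":
        return ClusterTable(self._rows[i] for i in ids)


class SimilarityMatrix:
    """Percent-similarity matrix over an ordered genome-id set.

    ``kind="nucleotide"`` matrices are symmetric intergenomic
    similarities; ``kind="proteome"`` matrices hold the directional
    fragmented translated-genome score and may be asymmetric.
    All values lie in [0, 100] with a diagonal of exactly 100.
    """

    KINDS = ("nucleotide", "proteome")

    def __init__(self, ids: Iterable[str], values, kind: str = "nucleotide") -> None:
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate genome ids in similarity matrix")
        self.values = np.asarray(values, dtype=float)
        if kind not in self.KINDS:
            raise ValueError(f"unknown matrix kind {kind!r}")
        self.kind = kind
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if n and not np.allclose(np.diag(self.values), 100.0, atol=1e-9):
            raise ValueError("similarity matrix diagonal must equal 100")
        if n and (self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9):
            raise ValueError("similarity values must lie in [0, 100]")
        if self.kind == "nucleotide" and n and not np.allclose(
            self.values, self.values.T, atol=1e-9
        ):
            raise ValueError("nucleotide similarity matrix must be symmetric")

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=1e-9))

    def index(self, genome_id: str) -> int:
        return self.ids.index(genome_id)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def reorder(self, ids: Iterable[str]) -> "SimilarityMatrix":
        ids = list(ids)
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(ids, self.values[np.ix_(idx, idx)], self.kind)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimilarityMatrix)
            and self.ids == other.ids
            and self.kind == other.kind
            and np.array_equal(self.values, other.values)
        )


@dataclass
class TaxonPartition:
    """A rank-labelled partition of genome ids (genus, species or subcluster)."""

    rank: str
    assignment: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    RANKS = ("genus", "species", "subcluster")

    def __post_init__(self) -> None:
        if self.rank not in self.RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        for gid, label in self.assignment.items():
            if not label:
                raise ValueError(f"empty taxon label for genome {gid!r}")

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    def groups(self) -> dict[str, set[str]]:
        """Mapping taxon label -> member genome ids."""
        out: dict[str, set[str]] = {}
        for gid, label in self.assignment.items():
            out.setdefault(label, set()).add(gid)
        return out

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass(frozen=True)
class Thresholds:
    """Demarcation thresholds (percent) used throughout the pipeline.

    ``genus_nt``/``species_nt`` are the intergenomic nucleotide
    similarity demarcations for genus and species; ``subcluster_prot``
    is the fragmented-proteome similarity boundary used to support genus
    and subcluster proposals; ``borderline_band`` is the width of the
    just-below-threshold zone reported for manual review.
    """

    genus_nt: float = 70.0
    species_nt: float = 95.0
    subcluster_prot: float = 50.0
    borderline_band: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.genus_nt < self.species_nt <= 100):
            raise ValueError("require 0 < genus_nt < species_nt <= 100")
        if self.borderline_band < 0:
            raise ValueError("borderline_band must be >= 0")
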