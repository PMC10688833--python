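"""Dataset curation: exclusion criteria and post-hoc relatedness checks.

Three exclusion criteria reduce the working dataset before similarity
analysis: (1) phages that cannot be assigned to a cluster (``UNKNOWN``),
(2) clusters represented by three or fewer genomes (underrepresented),
and (3) singleton phages.  Unknowns are pooled as one removed grouping
and singletons as another, so each removed cluster plus the two pools
count as individual groupings in the curation report.

The packaged ``refseq_cluster_census.tsv`` fixture reproduces the
published per-cluster census of the RefSeq mycobacteriophage dataset
(cluster label, phage count, subcluster count) and can be expanded into
a per-phage :class:`~phagetaxkit.records.ClusterTable` for arithmetic
checks without the underlying genome sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import pandas as pd

from .records import SINGLETON, UNKNOWN, ClusterRow, ClusterTable, GenomeRecord

__all__ = [
    "CurationReport",
    "apply_exclusion_criteria",
    "verify_exclusions",
    "load_cluster_census",
    "expand_census",
    "MIN_CLUSTER_SIZE",
]

#: A cluster must exceed this many genomes to be retained (criterion 2:
#: clusters with <= 3 genomes are considered underrepresented).
MIN_CLUSTER_SIZE = 4


@dataclass
class CurationReport:
    """Outcome of applying the exclusion criteria to a metadata table."""

    removed_groupings: list[tuple[str, int]] = field(default_factory=list)
    removed_genomes: list[str] = field(default_factory=list)
    retained_table: ClusterTable = field(default_factory=ClusterTable)
    retained_cluster_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed_groupings(self) -> int:
        return len(self.removed_groupings)

    @property
    def n_removed_genomes(self) -> int:
        return len(self.removed_genomes)

    @property
    def n_retained(self) -> int:
        return len(self.retained_table)


def apply_exclusion_criteria(
    table: ClusterTable, min_cluster_size: int = MIN_CLUSTER_SIZE
) -> CurationReport:
    """Remove unknowns, singletons and underrepresented clusters.

    Removed groupings are reported as one entry per removed cluster plus
    one pooled entry for singletons and one for unknowns (when present).
    """
    clusters = table.clusters()
    report = CurationReport()

    removed_ids: list[str] = []
    for label in (UNKNOWN, SINGLETON):
        members = clusters.pop(label, [])
        if members:
            pool = "unknown" if label == UNKNOWN else "singletons"
            report.removed_groupings.append((pool, len(members)))
            removed_ids.extend(members)

    for label in sorted(clusters):
        members = clusters[label]
        if len(members) < min_cluster_size:
            report.removed_groupings.append((f"cluster {label}", len(members)))
            removed_ids.extend(members)
        else:
            report.retained_cluster_sizes[label] = len(members)

    removed_set = set(removed_ids)
    report.removed_genomes = removed_ids
    report.retained_table = ClusterTable(
        row for row in table if row.phage_id not in removed_set
    )
    return report


@dataclass(frozen=True)
class ExclusionCheck:
    """Best retained match for one removed genome."""

    removed_id: str
    best_match_id: str
    similarity: float
    related: bool


def verify_exclusions(
    removed: Sequence[GenomeRecord],
    retained: Sequence[GenomeRecord],
    sim: Callable[[GenomeRecord, GenomeRecord], float],
    threshold: float = 70.0,
) -> list[ExclusionCheck]:
    """Check that removed genomes are not closely related to retained ones.

    For each removed genome the maximum pairwise intergenomic similarity
    against every retained genome is reported; a genome is flagged as
    ``related`` when that maximum reaches the genus threshold.
    """
    if not retained:
        raise ValueError("retained genome set is empty")
    if not removed:
        raise ValueError("removed genome set is empty")
    out = []
    for r in removed:
        best_id, best_sim = "", -1.0
        for t in retained:
            s = sim(r, t)
            if s > best_sim or (s == best_sim and t.id < best_id):
                best_id, best_sim = t.id, s
        out.append(ExclusionCheck(r.id, best_id, best_sim, best_sim >= threshold))
    return out


def load_cluster_census() -> pd.DataFrame:
    """Load the packaged per-cluster census of the RefSeq dataset."""
    with resources.files("phagetaxkit.data").joinpath(
        "refseq_cluster_census.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"cluster": str, "n_phages": int})


def expand_census(census: pd.DataFrame | None = None) -> ClusterTable:
    """Expand a per-cluster census into a per-phage metadata table.

    Placeholder phage ids ``<cluster>_001`` ... are generated; the
    ``Singletons``/``Unknown`` census rows become ``SINGLETON``/``UNKNOWN``
    sentinel rows.  Subcluster and genus columns are left absent — the
    census records counts only, not per-phage labels.
    """
    if census is None:
        census = load_cluster_census()
    table = ClusterTable()
    for _, row in census.iterrows():
        label = str(row["cluster"])
        if label.lower() == "singletons":
            cluster = SINGLETON
        elif label.lower() == "unknown":
            cluster = UNKNOWN
        else:
            cluster = label
        for i in range(int(row["n_phages"])):
            table.add(ClusterRow(f"{label}_{i + 1:03d}", cluster))
    return table
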