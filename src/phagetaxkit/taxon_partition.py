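"""Threshold clustering of similarity matrices and taxonomy comparison.

Genus and species partitions are obtained by agglomerative clustering
on distance 100 - similarity, cut at the demarcation threshold.  With
complete linkage (the default) every pair inside a resulting genus
meets the threshold, i.e. the threshold is the minimum similarity
required for genus inclusion; single linkage is available for
sensitivity analysis.  Pairs falling just below the threshold are
reported as borderline so judgment calls (such as accepting a 66%
boundary where 70% fragments an otherwise coherent group) are explicit
rather than silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .records import ClusterTable, SimilarityMatrix, TaxonPartition

__all__ = [
    "threshold_partition",
    "borderline_pairs",
    "order_rows",
    "GenusProposal",
    "propose_genera",
    "SubclusterProposal",
    "propose_subclusters",
    "compare_partitions",
]


def _lex_sorted(m: SimilarityMatrix) -> SimilarityMatrix:
    return m.reorder(sorted(m.ids))


def _require_symmetric(m: SimilarityMatrix) -> None:
    if not m.is_symmetric:
        raise ValueError("matrix is asymmetric: symmetrize a proteome matrix first")


def threshold_partition(
    m: SimilarityMatrix,
    theta: float,
    linkage: str = "complete",
    rank: str = "genus",
) -> TaxonPartition:
    """Cut an agglomerative clustering of 100 - sim at distance 100 - theta.

    Labels are assigned ``G1..Gk`` in order of each cluster's
    lexicographically smallest member id; ids are pre-sorted so merge
    order (and hence tie resolution) is deterministic.
    """
    if not (0 < theta <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    if linkage not in ("complete", "single"):
        raise ValueError("linkage must be 'complete' or 'single'")
    _require_symmetric(m)
    m = _lex_sorted(m)
    dist = np.clip(100.0 - m.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    if len(m.ids) == 1:
        flat = np.array([1])
    else:
        Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        flat = hierarchy.fcluster(Z, t=100.0 - theta, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for gid, c in zip(m.ids, flat):
        clusters.setdefault(int(c), []).append(gid)
    ordered = sorted(clusters.values(), key=lambda members: min(members))
    assignment = {}
    for i, members in enumerate(ordered, start=1):
        for gid in members:
            assignment[gid] = f"G{i}"
    return TaxonPartition(rank=rank, assignment=assignment)


def borderline_pairs(
    m: SimilarityMatrix, theta: float, band: float = 5.0
) -> list[tuple[str, str, float]]:
    """Unordered pairs with similarity in [theta - band, theta), descending."""
    _require_symmetric(m)
    out = []
    n = len(m.ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = float(m.values[i, j])
            if theta - band <= v < theta:
                a, b = sorted((m.ids[i], m.ids[j]))
                out.append((a, b, v))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def order_rows(m: SimilarityMatrix) -> list[str]:
    """Heatmap row order: average-linkage leaf order on 100 - sim."""
    _require_symmetric(m)
    m = _lex_sorted(m)
    if len(m.ids) < 3:
        return list(m.ids)
    dist = np.clip(100.0 - m.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return [m.ids[i] for i in hierarchy.leaves_list(Z)]


def novel_genus_name(members: set[str]) -> str:
    """Name a novel genus after its lexicographically first member."""
    first = min(members)
    return (first.lower() + "virus").capitalize()


@dataclass
class GenusProposal:
    """Comparison of a predicted genus partition with existing genera."""

    entries: list[dict] = field(default_factory=list)

    @property
    def novel(self) -> list[dict]:
        return [e for e in self.entries if e["status"] == "novel"]

    @property
    def n_novel(self) -> int:
        return len(self.novel)

    def name_of(self, label: str) -> str:
        for e in self.entries:
            if e["label"] == label:
                return e["name"]
        raise KeyError(label)


def propose_genera(p_new: TaxonPartition, existing: ClusterTable) -> GenusProposal:
    """Label each predicted genus as existing (identical member set) or novel.

    Novel genera are named after their lexicographically first member
    (lowercased, ``virus`` appended, capitalized).
    """
    table_ids = set(existing.ids)
    if set(p_new.ids) != table_ids:
        raise ValueError("partition and metadata table cover different genomes")
    existing_groups: dict[str, set[str]] = {}
    for row in existing:
        if row.genus:
            existing_groups.setdefault(row.genus, set()).add(row.phage_id)
    by_members = {frozenset(v): k for k, v in existing_groups.items()}
    proposal = GenusProposal()
    for label, members in sorted(p_new.groups().items(), key=lambda kv: min(kv[1])):
        match = by_members.get(frozenset(members))
        proposal.entries.append(
            {
                "label": label,
                "members": sorted(members),
                "status": "existing" if match else "novel",
                "name": match if match else novel_genus_name(members),
            }
        )
    return proposal


@dataclass
class SubclusterProposal:
    """Minimal-change reorganization of subclusters to match genus groups."""

    assignment: dict[str, str] = field(default_factory=dict)  # genome -> subcluster
    created: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)

    def partition(self) -> TaxonPartition:
        return TaxonPartition(rank="subcluster", assignment=dict(self.assignment))


def propose_subclusters(
    genus_partition: TaxonPartition, table: ClusterTable
) -> SubclusterProposal:
    """Reorganize each cluster's subclusters to mirror its genus groups.

    Within a cluster the proposed subclusters are exactly the genus
    groups.  Existing labels are inherited greedily by shared-member
    overlap (ties: larger group, then lexicographically first member);
    remaining groups receive the next free numeric suffix.  A genus
    group spanning two clusters violates cluster containment and is an
    error.
    """
    ids = set(genus_partition.ids)
    for gid in ids:
        if gid not in table:
            raise ValueError(f"genome {gid!r} missing from the metadata table")
    proposal = SubclusterProposal()
    groups_by_cluster: dict[str, dict[str, set[str]]] = {}
    for glabel, members in genus_partition.groups().items():
        clusters = {table[gid].cluster for gid in members}
        if len(clusters) > 1:
            raise ValueError(
                f"genus group {glabel} spans clusters {sorted(clusters)}: "
                "cluster containment violated"
            )
        groups_by_cluster.setdefault(clusters.pop(), {})[glabel] = members

    for cluster in sorted(groups_by_cluster):
        groups = groups_by_cluster[cluster]
        existing: dict[str, set[str]] = {}
        for gid in (i for i in table.ids if table[i].cluster == cluster):
            sub = table[gid].subcluster
            if sub:
                existing.setdefault(sub, set()).add(gid)
        # greedy one-to-one matching on overlap, then group size, then lex
        candidates = []
        for glabel, members in groups.items():
            for slabel, smembers in existing.items():
                ov = len(members & smembers)
                if ov:
                    candidates.append((-ov, -len(members), min(members), slabel, glabel))
        candidates.sort()
        matched_groups: dict[str, str] = {}
        used_labels: set[str] = set()
        for _, _, _, slabel, glabel in candidates:
            if glabel in matched_groups or slabel in used_labels:
                continue
            matched_groups[glabel] = slabel
            used_labels.add(slabel)
        # numeric suffixes already in use within this cluster
        taken = set()
        for slabel in list(existing) + list(matched_groups.values()):
            suffix = slabel[len(cluster) :]
            if suffix.isdigit():
                taken.add(int(suffix))
        next_free = 1
        for glabel, members in sorted(groups.items(), key=lambda kv: min(kv[1])):
            if glabel in matched_groups:
                label = matched_groups[glabel]
                proposal.retained.append(label)
            else:
                while next_free in taken:
                    next_free += 1
                taken.add(next_free)
                label = f"{cluster}{next_free}"
                proposal.created.append(label)
            for gid in members:
                proposal.assignment[gid] = label
        proposal.removed.extend(sorted(set(existing) - used_labels))
    proposal.created.sort()
    proposal.retained.sort()
    proposal.removed.sort()
    return proposal


def compare_partitions(
    p: TaxonPartition, q: TaxonPartition
) -> tuple[pd.DataFrame, float]:
    """Contingency table and adjusted Rand index of two partitions."""
    if set(p.ids) != set(q.ids):
        raise ValueError("partitions cover different genome sets")
    ids = sorted(p.ids)
    pl = [p.assignment[i] for i in ids]
    ql = [q.assignment[i] for i in ids]
    table = pd.crosstab(pd.Series(pl, name=p.rank), pd.Series(ql, name=q.rank))
    return table, float(adjusted_rand_score(pl, ql))
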