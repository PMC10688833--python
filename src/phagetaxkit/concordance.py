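"""The genus-subcluster concordance statistic and reorganization editing.

The genus-subcluster hypothesis states that each subcluster corresponds
to exactly one genus (and vice versa).  It is quantified over *groups*:
each subcluster is a group, and a cluster with no subclusters at all is
itself one group (otherwise clusters lacking subdivisions could not
participate).  A group supports the hypothesis when its members carry a
single genus; the statistic is the percentage of supporting groups.
The strict variant additionally requires the genus to occur in no other
group (a one-to-one correspondence).

The reorganization editor applies an ordered list of subcluster edits
(create / merge / reassign / remove) to a metadata table, producing an
audit trail, so the statistic can be compared before and after a
proposed re-taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .records import SINGLETON, UNKNOWN, ClusterTable, TaxonPartition

__all__ = [
    "GroupTable",
    "ConcordanceReport",
    "ReorgEdit",
    "build_groups",
    "concordance_statistic",
    "apply_reorganization",
    "before_after_report",
    "edits_from_proposal",
    "round_percent",
]


def round_percent(x: float) -> float:
    """Round half-up to one decimal (printed precision of the statistic)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class GroupTable:
    """Partition of the genome set into subcluster-level groups."""

    groups: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.groups)


def build_groups(table: ClusterTable) -> GroupTable:
    """One group per subcluster; one group per undivided cluster.

    In a mixed cluster (some members subclustered, some not) the
    unlabelled members form a residual ``<cluster>-unplaced`` group.
    Sentinel SINGLETON/UNKNOWN rows are outside the hypothesis and are
    ignored.
    """
    gt = GroupTable()
    by_cluster: dict[str, list] = {}
    for row in table:
        if row.cluster in (SINGLETON, UNKNOWN):
            continue
        by_cluster.setdefault(row.cluster, []).append(row)
    for cluster, rows in by_cluster.items():
        labelled = [r for r in rows if r.subcluster]
        unlabelled = [r for r in rows if not r.subcluster]
        for r in labelled:
            gt.groups.setdefault(r.subcluster, set()).add(r.phage_id)
        if unlabelled:
            key = cluster if not labelled else f"{cluster}-unplaced"
            gt.groups.setdefault(key, set()).update(r.phage_id for r in unlabelled)
    return gt


@dataclass
class ConcordanceReport:
    """Per-group support for the genus-subcluster hypothesis."""

    per_group: dict[str, dict] = field(default_factory=dict)
    statistic: float = 0.0
    strict_statistic: float = 0.0

    @property
    def n_groups(self) -> int:
        return len(self.per_group)

    @property
    def n_supported(self) -> int:
        return sum(1 for g in self.per_group.values() if g["supported"])


def concordance_statistic(g: GroupTable, genus: TaxonPartition) -> ConcordanceReport:
    """Percentage of groups whose members carry exactly one genus.

    ``strict_statistic`` additionally requires that genus to appear in
    no other group.  Percentages are rounded half-up to one decimal.
    """
    report = ConcordanceReport()
    genus_to_groups: dict[str, set[str]] = {}
    for label, members in g.groups.items():
        for gid in members:
            if gid not in genus.assignment:
                raise ValueError(f"genome {gid!r} has no genus label")
            genus_to_groups.setdefault(genus.assignment[gid], set()).add(label)
    strict_count = 0
    for label in sorted(g.groups):
        members = g.groups[label]
        genera = {genus.assignment[gid] for gid in members}
        supported = len(genera) == 1
        strict = supported and len(genus_to_groups[next(iter(genera))]) == 1
        strict_count += strict
        report.per_group[label] = {
            "n_members": len(members),
            "n_genera": len(genera),
            "supported": supported,
            "strict": strict,
        }
    n = len(g.groups)
    if n:
        report.statistic = round_percent(100.0 * report.n_supported / n)
        report.strict_statistic = round_percent(100.0 * strict_count / n)
    return report


@dataclass(frozen=True)
class ReorgEdit:
    """One subcluster reorganization step.

    Operations and their parameters:

    - ``create_subcluster``: ``cluster``, ``label``, ``members`` — move
      the listed genomes of the cluster into a new subcluster label.
    - ``merge_subclusters``: ``sources``, ``target`` — relabel all
      members of the source subclusters to the target label.
    - ``reassign_genome``: ``genome``, ``subcluster`` — move one genome
      to an existing (or empty) subcluster label of its cluster.
    - ``remove_subcluster``: ``label``, optional ``into`` — dissolve a
      subcluster, moving members to ``into`` or leaving them unplaced.
    """

    op: str
    params: tuple[tuple[str, object], ...]

    OPS = ("create_subcluster", "merge_subclusters", "reassign_genome", "remove_subcluster")

    @classmethod
    def make(cls, op: str, **params) -> "ReorgEdit":
        if op not in cls.OPS:
            raise ValueError(f"unknown edit operation {op!r}")
        norm = tuple(
            (k, tuple(v) if isinstance(v, (list, set)) else v)
            for k, v in sorted(params.items())
        )
        return cls(op, norm)

    @property
    def kwargs(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.params}

    def to_json(self) -> dict:
        return {"op": self.op, **self.kwargs}

    @classmethod
    def from_json(cls, obj: dict) -> "ReorgEdit":
        obj = dict(obj)
        return cls.make(obj.pop("op"), **obj)


def _subcluster_members(table: ClusterTable, label: str) -> list[str]:
    return [r.phage_id for r in table if r.subcluster == label]


def apply_reorganization(
    table: ClusterTable, edits: list[ReorgEdit]
) -> tuple[ClusterTable, list[str]]:
    """Apply edits in order; returns the new table and an audit log."""
    out = table.copy()
    audit: list[str] = []
    for idx, edit in enumerate(edits):
        kw = edit.kwargs
        try:
            if edit.op == "create_subcluster":
                cluster, label, members = kw["cluster"], kw["label"], kw["members"]
                if not label.startswith(cluster):
                    raise ValueError(f"label {label!r} not prefixed by cluster {cluster!r}")
                if _subcluster_members(out, label):
                    raise ValueError(f"subcluster {label!r} already exists")
                for gid in members:
                    if gid not in out:
                        raise ValueError(f"unknown genome {gid!r}")
                    if out[gid].cluster != cluster:
                        raise ValueError(f"genome {gid!r} is not in cluster {cluster!r}")
                    out.replace(gid, subcluster=label)
                audit.append(f"create_subcluster {label} <- {sorted(members)}")
            elif edit.op == "merge_subclusters":
                sources, target = kw["sources"], kw["target"]
                moved = []
                for src in sources:
                    members = _subcluster_members(out, src)
                    if not members and src != target:
                        raise ValueError(f"unknown subcluster {src!r}")
                    for gid in members:
                        out.replace(gid, subcluster=target)
                        moved.append(gid)
                audit.append(f"merge_subclusters {list(sources)} -> {target} ({len(moved)} genomes)")
            elif edit.op == "reassign_genome":
                gid, label = kw["genome"], kw["subcluster"]
                if gid not in out:
                    raise ValueError(f"unknown genome {gid!r}")
                out.replace(gid, subcluster=label)
                audit.append(f"reassign_genome {gid} -> {label}")
            elif edit.op == "remove_subcluster":
                label, into = kw["label"], kw.get("into")
                members = _subcluster_members(out, label)
                if not members:
                    raise ValueError(f"unknown subcluster {label!r}")
                for gid in members:
                    out.replace(gid, subcluster=into)
                dest = into if into else "unplaced"
                audit.append(f"remove_subcluster {label} ({len(members)} genomes -> {dest})")
            else:  # pragma: no cover - guarded by ReorgEdit.make
                raise ValueError(f"unknown edit operation {edit.op!r}")
        except (KeyError, ValueError) as exc:
            raise ValueError(f"edit {idx} ({edit.op}): {exc}") from exc
    return out, audit


@dataclass
class BeforeAfterReport:
    """Concordance before and after a proposed reorganization."""

    before: ConcordanceReport
    after: ConcordanceReport
    audit: list[str] = field(default_factory=list)

    @property
    def delta(self) -> float:
        return round_percent(self.after.statistic - self.before.statistic)


def before_after_report(
    table: ClusterTable,
    edits: list[ReorgEdit],
    genus_old: TaxonPartition,
    genus_new: TaxonPartition,
) -> BeforeAfterReport:
    """Concordance on (table, genus_old) vs (edited table, genus_new)."""
    before = concordance_statistic(build_groups(table), genus_old)
    new_table, audit = apply_reorganization(table, edits)
    after = concordance_statistic(build_groups(new_table), genus_new)
    return BeforeAfterReport(before=before, after=after, audit=audit)


def edits_from_proposal(
    table: ClusterTable, proposed: TaxonPartition
) -> list[ReorgEdit]:
    """Translate a proposed subcluster partition into an edit list.

    Emits ``create_subcluster`` for labels that do not yet exist and
    ``reassign_genome`` for genomes moving between existing labels, in
    deterministic (lexicographic) order.
    """
    if proposed.rank != "subcluster":
        raise ValueError("proposal must be a subcluster partition")
    existing_labels = {r.subcluster for r in table if r.subcluster}
    edits: list[ReorgEdit] = []
    for label, members in sorted(proposed.groups().items()):
        current = {gid for gid in members if table[gid].subcluster == label}
        movers = sorted(members - current)
        if not movers:
            continue
        if label not in existing_labels:
            cluster = table[movers[0]].cluster
            edits.append(
                ReorgEdit.make(
                    "create_subcluster", cluster=cluster, label=label, members=movers
                )
            )
            existing_labels.add(label)
        else:
            for gid in movers:
                edits.append(ReorgEdit.make("reassign_genome", genome=gid, subcluster=label))
    return edits
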