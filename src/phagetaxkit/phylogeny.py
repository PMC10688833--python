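"""Distance trees, bootstrap support and monophyly testing.

Similarity matrices are converted to distances d = (100 - sim)/100 and
trees are built with neighbor joining.  Branch support comes from
resampling each genome's query fragments with replacement, recomputing
the fragmented-proteome matrix and tree, and counting how often each
internal bipartition of the reference tree recurs.  Monophyly is
defined on the unrooted tree: a set of leaves is monophyletic iff it
(or its complement) is one side of some edge bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .prot_similarity import FragmentationParams, fragment_score_table, symmetrize
from .records import GenomeRecord, SimilarityMatrix, TaxonPartition

__all__ = [
    "DistanceMatrix",
    "MonophylyReport",
    "distance_from_similarity",
    "nj_tree",
    "tree_bipartitions",
    "is_monophyletic",
    "monophyly_report",
    "bootstrap_support",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if n and not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if n and self.values.min() < -1e-9:
            raise ValueError("distances must be non-negative")


def distance_from_similarity(m: SimilarityMatrix) -> DistanceMatrix:
    """d = (100 - sim) / 100, clamped to [0, 1]; requires a symmetric matrix."""
    if not m.is_symmetric:
        raise ValueError("matrix is asymmetric: symmetrize a proteome matrix first")
    d = np.clip((100.0 - m.values) / 100.0, 0.0, 1.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.ids), d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining with deterministic tie-breaking.

    Q-matrix ties are broken by the lexicographically smallest pair of
    clade labels (a clade is labelled by its smallest leaf id); negative
    branch lengths are clamped to zero.  The result is an unrooted tree
    whose seed node is the final trifurcation.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes = [dendropy.Node(taxon=tns.get_taxon(i)) for i in dm.ids]
    labels = list(dm.ids)  # smallest leaf label within each active clade
    D = dm.values.copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        parent = dendropy.Node()
        for child, ln in ((nodes[i_pos], li), (nodes[j_pos], lj)):
            parent.add_child(child)
            child.edge.length = max(0.0, float(ln))
        nodes[i_pos] = parent
        labels[i_pos] = min(labels[i_pos], labels[j_pos])
        del nodes[j_pos], labels[j_pos]

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((labels[i], labels[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new_row = (sub[i, :] + sub[j, :] - dij) / 2.0
        # write the merged node into slot active[i]
        ai, aj = active[i], active[j]
        for t, pos in enumerate(active):
            D[ai, pos] = D[pos, ai] = new_row[t]
        D[ai, ai] = 0.0
        join(i, j, li, lj)
        del active[j]

    # final trifurcation (or exactly three taxa)
    sub = D[np.ix_(active, active)]
    va = (sub[0, 1] + sub[0, 2] - sub[1, 2]) / 2.0
    vb = (sub[0, 1] + sub[1, 2] - sub[0, 2]) / 2.0
    vc = (sub[0, 2] + sub[1, 2] - sub[0, 1]) / 2.0
    root = dendropy.Node()
    for child, ln in zip(nodes, (va, vb, vc)):
        root.add_child(child)
        child.edge.length = max(0.0, float(ln))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def tree_bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Map each edge's leaf-side set to its child node.

    Every edge (except the seed node's null edge) contributes the leaf
    set below it; together with its complement this defines the edge's
    bipartition of the unrooted tree.
    """
    out: dict[frozenset, dendropy.Node] = {}
    below: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            out[below[node]] = node
    return out


def is_monophyletic(tree: dendropy.Tree, leaves: set[str]) -> bool:
    """True iff the leaf set is one side of an edge bipartition.

    Singletons and the full leaf set are monophyletic by convention;
    complement symmetry holds because the tree is unrooted.
    """
    all_leaves = _leaf_labels(tree)
    leaves = set(leaves)
    if not leaves:
        raise ValueError("empty leaf set")
    unknown = leaves - all_leaves
    if unknown:
        raise ValueError(f"unknown leaf id(s): {sorted(unknown)}")
    if len(leaves) == 1 or leaves == all_leaves:
        return True
    sides = tree_bipartitions(tree)
    return frozenset(leaves) in sides or frozenset(all_leaves - leaves) in sides


@dataclass
class MonophylyReport:
    """Per-label monophyly flags for a partition of the tree's leaves."""

    monophyletic: dict[str, bool]
    support: dict[str, float | None] = field(default_factory=dict)

    @property
    def fully_supported(self) -> bool:
        return all(self.monophyletic.values())

    @property
    def fraction_monophyletic(self) -> float:
        if not self.monophyletic:
            return 1.0
        return sum(self.monophyletic.values()) / len(self.monophyletic)


def monophyly_report(tree: dendropy.Tree, p: TaxonPartition) -> MonophylyReport:
    """Test every taxon label of the partition for monophyly on the tree."""
    all_leaves = _leaf_labels(tree)
    if set(p.ids) != all_leaves:
        raise ValueError("partition ids do not match the tree leaf set")
    sides = tree_bipartitions(tree)
    report = MonophylyReport({}, {})
    for label, members in sorted(p.groups().items()):
        members_f = frozenset(members)
        comp = frozenset(all_leaves - members)
        mono = (
            len(members) == 1
            or members == all_leaves
            or members_f in sides
            or comp in sides
        )
        report.monophyletic[label] = bool(mono)
        node = sides.get(members_f) or sides.get(comp)
        support = None
        if node is not None and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        report.support[label] = support
    return report


def bootstrap_support(
    genomes: list[GenomeRecord],
    p: FragmentationParams = FragmentationParams(),
    replicates: int = 100,
    seed: int = 0,
    table=None,
) -> dendropy.Tree:
    """Fragment-resampling bootstrap on the proteome-distance NJ tree.

    Each replicate resamples every genome's query fragments with
    replacement, recomputes the symmetrized fragmented-proteome matrix
    and its NJ tree, and scores each internal edge of the reference
    tree by the percentage of replicate trees containing the same
    bipartition.  Supports are stored as internal-node labels.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(genomes) < 4:
        raise ValueError("bootstrap support requires at least 4 genomes")
    if table is None:
        table = fragment_score_table(genomes, p)
    ref_matrix = symmetrize(table.matrix())
    ref_tree = nj_tree(distance_from_similarity(ref_matrix))
    all_leaves = frozenset(g.id for g in genomes)

    def canon(side: frozenset) -> frozenset:
        comp = all_leaves - side
        return min(side, comp, key=lambda s: (len(s), sorted(s)))

    ref_sides = {
        canon(side): node
        for side, node in tree_bipartitions(ref_tree).items()
        if 1 < len(side) < len(all_leaves) - 1
    }
    counts = {side: 0 for side in ref_sides}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = [rng.integers(0, nf, size=nf) for nf in table.n_fragments]
        rep_tree = nj_tree(distance_from_similarity(symmetrize(table.matrix(idx))))
        rep_sides = {
            canon(side)
            for side in tree_bipartitions(rep_tree)
            if 1 < len(side) < len(all_leaves) - 1
        }
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    for side, node in ref_sides.items():
        node.label = f"{100.0 * counts[side] / replicates:g}"
    return ref_tree
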