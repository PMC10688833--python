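"""Independent oracles used by the test suite.

These deliberately re-derive expected results through different
algorithms and libraries than the package implementation: an exhaustive
affine-gap Smith-Waterman HSP enumerator (plain DP with masking, numba
compiled), path-metric distance matrices from explicitly generated
additive trees, and MRCA-based monophyly checks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# scoring must mirror the package defaults: match +2, mismatch -3,
# gap of length L costs 5 + 2L, HSPs below 50 discarded, N never matches
MATCH = 2.0
MISMATCH = -3.0
GAP_FIRST = 7.0  # open 5 + extend 2 for the first gap residue
GAP_EXT = 2.0
MIN_SCORE = 50.0

_CODE = {c: i for i, c in enumerate("ACGTN")}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


@njit(cache=True)
def _sw_once(a, b, amask, bmask):  # pragma: no cover - compiled
    """One optimal local alignment; returns (score, aligned pairs array)."""
    n, m = len(a), len(b)
    NEG = -1e12
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (move along b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (move along a)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop,1 diag,2 E,3 F
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - GAP_EXT, H[i, j - 1] - GAP_FIRST)
            F[i, j] = max(F[i - 1, j] - GAP_EXT, H[i - 1, j] - GAP_FIRST)
            if amask[i - 1] or bmask[j - 1]:
                s = NEG
            elif a[i - 1] == b[j - 1] and a[i - 1] < 4:
                s = MATCH
            else:
                s = MISMATCH
            diag = H[i - 1, j - 1] + s
            h = 0.0
            p = 0
            if diag > h:
                h, p = diag, 1
            if E[i, j] > h:
                h, p = E[i, j], 2
            if F[i, j] > h:
                h, p = F[i, j], 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    # traceback
    pairs = np.empty((n + m, 2), dtype=np.int64)
    k = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        p = ptr[i, j]
        if p == 0:
            break
        if p == 1:
            pairs[k, 0] = i - 1
            pairs[k, 1] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif p == 2:
            # walk back along the gap in a
            while j > 0 and E[i, j] == E[i, j - 1] - GAP_EXT and E[i, j] > H[i, j - 1] - GAP_FIRST:
                j -= 1
            j -= 1
        else:
            while i > 0 and F[i, j] == F[i - 1, j] - GAP_EXT and F[i, j] > H[i - 1, j] - GAP_FIRST:
                i -= 1
            i -= 1
    return best, pairs[:k][::-1]


def sw_hsps(a_seq: str, b_seq: str, min_score: float = MIN_SCORE):
    """All HSPs >= min_score by iterated optimal alignment with masking."""
    a, b = encode(a_seq), encode(b_seq)
    amask = np.zeros(len(a), dtype=np.bool_)
    bmask = np.zeros(len(b), dtype=np.bool_)
    out = []
    for _ in range(64):
        score, pairs = _sw_once(a, b, amask, bmask)
        if score < min_score or len(pairs) == 0:
            break
        out.append((score, pairs))
        amask[pairs[:, 0]] = True
        bmask[pairs[:, 1]] = True
    return out


def oracle_identity_counts(a_seq: str, b_seq: str) -> tuple[int, int]:
    """Merged per-position identity counts on both genomes, both strands."""
    ident_a = np.zeros(len(a_seq), dtype=np.bool_)
    ident_b = np.zeros(len(b_seq), dtype=np.bool_)
    for strand, bs in (("+", b_seq), ("-", revcomp(b_seq))):
        a_cov = np.zeros(len(a_seq), dtype=np.bool_)
        b_cov = np.zeros(len(b_seq), dtype=np.bool_)
        a_id = np.zeros(len(a_seq), dtype=np.bool_)
        b_id = np.zeros(len(b_seq), dtype=np.bool_)
        for score, pairs in sw_hsps(a_seq, bs):
            for i, j in pairs:
                jj = j if strand == "+" else len(b_seq) - 1 - j
                m = a_seq[i] == bs[j] and a_seq[i] != "N"
                if not a_cov[i]:
                    a_cov[i] = True
                    a_id[i] = m
                if not b_cov[jj]:
                    b_cov[jj] = True
                    b_id[jj] = m
        ident_a |= a_id
        ident_b |= b_id
    return int(ident_a.sum()), int(ident_b.sum())


def oracle_similarity(a_seq: str, b_seq: str) -> float:
    ia, ib = oracle_identity_counts(a_seq, b_seq)
    return 100.0 * (ia + ib) / (len(a_seq) + len(b_seq))


# ---------------------------------------------------------------------------
# random additive trees


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random unrooted binary tree with positive branch lengths.

    Returns (labels, distance_matrix, bipartitions) where bipartitions
    is the set of canonical non-trivial splits (frozenset of the side
    containing the first label's complement-free choice: the smaller
    side, ties by sorted labels).
    """
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    # adjacency: node -> list of (node, weight); leaves are 0..n-1
    edges: dict[tuple[int, int], float] = {}
    next_node = n_leaves

    def add_edge(u, v, w):
        edges[(min(u, v), max(u, v))] = w

    def wlen():
        return float(rng.uniform(0.05, 1.0))

    # start with a star on the first three leaves
    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(leaf, center, wlen())
    for leaf in range(3, n_leaves):
        # split a random existing edge with a new internal node
        (u, v), w = list(edges.items())[rng.integers(0, len(edges))]
        del edges[(u, v)]
        mid = next_node
        next_node += 1
        t = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * t)
        add_edge(mid, v, w * (1 - t))
        add_edge(leaf, mid, wlen())

    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    # path distances by BFS from each leaf
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]

    # bipartitions: for each edge, leaves on one side
    splits = set()
    for (u, v) in edges:
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, _ in adj[x]:
                if y == v and x == u:
                    continue
                if (min(x, y), max(x, y)) == (min(u, v), max(u, v)):
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(labels[i] for i in seen if i < n_leaves)
        if 1 < len(side) < n_leaves - 1:
            splits.add(canonical_split(side, frozenset(labels)))
    return labels, D, splits


def canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    comp = all_leaves - side
    return min(side, comp, key=lambda s: (len(s), sorted(s)))


def tree_splits(tree, labels) -> set:
    """Canonical non-trivial splits of a dendropy tree (package-independent
    traversal via ad-hoc recursion over child nodes)."""
    all_leaves = frozenset(labels)
    splits = set()

    def below(node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.taxon.label])
        return frozenset().union(*(below(c) for c in node.child_nodes()))

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = below(node)
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(canonical_split(side, all_leaves))
    return splits


def mrca_monophyly(tree, leaves: set[str]) -> bool:
    """Monophyly via dendropy MRCA after rooting at an outside leaf."""
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if len(leaves) == 1 or leaves == all_leaves:
        return True
    outside = sorted(all_leaves - leaves)[0]
    t = tree.clone(depth=1)
    out_node = t.find_node_with_taxon_label(outside)
    t.reroot_at_edge(out_node.edge, update_bipartitions=False)
    taxa = [t.taxon_namespace.get_taxon(l) for l in sorted(leaves)]
    mrca = t.mrca(taxa=taxa)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == set(leaves)
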