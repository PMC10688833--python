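import numpy as np
import pytest

from phagetaxkit.records import ClusterRow, ClusterTable, SimilarityMatrix, TaxonPartition
from phagetaxkit.taxon_partition import (
    borderline_pairs,
    compare_partitions,
    novel_genus_name,
    order_rows,
    propose_genera,
    propose_subclusters,
    threshold_partition,
)


def matrix_from_pairs(ids, pairs, default=0.0):
    n = len(ids)
    vals = np.full((n, n), default)
    np.fill_diagonal(vals, 100.0)
    idx = {g: i for i, g in enumerate(ids)}
    for (a, b), v in pairs.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = v
    return SimilarityMatrix(ids, vals)


def groups_of(p: TaxonPartition) -> set[frozenset]:
    return {frozenset(m) for m in p.groups().values()}


class TestThresholdPartition:
    def test_all_pairs_above_threshold_single_cluster(self):
        m = matrix_from_pairs("ABC", {("A", "B"): 90, ("A", "C"): 85, ("B", "C"): 80})
        p = threshold_partition(m, 70)
        assert groups_of(p) == {frozenset("ABC")}

    def test_simple_split(self):
        m = matrix_from_pairs("ABC", {("A", "B"): 80, ("A", "C"): 60, ("B", "C"): 60})
        p = threshold_partition(m, 70)
        assert groups_of(p) == {frozenset("AB"), frozenset("C")}

    def test_linkage_choice_changes_chain_resolution(self):
        m = matrix_from_pairs("ABC", {("A", "B"): 75, ("B", "C"): 75, ("A", "C"): 50})
        assert groups_of(threshold_partition(m, 70, "complete")) == {
            frozenset("AB"),
            frozenset("C"),
        }
        assert groups_of(threshold_partition(m, 70, "single")) == {frozenset("ABC")}

    def test_labels_follow_lexicographic_first_member(self):
        m = matrix_from_pairs(
            ["d", "a", "c", "b"],
            {("a", "c"): 90, ("b", "d"): 90},
        )
        p = threshold_partition(m, 70)
        assert p.assignment == {"a": "G1", "c": "G1", "b": "G2", "d": "G2"}

    def test_extreme_thresholds(self):
        m = matrix_from_pairs("ABCD", {("A", "B"): 50}, default=10.0)
        assert len(groups_of(threshold_partition(m, 0.5))) == 1
        assert len(groups_of(threshold_partition(m, 100))) == 4

    def test_asymmetric_matrix_rejected(self):
        vals = np.array([[100.0, 60.0], [40.0, 100.0]])
        m = SimilarityMatrix(["a", "b"], vals, "proteome")
        with pytest.raises(ValueError, match="symmetrize"):
            threshold_partition(m, 70)


class TestBorderlinePairs:
    def test_band_is_half_open(self):
        m = matrix_from_pairs("ABC", {("A", "B"): 66, ("A", "C"): 70, ("B", "C"): 64})
        out = borderline_pairs(m, 70, 5)
        assert out == [("A", "B", 66.0)]  # 70 excluded (>= theta), 64 below band

    def test_empty_region(self):
        m = matrix_from_pairs("AB", {("A", "B"): 90})
        assert borderline_pairs(m, 70, 5) == []


class TestOrderRows:
    def test_blocks_stay_contiguous(self, rng):
        ids = [f"g{i}" for i in range(9)]
        blocks = [ids[:3], ids[3:6], ids[6:]]
        pairs = {}
        for block in blocks:
            for i, a in enumerate(block):
                for b in block[i + 1 :]:
                    pairs[(a, b)] = 90 + rng.uniform(-3, 3)
        m = matrix_from_pairs(ids, pairs, default=5.0)
        order = order_rows(m)
        for block in blocks:
            positions = sorted(order.index(g) for g in block)
            assert positions == list(range(positions[0], positions[0] + len(block)))


class TestProposeGenera:
    @staticmethod
    def table(rows):
        return ClusterTable(ClusterRow(*r) for r in rows)

    def test_identical_partition_yields_zero_novel(self):
        t = self.table([("p1", "A", "A1", "Gx"), ("p2", "A", "A1", "Gx")])
        p = TaxonPartition("genus", {"p1": "G1", "p2": "G1"})
        proposal = propose_genera(p, t)
        assert proposal.n_novel == 0
        assert proposal.entries[0]["name"] == "Gx"

    def test_split_genus_yields_two_novel(self):
        t = self.table(
            [("p1", "A", None, "Gx"), ("p2", "A", None, "Gx"), ("p3", "A", None, "Gx")]
        )
        p = TaxonPartition("genus", {"p1": "G1", "p2": "G1", "p3": "G2"})
        proposal = propose_genera(p, t)
        assert proposal.n_novel == 2

    def test_novel_name_from_first_member(self):
        assert novel_genus_name({"Yecey3", "Zeta"}) == "Yecey3virus"
        assert novel_genus_name({"D29"}) == "D29virus"


class TestProposeSubclusters:
    @staticmethod
    def table(rows):
        return ClusterTable(ClusterRow(*r) for r in rows)

    def test_undivided_cluster_gets_numbered_subclusters(self):
        t = self.table([(f"p{i}", "J", None, None) for i in range(4)])
        genus = TaxonPartition(
            "genus", {"p0": "G1", "p1": "G1", "p2": "G2", "p3": "G2"}
        )
        prop = propose_subclusters(genus, t)
        assert prop.created == ["J1", "J2"]
        assert prop.assignment["p0"] == "J1" and prop.assignment["p2"] == "J2"

    def test_exact_match_retains_label(self):
        t = self.table([("p1", "A", "A1", None), ("p2", "A", "A1", None)])
        genus = TaxonPartition("genus", {"p1": "G1", "p2": "G1"})
        prop = propose_subclusters(genus, t)
        assert prop.retained == ["A1"] and prop.created == [] and prop.removed == []

    def test_largest_overlap_inherits_existing_label(self):
        # one existing subcluster split 3/2/3: the group overlapping most
        # (ties by size then lexicographic member) keeps the old label
        rows = [(f"q{i}", "A", "A2", None) for i in range(8)]
        t = self.table(rows)
        genus = TaxonPartition(
            "genus",
            {
                "q0": "Ga", "q1": "Ga",
                "q2": "Gb", "q3": "Gb", "q4": "Gb",
                "q5": "Gc", "q6": "Gc", "q7": "Gc",
            },
        )
        prop = propose_subclusters(genus, t)
        # Gb ({q2,q3,q4}) wins the tie against Gc by lexicographic member
        assert prop.assignment["q2"] == "A2"
        assert prop.assignment["q0"] != "A2" and prop.assignment["q5"] != "A2"
        assert len(prop.created) == 2
        assert all(lbl.startswith("A") for lbl in prop.created)

    def test_no_label_reused_twice(self):
        t = self.table(
            [("p1", "A", "A1", None), ("p2", "A", "A1", None), ("p3", "A", "A2", None)]
        )
        genus = TaxonPartition("genus", {"p1": "G1", "p2": "G2", "p3": "G2"})
        prop = propose_subclusters(genus, t)
        labels = list(prop.assignment.values())
        by_group = {}
        for gid, lbl in prop.assignment.items():
            by_group.setdefault(genus.assignment[gid], set()).add(lbl)
        flat = [lbl for s in by_group.values() for lbl in s]
        assert len(flat) == len(set(flat))

    def test_group_spanning_clusters_rejected(self):
        t = self.table([("p1", "A", None, None), ("p2", "B", None, None)])
        genus = TaxonPartition("genus", {"p1": "G1", "p2": "G1"})
        with pytest.raises(ValueError, match="containment"):
            propose_subclusters(genus, t)


class TestComparePartitions:
    def test_identical_partitions_index_one(self):
        p = TaxonPartition("genus", {"a": "x", "b": "x", "c": "y"})
        q = TaxonPartition("genus", {"a": "u", "b": "u", "c": "v"})
        table, ari = compare_partitions(p, q)
        assert ari == 1.0

    def test_one_cluster_vs_singletons_is_zero(self):
        p = TaxonPartition("genus", {c: "one" for c in "abcd"})
        q = TaxonPartition("genus", {c: c for c in "abcd"})
        _, ari = compare_partitions(p, q)
        assert ari == pytest.approx(0.0, abs=1e-12)

    def test_id_mismatch_rejected(self):
        p = TaxonPartition("genus", {"a": "x"})
        q = TaxonPartition("genus", {"b": "x"})
        with pytest.raises(ValueError):
            compare_partitions(p, q)

    def test_monotone_refinement_in_threshold(self, rng):
        ids = [f"g{i}" for i in range(6)]
        vals = rng.uniform(0, 100, (6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 100.0)
        m = SimilarityMatrix(ids, vals)
        sizes = [
            len(groups_of(threshold_partition(m, t))) for t in (10, 40, 70, 99.9)
        ]
        assert sizes == sorted(sizes)
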