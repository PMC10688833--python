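import pytest

from phagetaxkit.concordance import (
    ReorgEdit,
    apply_reorganization,
    before_after_report,
    build_groups,
    concordance_statistic,
    edits_from_proposal,
    round_percent,
)
from phagetaxkit.records import ClusterRow, ClusterTable, TaxonPartition


def table_of(rows) -> ClusterTable:
    return ClusterTable(ClusterRow(*r) for r in rows)


class TestBuildGroups:
    def test_subclustered_cluster_one_group_per_subcluster(self):
        rows = [(f"p{i}", "A", f"A{1 + i % 19}", None) for i in range(38)]
        gt = build_groups(table_of(rows))
        assert len(gt) == 19

    def test_undivided_cluster_is_one_group(self):
        rows = [(f"j{i}", "J", None, None) for i in range(11)]
        gt = build_groups(table_of(rows))
        assert set(gt.groups) == {"J"} and len(gt.groups["J"]) == 11

    def test_mixed_cluster_gets_unplaced_group(self):
        rows = [("p1", "A", "A1", None), ("p2", "A", None, None)]
        gt = build_groups(table_of(rows))
        assert set(gt.groups) == {"A1", "A-unplaced"}

    def test_empty_table(self):
        assert len(build_groups(ClusterTable())) == 0

    def test_sentinels_ignored(self):
        rows = [("p1", "A", "A1", None), ("s1", "SINGLETON", None, None)]
        assert set(build_groups(table_of(rows)).groups) == {"A1"}


class TestConcordanceStatistic:
    def test_direct_count_example(self):
        rows = [
            ("a", "S", "S1", None), ("b", "S", "S1", None),
            ("c", "T", "T2", None),
            ("d", "J", None, None), ("e", "J", None, None),
        ]
        genus = TaxonPartition(
            "genus", {"a": "g1", "b": "g1", "c": "g2", "d": "g3", "e": "g4"}
        )
        rep = concordance_statistic(build_groups(table_of(rows)), genus)
        assert rep.n_groups == 3 and rep.n_supported == 2
        assert rep.statistic == 66.7

    def test_perfect_bijection_both_100(self):
        rows = [("a", "A", "A1", None), ("b", "B", "B1", None)]
        genus = TaxonPartition("genus", {"a": "g1", "b": "g2"})
        rep = concordance_statistic(build_groups(table_of(rows)), genus)
        assert rep.statistic == 100.0 and rep.strict_statistic == 100.0

    def test_shared_genus_lowers_strict_only(self):
        rows = [("a", "A", "A1", None), ("b", "A", "A2", None)]
        genus = TaxonPartition("genus", {"a": "g1", "b": "g1"})
        rep = concordance_statistic(build_groups(table_of(rows)), genus)
        assert rep.statistic == 100.0
        assert rep.strict_statistic == 0.0
        assert rep.strict_statistic <= rep.statistic

    def test_missing_genus_names_genome(self):
        rows = [("a", "A", "A1", None)]
        with pytest.raises(ValueError, match="'a'"):
            concordance_statistic(
                build_groups(table_of(rows)), TaxonPartition("genus", {})
            )

    def test_relabelling_invariance(self):
        rows = [("a", "A", "A1", None), ("b", "A", "A2", None), ("c", "B", None, None)]
        g1 = TaxonPartition("genus", {"a": "x", "b": "y", "c": "z"})
        g2 = TaxonPartition("genus", {"a": "1", "b": "2", "c": "3"})
        r1 = concordance_statistic(build_groups(table_of(rows)), g1)
        r2 = concordance_statistic(build_groups(table_of(rows)), g2)
        assert (r1.statistic, r1.strict_statistic) == (r2.statistic, r2.strict_statistic)

    def test_rounding_half_up_one_decimal(self):
        assert round_percent(100 * 60 / 72) == 83.3
        assert round_percent(100 * 82 / 84) == 97.6
        assert round_percent(66.65) == 66.7


class TestApplyReorganization:
    def test_remove_and_reassign_mirrors_g5_into_g3(self):
        rows = [
            ("g3a", "G", "G3", None), ("g3b", "G", "G3", None),
            ("ants", "G", "G5", None),
        ]
        edits = [ReorgEdit.make("remove_subcluster", label="G5", into="G3")]
        out, audit = apply_reorganization(table_of(rows), edits)
        assert out["ants"].subcluster == "G3"
        assert not [r for r in out if r.subcluster == "G5"]
        assert len(audit) == 1

    def test_create_then_merge_back_restores_table(self):
        rows = [("a", "A", "A1", None), ("b", "A", "A1", None)]
        t = table_of(rows)
        edits = [
            ReorgEdit.make("create_subcluster", cluster="A", label="A9", members=["b"]),
            ReorgEdit.make("merge_subclusters", sources=["A9"], target="A1"),
        ]
        out, audit = apply_reorganization(t, edits)
        assert out == t and len(audit) == 2

    def test_splitting_subcluster_adds_groups(self):
        rows = [(f"q{i}", "A", "A2", None) for i in range(8)]
        genus = {f"q{i}": g for i, g in enumerate("aabbbccc")}
        edits = [
            ReorgEdit.make("create_subcluster", cluster="A", label="A20", members=["q0", "q1"]),
            ReorgEdit.make("create_subcluster", cluster="A", label="A21", members=["q5", "q6", "q7"]),
        ]
        t = table_of(rows)
        before = concordance_statistic(build_groups(t), TaxonPartition("genus", genus))
        out, _ = apply_reorganization(t, edits)
        after = concordance_statistic(build_groups(out), TaxonPartition("genus", genus))
        assert before.n_groups == 1 and after.n_groups == 3
        assert before.statistic == 0.0 and after.statistic == 100.0

    def test_bad_edit_identifies_index(self):
        rows = [("a", "A", "A1", None)]
        edits = [
            ReorgEdit.make("reassign_genome", genome="a", subcluster="A2"),
            ReorgEdit.make("remove_subcluster", label="Zz"),
        ]
        with pytest.raises(ValueError, match="edit 1"):
            apply_reorganization(table_of(rows), edits)

    def test_create_violating_prefix_rejected(self):
        rows = [("a", "A", None, None)]
        edits = [ReorgEdit.make("create_subcluster", cluster="A", label="B1", members=["a"])]
        with pytest.raises(ValueError, match="prefix"):
            apply_reorganization(table_of(rows), edits)


class TestBeforeAfter:
    def test_no_edits_zero_delta(self):
        rows = [("a", "A", "A1", None), ("b", "B", None, None)]
        genus = TaxonPartition("genus", {"a": "x", "b": "y"})
        rep = before_after_report(table_of(rows), [], genus, genus)
        assert rep.delta == 0.0

    def test_split_fixes_impure_group(self):
        rows = [
            ("a", "A", "A1", None), ("b", "A", "A1", None),
            ("c", "B", "B1", None), ("d", "C", "C1", None),
        ]
        genus = TaxonPartition("genus", {"a": "x", "b": "y", "c": "z", "d": "w"})
        edits = [ReorgEdit.make("create_subcluster", cluster="A", label="A2", members=["b"])]
        rep = before_after_report(table_of(rows), edits, genus, genus)
        assert rep.before.statistic == 66.7
        assert rep.after.statistic == 100.0
        assert rep.delta == 33.3

    def test_edits_from_proposal_round_trip(self):
        rows = [(f"p{i}", "J", None, None) for i in range(4)]
        t = table_of(rows)
        proposed = TaxonPartition(
            "subcluster", {"p0": "J1", "p1": "J1", "p2": "J2", "p3": "J2"}
        )
        edits = edits_from_proposal(t, proposed)
        out, _ = apply_reorganization(t, edits)
        assert {r.phage_id: r.subcluster for r in out} == proposed.assignment
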