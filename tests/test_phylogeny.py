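import dendropy
import numpy as np
import pytest

from conftest import mutate_seq, random_seq
from oracles import mrca_monophyly, random_additive_tree, tree_splits
from phagetaxkit.phylogeny import (
    DistanceMatrix,
    bootstrap_support,
    distance_from_similarity,
    is_monophyletic,
    monophyly_report,
    nj_tree,
)
from phagetaxkit.records import GenomeRecord, SimilarityMatrix, TaxonPartition


def parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


class TestDistanceConversion:
    def test_similarity_to_distance_values(self):
        m = SimilarityMatrix(
            ["a", "b", "c"],
            [[100, 0, 66.67], [0, 100, 50], [66.67, 50, 100]],
        )
        d = distance_from_similarity(m)
        assert d.values[0, 1] == 1.0
        assert d.values[0, 2] == pytest.approx(0.3333)
        assert np.all(np.diag(d.values) == 0)

    def test_asymmetric_matrix_rejected(self):
        m = SimilarityMatrix(["a", "b"], [[100, 60], [40, 100]], "proteome")
        with pytest.raises(ValueError, match="symmetrize"):
            distance_from_similarity(m)


class TestNeighborJoining:
    def test_recovers_known_quartet_with_exact_lengths(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4):1)
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(ids, D))
        splits = tree_splits(tree, ids)
        assert splits == {frozenset({"A", "B"})}
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 0.0, "b": 2.0, "c": 3.0}

    def test_ultrametric_cherries(self):
        D = np.array(
            [[0, 0.2, 1, 1], [0.2, 0, 1, 1], [1, 1, 0, 0.2], [1, 1, 0.2, 0]]
        )
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], D))
        assert tree_splits(tree, ["a", "b", "c", "d"]) == {frozenset({"a", "b"})}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]])))

    def test_additive_recovery_small_sample(self, rng):
        """NJ reproduces the generating topology on random additive trees
        (the full 100-tree sweep runs in the acceptance suite)."""
        for _ in range(15):
            n = int(rng.integers(4, 13))
            labels, D, true_splits = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(labels, D))
            assert tree_splits(tree, labels) == true_splits


class TestMonophyly:
    def test_clade_and_non_clade(self):
        t = parse("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_conventions(self):
        t = parse("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(t, {"A"})
        assert is_monophyletic(t, {"A", "B", "C", "D"})

    def test_complement_symmetry(self):
        t = parse("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        leaves = {"A", "B", "C", "D", "E"}
        for sub in ({"A", "B"}, {"A", "D"}, {"D", "E"}, {"A", "B", "C"}):
            assert is_monophyletic(t, sub) == is_monophyletic(t, leaves - sub)

    def test_unknown_leaf_rejected(self):
        t = parse("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(t, {"A", "Z"})

    def test_agrees_with_mrca_oracle_on_random_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            labels, D, _ = random_additive_tree(rng, n)
            from phagetaxkit.phylogeny import nj_tree as _nj

            tree = _nj(DistanceMatrix(labels, D))
            for _ in range(6):
                k = int(rng.integers(1, n))
                sub = set(rng.choice(labels, size=k, replace=False))
                assert is_monophyletic(tree, sub) == mrca_monophyly(tree, sub)


class TestMonophylyReport:
    def test_singleton_partition_all_true(self):
        t = parse("((A:1,B:1):1,(C:1,D:1):1);")
        p = TaxonPartition("genus", {x: x for x in "ABCD"})
        assert monophyly_report(t, p).fully_supported

    def test_interleaved_labels_fail(self):
        t = parse("((A:1,B:1):1,(C:1,D:1):1);")
        p = TaxonPartition("genus", {"A": "x", "C": "x", "B": "y", "D": "y"})
        rep = monophyly_report(t, p)
        assert not rep.fully_supported

    def test_outlier_plus_groups_structure(self):
        # one tight group, one distinct pair, one outlier singleton
        t = parse("(((H1a:0.1,H1b:0.1):0.9,Pred:1.5):0.5,(H2a:0.1,H2b:0.1):0.9);")
        p = TaxonPartition(
            "genus",
            {
                "H1a": "Konstantinevirus",
                "H1b": "Konstantinevirus",
                "Pred": "Predatorvirus",
                "H2a": "H2virus",
                "H2b": "H2virus",
            },
        )
        rep = monophyly_report(t, p)
        assert rep.fully_supported

    def test_leaf_mismatch_rejected(self):
        t = parse("((A:1,B:1):1,(C:1,D:1):1);")
        p = TaxonPartition("genus", {"A": "x", "B": "x"})
        with pytest.raises(ValueError, match="leaf"):
            monophyly_report(t, p)


class TestBootstrap:
    @staticmethod
    def planted_genomes(rng, n_per=3, length=900):
        base1, base2 = random_seq(rng, length), random_seq(rng, length)
        out = []
        for i in range(n_per):
            out.append(GenomeRecord(f"x{i}", mutate_seq(rng, base1, 20)))
            out.append(GenomeRecord(f"y{i}", mutate_seq(rng, base2, 20)))
        return out

    def test_deep_split_gets_high_support_and_seed_determinism(self, rng):
        genomes = self.planted_genomes(rng)
        t1 = bootstrap_support(genomes, replicates=20, seed=7)
        t2 = bootstrap_support(genomes, replicates=20, seed=7)
        sides1 = {
            frozenset(l.taxon.label for l in node.leaf_iter()): node.label
            for node in t1.preorder_node_iter()
            if node.parent_node is not None and not node.is_leaf()
        }
        split = frozenset({"x0", "x1", "x2"})
        comp = frozenset({"y0", "y1", "y2"})
        label = sides1.get(split) or sides1.get(comp)
        assert label is not None and float(label) >= 95.0
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_single_replicate_supports_binary(self, rng):
        genomes = self.planted_genomes(rng, n_per=2)
        t = bootstrap_support(genomes, replicates=1, seed=3)
        for node in t.preorder_node_iter():
            if node.parent_node is not None and node.label is not None:
                assert float(node.label) in (0.0, 100.0)

    def test_invalid_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(self.planted_genomes(rng, n_per=2), replicates=0)
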