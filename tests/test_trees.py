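import numpy as np
import pytest

from pmpi.simulate import ModelParams, simulate_dataset, trees_from_dataset
from pmpi.trees import (
    GeneTree,
    aligned_vectors,
    clade_lengths,
    is_agreement_subset,
    mast_pair,
    pair_filter,
    read_newick,
    read_newick_dir,
    reroot_at_leaf,
    restrict_to,
    to_newick,
    write_newick,
)
from tests.conftest import brute_force_mast_size, random_binary_tree


@pytest.fixture
def fig_trees(tmp_path):
    """Two 4-taxon trees: in the second, taxa 2 and 3 are sisters (HGT-like)."""
    (tmp_path / "red.nwk").write_text("((1:1.0,2:2.0):0.5,(3:1.5,4:1.0):0.5);\n")
    (tmp_path / "blue.nwk").write_text("((1:1.0,(2:1.0,3:1.0):0.5):0.5,4:2.0);\n")
    red = read_newick(tmp_path / "red.nwk")[0]
    blue = read_newick(tmp_path / "blue.nwk")[0]
    return red, blue


class TestNewickIO:
    def test_parse_counts_leaves_and_lengths(self, tmp_path):
        f = tmp_path / "t.nwk"
        f.write_text("((A:1,B:2):0.5,C:3);\n")
        (tree,) = read_newick(f)
        assert tree.leaf_labels() == {"A", "B", "C"}

    def test_missing_length_is_an_error_by_default(self, tmp_path):
        f = tmp_path / "t.nwk"
        f.write_text("((A,B:2):0.5,C:3);\n")
        with pytest.raises(ValueError, match="missing branch length"):
            read_newick(f)
        (tree,) = read_newick(f, missing_length="zero")
        assert tree.leaf_labels() == {"A", "B", "C"}

    def test_malformed_newick_names_file(self, tmp_path):
        f = tmp_path / "bad.nwk"
        f.write_text("((A:1,B:2;\n")
        with pytest.raises(ValueError, match="bad.nwk"):
            read_newick(f)

    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(0)
        tree = random_binary_tree(rng, ["a", "b", "c", "d", "e"])
        tree.id = "gene1"
        write_newick([tree], tmp_path / "out")
        (back,) = read_newick_dir(tmp_path / "out")
        assert back.leaf_labels() == tree.leaf_labels()
        k1 = clade_lengths(reroot_at_leaf(tree, "a"), merge_root_split=False)
        k2 = clade_lengths(reroot_at_leaf(back, "a"), merge_root_split=False)
        assert set(k1) == set(k2)
        for key in k1:
            assert k1[key] == pytest.approx(k2[key])


class TestRestrictAndLengths:
    def test_path_length_conservation(self):
        """Leaf-to-leaf path lengths survive restriction and rerooting."""
        rng = np.random.default_rng(1)
        labels = [str(i) for i in range(8)]
        tree = random_binary_tree(rng, labels)

        def leaf_dist(t, a, b):
            m = clade_lengths(reroot_at_leaf(t, a), merge_root_split=False)
            # distance from a (the root position) to b: sum of edges on the
            # path = all edges whose clade contains b, plus a's pendant edge
            total = m[frozenset([a])]
            for key, length in m.items():
                if b in key and key != frozenset([a]):
                    total += length
            return total

        keep = {"0", "2", "5", "7"}
        sub = restrict_to(tree, keep)
        for a in sorted(keep):
            for b in sorted(keep - {a}):
                assert leaf_dist(sub, a, b) == pytest.approx(leaf_dist(tree, a, b))


class TestMast:
    def test_identical_trees_full_leaf_set(self):
        rng = np.random.default_rng(2)
        tree = random_binary_tree(rng, ["a", "b", "c", "d", "e", "f"])
        res = mast_pair(tree, tree)
        assert res.leaf_set == tree.leaf_labels()
        np.testing.assert_allclose(*res.vectors())

    def test_hgt_case_agreement_set(self, fig_trees):
        """An HGT-displaced taxon is excluded: the agreement set is {1,2,4}."""
        red, blue = fig_trees
        res = mast_pair(red, blue)
        assert res.leaf_set == frozenset({"1", "2", "4"})
        assert is_agreement_subset(red, blue, {"1", "2", "4"})
        assert not is_agreement_subset(red, blue, {"1", "2", "3", "4"})

    def test_cardinality_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n_leaves = int(rng.integers(4, 9))
            labels = [str(i) for i in range(n_leaves)]
            t1 = random_binary_tree(rng, labels)
            t2 = random_binary_tree(rng, labels)
            res = mast_pair(t1, t2)
            assert res.size == brute_force_mast_size(t1, t2)
            assert is_agreement_subset(t1, t2, res.leaf_set)

    def test_symmetry_of_cardinality(self):
        rng = np.random.default_rng(4)
        labels = [str(i) for i in range(7)]
        t1, t2 = random_binary_tree(rng, labels), random_binary_tree(rng, labels)
        assert mast_pair(t1, t2).size == mast_pair(t2, t1).size

    def test_no_shared_leaves_empty_result(self):
        rng = np.random.default_rng(5)
        t1 = random_binary_tree(rng, ["a", "b", "c"])
        t2 = random_binary_tree(rng, ["x", "y", "z"])
        res = mast_pair(t1, t2)
        assert res.size == 0
        assert res.aligned.empty

    def test_induced_lengths_sum_contracted_paths(self, fig_trees):
        red, blue = fig_trees
        res = mast_pair(red, blue)
        lens = dict(zip(res.aligned["edge"], res.aligned["len_b"]))
        # blue restricted to {1,2,4}: taxon 2's pendant absorbs the
        # contracted (2,3)-ancestor edge: 1.0 + 0.5
        assert lens["2"] == pytest.approx(1.5)

    def test_overlapping_taxon_sets(self):
        rng = np.random.default_rng(6)
        t1 = random_binary_tree(rng, ["a", "b", "c", "d", "e"])
        t2 = random_binary_tree(rng, ["c", "d", "e", "f", "g"])
        res = mast_pair(t1, t2)
        assert res.leaf_set <= {"c", "d", "e"}
        assert res.size == brute_force_mast_size(t1, t2)


class TestPairFilter:
    def _results(self):
        rng = np.random.default_rng(7)
        labels = [str(i) for i in range(12)]
        t1 = random_binary_tree(rng, labels)
        t1.id = "t1"
        t2 = GeneTree(id="t2", root=t1.root)  # identical topology
        return {("t1", "t2"): mast_pair(t1, t2)}

    def test_inclusive_threshold(self):
        results = self._results()
        assert pair_filter(results, min_leaves=12) == [("t1", "t2")]
        assert pair_filter(results, min_leaves=13) == []

    def test_min_leaves_validated(self):
        with pytest.raises(ValueError):
            pair_filter({}, min_leaves=2)

    def test_aligned_vectors_feed_regression(self):
        vecs = aligned_vectors(self._results(), min_leaves=10)
        (x, y), = vecs.values()
        assert x.shape == y.shape
        np.testing.assert_allclose(x, y)  # identical trees


class TestSimulatedTrees:
    def test_caterpillar_edges_carry_table_rows(self):
        ds = simulate_dataset(
            ModelParams(n=4, k=2, tau=25, pair_drop_prob=0.0, seed=8)
        )
        trees = trees_from_dataset(ds)
        res = mast_pair(trees[0], trees[1])
        assert res.size == 14  # (tau + 3) / 2 taxa, full agreement
        xa, xb = res.vectors()
        assert sorted(xa) == sorted(ds.lengths.iloc[0])
        assert sorted(xb) == sorted(ds.lengths.iloc[1])

    def test_even_tau_rejected(self):
        ds = simulate_dataset(ModelParams(n=4, k=2, tau=24, seed=8))
        with pytest.raises(ValueError, match="odd tau"):
            trees_from_dataset(ds)

    def test_newick_round_trip_of_simulated_trees(self, tmp_path):
        ds = simulate_dataset(
            ModelParams(n=3, k=1, tau=9, pair_drop_prob=0.0, seed=9)
        )
        trees = trees_from_dataset(ds)
        write_newick(trees, tmp_path)
        back = read_newick_dir(tmp_path)
        res_a = mast_pair(trees[0], trees[1])
        res_b = mast_pair(back[0], back[1])
        assert res_a.leaf_set == res_b.leaf_set
        np.testing.assert_allclose(
            res_a.aligned[["len_a", "len_b"]], res_b.aligned[["len_a", "len_b"]],
            rtol=1e-6,
        )
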