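import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmpi.partdist import (
    MatchingResult,
    Partition,
    RandomModelParams,
    exact_partdist,
    expected_random_similarity,
    greedy_partdist,
    identity_distance,
    normalized_distance,
    random_recolor,
    similarity_graph,
)
from tests.conftest import correctly_clustered_pair, random_partition_pair


def exhaustive_partdist(p: Partition, q: Partition) -> int:
    """Brute force over all color bijections (oracle for exact_partdist)."""
    size = max(len(p), len(q))
    w = np.zeros((size, size), dtype=int)
    for (i, j), s in similarity_graph(p, q).items():
        w[i, j] = s
    best = max(
        sum(w[i, perm[i]] for i in range(size))
        for perm in itertools.permutations(range(size))
    )
    return len(p.universe) - best


class TestPartition:
    def test_from_labels_and_parts_agree(self):
        p1 = Partition.from_labels([0, 0, 1, 1, 2])
        p2 = Partition.from_parts([{0, 1}, {2, 3}, {4}])
        assert p1 == p2

    def test_parts_disjoint_cover(self):
        p = Partition.from_labels([1, 0, 1, 2])
        assert frozenset().union(*p.parts) == p.universe
        assert sum(len(part) for part in p.parts) == len(p.universe)

    def test_overlapping_parts_rejected(self):
        with pytest.raises(ValueError):
            Partition.from_parts([{0, 1}, {1, 2}])

    def test_tsv_round_trip(self, tmp_path):
        p = Partition.from_labels([0, 1, 0, 2])
        p.to_tsv(tmp_path / "p.tsv")
        assert Partition.read_tsv(tmp_path / "p.tsv") == p


class TestIdentityDistance:
    def test_identical_partitions(self):
        p = Partition.from_labels([0, 1, 1, 0])
        assert identity_distance(p, p) == 0

    def test_full_swap_of_equal_parts(self):
        p = Partition.from_labels([0, 0, 1, 1])
        q = Partition.from_labels([1, 1, 0, 0])
        assert identity_distance(p, q) == 4

    def test_two_relabeled_elements(self):
        p = Partition.from_labels([0, 0, 0, 1, 1, 1])
        q = Partition.from_labels([0, 0, 1, 0, 1, 1])
        assert identity_distance(p, q) == 2

    def test_element_mismatch_rejected(self):
        p = Partition.from_labels([0, 1], elements=["a", "b"])
        q = Partition.from_labels([0, 1], elements=["a", "c"])
        with pytest.raises(ValueError, match="element sets"):
            identity_distance(p, q)


class TestSimilarityGraph:
    def test_identical_partitions_diagonal(self):
        p = Partition.from_labels([0, 0, 1, 1, 1])
        edges = similarity_graph(p, p)
        assert edges == {(0, 0): 2, (1, 1): 3}

    def test_disjoint_parts_no_edge(self):
        p = Partition.from_labels([0, 0, 1, 1])
        q = Partition.from_labels([0, 0, 1, 1])
        assert (0, 1) not in similarity_graph(p, q)

    def test_intersection_symmetric_difference_identity(self):
        rng = np.random.default_rng(0)
        p, q = random_partition_pair(rng, n=30)
        for (i, j), s in similarity_graph(p, q).items():
            pi, qj = p.parts[i], q.parts[j]
            d = len(pi ^ qj)
            assert len(pi) + len(qj) == s + (s + d)

    def test_cyclic_majority_structure(self):
        """Three parts whose majorities shift cyclically: optimal distance 3."""
        # blue -> green, red -> blue, green -> red (majorities of 2 of 3 each)
        source = Partition.from_labels(
            ["b", "b", "b", "r", "r", "r", "g", "g", "g"]
        )
        target = Partition.from_labels(
            ["g", "g", "b", "b", "b", "r", "r", "r", "g"]
        )
        edges = similarity_graph(source, target)
        # heaviest edges are the cyclically shifted pairs
        heavy = {e for e, w in edges.items() if w == 2}
        ib, ig, ir = 0, 1, 2  # labels sort as b, g, r
        assert heavy == {(ib, ig), (ir, ib), (ig, ir)}
        assert exact_partdist(source, target).distance == 3
        assert greedy_partdist(source, target).distance == 3
        assert identity_distance(source, target) > 3


class TestGreedyPartdist:
    def test_identical_partitions_zero(self):
        p = Partition.from_labels([0, 1, 2, 0, 1, 2])
        assert greedy_partdist(p, p).distance == 0

    def test_exact_on_correctly_clustered_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            k = int(rng.integers(2, 7))
            p, q = correctly_clustered_pair(rng, n=50, k=k)
            g, e = greedy_partdist(p, q), exact_partdist(p, q)
            assert g.similarity == e.similarity

    def test_half_approximation_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p, q = random_partition_pair(rng, n=60)
            g, e = greedy_partdist(p, q), exact_partdist(p, q)
            assert g.similarity * 2 >= e.similarity

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_similarity_plus_distance_is_n(self, seed):
        rng = np.random.default_rng(seed)
        p, q = random_partition_pair(rng, n=25, max_parts=5)
        for algo in (greedy_partdist, exact_partdist):
            res = algo(p, q)
            assert res.similarity + res.distance == 25
            assert 0 <= res.distance <= 25


class TestExactPartdist:
    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p, q = random_partition_pair(rng, n=24, max_parts=6)
            assert exact_partdist(p, q).distance == exhaustive_partdist(p, q)

    def test_never_exceeds_identity_distance(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            labels = rng.integers(0, 5, 30)
            q_labels = random_recolor(labels, 0.6, rng, k=5)
            p = Partition.from_labels(labels)
            q = Partition.from_labels(q_labels)
            assert exact_partdist(p, q).distance <= identity_distance(p, q)

    def test_symmetric_under_argument_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p, q = random_partition_pair(rng, n=30)
            assert exact_partdist(p, q).distance == exact_partdist(q, p).distance

    def test_unequal_part_counts_padded(self):
        p = Partition.from_labels([0, 0, 1, 1])
        q = Partition.from_labels([0, 1, 2, 3])
        res = exact_partdist(p, q)
        assert res.similarity + res.distance == 4
        assert res.distance == 2

    def test_json_serialization(self):
        p = Partition.from_labels([0, 1])
        res = exact_partdist(p, p)
        assert '"algorithm": "exact"' in res.to_json()


class TestRandomBaseline:
    def test_alpha_one_gives_n(self):
        assert expected_random_similarity(RandomModelParams(1.0, 100, 4)) == 100

    def test_alpha_zero_gives_n_over_k(self):
        assert expected_random_similarity(RandomModelParams(0.0, 100, 4)) == 25

    def test_monte_carlo_matches_expectation(self):
        """Stay-or-uniform process matches E[s] = (k-1) a n / k + n / k."""
        rng = np.random.default_rng(6)
        n, k, alpha, reps = 100, 4, 0.5, 10_000
        labels = np.repeat(np.arange(k), n // k)
        sims = np.empty(reps)
        for i in range(reps):
            sims[i] = (random_recolor(labels, alpha, rng, k=k) == labels).sum()
        expected = expected_random_similarity(RandomModelParams(alpha, n, k))
        se = sims.std(ddof=1) / np.sqrt(reps)
        assert abs(sims.mean() - expected) < 3 * se

    def test_random_partitions_concentrate_at_one_minus_inverse_k(self):
        rng = np.random.default_rng(7)
        n, k = 300, 4
        labels = np.repeat(np.arange(k), n // k)
        dists = []
        for _ in range(30):
            q = Partition.from_labels(random_recolor(labels, 0.0, rng, k=k))
            res = exact_partdist(Partition.from_labels(labels), q)
            dists.append(normalized_distance(res, n))
        assert np.mean(dists) == pytest.approx(1 - 1 / k, abs=0.05)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            RandomModelParams(1.5, 10, 2)


def test_matching_result_invariant_types():
    p = Partition.from_labels([0, 0, 1])
    res = greedy_partdist(p, p)
    assert isinstance(res, MatchingResult)
    assert res.algorithm == "greedy"
    assert dict(res.matching) == {0: 0, 1: 1}
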