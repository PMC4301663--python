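"""Partition distance between a reconstructed and a true gene partition.

A partition assigns each gene a color (its pacemaker).  The identity
distance counts genes whose colors differ outright; the partition distance
minimizes that count over bijections f between the two color sets, which is
a maximum-weight bipartite matching on the part-intersection graph.  Two
solvers are provided: the exact assignment solution, and the greedy
heaviest-edge-first matching, which carries a 1/2-approximation guarantee
in general and is exact whenever every part is "correctly clustered" (a
strict majority of each source part lands in one target part).

Also here: the stay-or-uniform random baseline — each gene keeps its part
with probability alpha and otherwise picks one of the k parts uniformly
(its own included) — with expected identity similarity

    E[s] = (k - 1) * alpha * n / k + n / k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Partition",
    "MatchingResult",
    "RandomModelParams",
    "identity_distance",
    "similarity_graph",
    "greedy_partdist",
    "exact_partdist",
    "normalized_distance",
    "expected_random_similarity",
    "random_recolor",
    "random_partition_pair",
    "correctly_clustered_pair",
]


class Partition:
    """A coloring of a ground element set into disjoint parts.

    Constructed from an element -> color mapping; parts are ordered by
    sorted color label, which fixes the deterministic tie-breaks of the
    greedy matcher.
    """

    def __init__(self, coloring: Mapping):
        if isinstance(coloring, pd.Series):
            coloring = coloring.to_dict()
        self._coloring = dict(coloring)
        self.part_labels = sorted(set(self._coloring.values()), key=repr)
        self.parts = [
            frozenset(e for e, c in self._coloring.items() if c == lab)
            for lab in self.part_labels
        ]
        self.universe = frozenset(self._coloring)

    @classmethod
    def from_labels(cls, labels, elements=None) -> "Partition":
        if isinstance(labels, pd.Series):
            return cls(labels)
        labels = list(labels)
        if elements is None:
            elements = range(len(labels))
        return cls(dict(zip(elements, labels)))

    @classmethod
    def from_parts(cls, parts) -> "Partition":
        coloring = {}
        for i, part in enumerate(parts):
            for e in part:
                if e in coloring:
                    raise ValueError(f"element {e!r} appears in two parts")
                coloring[e] = i
        return cls(coloring)

    def color_of(self, element):
        return self._coloring[element]

    def __len__(self) -> int:
        return len(self.parts)

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and set(self.parts) == set(other.parts)

    def __hash__(self):
        return hash(frozenset(self.parts))

    def to_tsv(self, path) -> None:
        pd.Series(self._coloring).sort_index().rename("part_id").to_csv(
            path, sep="\t", index_label="element_id"
        )

    @classmethod
    def read_tsv(cls, path) -> "Partition":
        df = pd.read_csv(path, sep="\t", index_col="element_id")
        return cls(df.iloc[:, 0])


@dataclass(frozen=True)
class MatchingResult:
    """A bijection between (padded) part sets with its similarity score.

    ``matching`` pairs source-part indices with target-part indices (None
    marks an empty padding part); ``similarity + distance == |N|`` always.
    """

    matching: tuple
    similarity: int
    distance: int
    algorithm: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "algorithm": self.algorithm,
                "similarity": self.similarity,
                "distance": self.distance,
                "matching": [list(m) for m in self.matching],
            }
        )


@dataclass(frozen=True)
class RandomModelParams:
    """Stay-or-uniform recoloring model: stay probability alpha, n genes, k parts."""

    alpha: float
    n: int
    k: int

    def __post_init__(self):
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if self.n < 1 or self.k < 1:
            raise ValueError("n and k must be positive")


def _check_universe(p: Partition, q: Partition) -> None:
    if p.universe != q.universe:
        missing = p.universe ^ q.universe
        raise ValueError(
            f"partitions cover different element sets (symmetric difference "
            f"size {len(missing)})"
        )


def identity_distance(p: Partition, q: Partition) -> int:
    """Number of elements whose colors differ under the identity mapping."""
    _check_universe(p, q)
    return sum(1 for e in p.universe if p.color_of(e) != q.color_of(e))


def similarity_graph(p: Partition, q: Partition) -> dict:
    """Weighted bipartite edges (i, j) -> |p_i intersect q_j| > 0."""
    _check_universe(p, q)
    edges = {}
    for i, pi in enumerate(p.parts):
        for j, qj in enumerate(q.parts):
            s = len(pi & qj)
            if s > 0:
                edges[(i, j)] = s
    return edges


def greedy_partdist(p: Partition, q: Partition) -> MatchingResult:
    """Heaviest-edge-first greedy matching between part sets.

    Edges sorted by descending weight with lexicographic (source, target)
    tie-break; leftover zero-degree parts are matched in ascending index
    order (their contribution is zero either way).  O(m log n).
    """
    edges = similarity_graph(p, q)
    order = sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))
    used_p, used_q = set(), set()
    matching, similarity = [], 0
    for (i, j), w in order:
        if i in used_p or j in used_q:
            continue
        matching.append((i, j))
        used_p.add(i)
        used_q.add(j)
        similarity += w
    free_p = [i for i in range(len(p)) if i not in used_p]
    free_q = [j for j in range(len(q)) if j not in used_q]
    for i, j in zip(free_p, free_q):
        matching.append((i, j))
    for i in free_p[len(free_q):]:
        matching.append((i, None))
    for j in free_q[len(free_p):]:
        matching.append((None, j))
    n = len(p.universe)
    return MatchingResult(
        matching=tuple(matching),
        similarity=similarity,
        distance=n - similarity,
        algorithm="greedy",
    )


def exact_partdist(p: Partition, q: Partition) -> MatchingResult:
    """Optimal partition distance via the assignment problem.

    Pads the smaller side with empty parts so the mapping is a bijection;
    empty matches contribute zero similarity.
    """
    _check_universe(p, q)
    size = max(len(p), len(q))
    w = np.zeros((size, size), dtype=int)
    for (i, j), s in similarity_graph(p, q).items():
        w[i, j] = s
    rows, cols = linear_sum_assignment(w, maximize=True)
    matching = tuple(
        (int(i) if i < len(p) else None, int(j) if j < len(q) else None)
        for i, j in zip(rows, cols)
    )
    similarity = int(w[rows, cols].sum())
    n = len(p.universe)
    return MatchingResult(
        matching=matching,
        similarity=similarity,
        distance=n - similarity,
        algorithm="exact",
    )


def normalized_distance(result: MatchingResult, n: int) -> float:
    """Partition distance scaled to [0, 1] by the element count."""
    return result.distance / n


def expected_random_similarity(params: RandomModelParams) -> float:
    """Expected identity similarity of the stay-or-uniform process.

    Each gene stays with probability alpha and otherwise re-draws its part
    uniformly among all k (its own included):
    E[s] = (k - 1) alpha n / k + n / k.
    """
    a, n, k = params.alpha, params.n, params.k
    return (k - 1) * a * n / k + n / k


def random_partition_pair(rng, n: int = 60, max_parts: int = 8):
    """Two independent uniform random colorings over the same n elements."""
    ka = int(rng.integers(2, max_parts + 1))
    kb = int(rng.integers(2, max_parts + 1))
    return (
        Partition.from_labels(rng.integers(0, ka, size=n)),
        Partition.from_labels(rng.integers(0, kb, size=n)),
    )


def correctly_clustered_pair(rng, n: int = 60, k: int = 4):
    """A source partition and a target where every source part keeps a
    strict majority of its members — the regime in which the greedy matcher
    is provably optimal."""
    source = rng.integers(0, k, size=n)
    source[:k] = np.arange(k)  # every part non-empty
    target = source.copy()
    for lab in range(k):
        members = np.flatnonzero(source == lab)
        n_move = int(rng.integers(0, (len(members) - 1) // 2 + 1))
        move = rng.choice(members, size=n_move, replace=False)
        target[move] = rng.integers(0, k, size=n_move)
    return Partition.from_labels(source), Partition.from_labels(target)


def random_recolor(labels, alpha: float, rng, k: int | None = None) -> np.ndarray:
    """One draw of the stay-or-uniform recoloring of a label vector."""
    labels = np.asarray(labels)
    if k is None:
        k = len(np.unique(labels))
    stay = rng.random(labels.size) < alpha
    fresh = rng.integers(0, k, size=labels.size)
    return np.where(stay, labels, fresh)
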