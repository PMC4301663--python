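"""k-means clustering of the embedding and gap-statistic model selection.

The number of pacemakers is unknown on real data, so the embedding is
clustered for a range of k and Tibshirani's gap statistic compares the
observed log within-cluster dispersion to that of B uniform reference
datasets drawn over the bounding box of the embedded points:

    Gap[k]      = mean_b log W*_kb - log W_k
    sigma[k]    = sd_b(log W*_kb) * sqrt(1 + 1/B)
    deltaGap[k] = Gap[k] - Gap[k+1] + sigma[k+1]

and the chosen k is the smallest with deltaGap[k] >= 0.  The dispersion
W_K sums, over clusters, the pairwise squared distances between members
normalized by 2 n_r (equivalently half the k-means inertia); a raw
unnormalized pairwise-distance variant is exposed via flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

__all__ = [
    "ClusteringResult",
    "GapTable",
    "kmeans_cluster",
    "dispersion",
    "gap_statistic",
]


@dataclass
class ClusteringResult:
    """Labels of the best k-means run plus its dispersion W_K."""

    labels: pd.Series
    k: int
    wcss: float
    seed: int
    restarts: int

    def write_tsv(self, path) -> None:
        self.labels.rename("cluster").to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GapTable:
    """Per-k gap-statistic table and the selected number of clusters.

    ``table`` has columns k, log_w, gap, sigma, delta_gap (delta_gap is NaN
    for the largest k, which has no successor); ``chosen_k`` is None when no
    k in the scanned range satisfies the rule.
    """

    table: pd.DataFrame
    chosen_k: int | None

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _coords(emb) -> np.ndarray:
    if hasattr(emb, "coords"):
        return emb.coords.to_numpy(dtype=float)
    if isinstance(emb, pd.DataFrame):
        return emb.to_numpy(dtype=float)
    return np.asarray(emb, dtype=float)


def _index(emb, n: int) -> pd.Index:
    if hasattr(emb, "coords"):
        return emb.coords.index
    if isinstance(emb, pd.DataFrame):
        return emb.index
    return pd.Index(range(n), name="gene_id")


def dispersion(emb, labels, squared: bool = True, normalize: bool = True) -> float:
    """Within-cluster dispersion W_K.

    Default (Tibshirani): W = sum_r D_r / (2 n_r) with D_r the sum of
    squared pairwise Euclidean distances over unordered member pairs of
    cluster r — identical to half the k-means inertia.  ``squared=False``
    uses raw distances; ``normalize=False`` drops the 1/(2 n_r) factor.
    """
    x = _coords(emb)
    labels = np.asarray(labels.values if isinstance(labels, pd.Series) else labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels must cover all embedded genes")
    total = 0.0
    for lab in np.unique(labels):
        members = x[labels == lab]
        nr = members.shape[0]
        if nr < 2:
            continue
        if squared and normalize:
            # sum_{i<j} ||x_i - x_j||^2 = n_r * sum_i ||x_i - centroid||^2
            centroid = members.mean(axis=0)
            d_r = nr * float(((members - centroid) ** 2).sum())
            total += d_r / (2.0 * nr)
        else:
            d = pdist(members)
            d_r = float((d**2).sum() if squared else d.sum())
            total += d_r / (2.0 * nr) if normalize else d_r
    return total


def kmeans_cluster(emb, k: int, restarts: int = 25, seed: int = 0) -> ClusteringResult:
    """Best-of-``restarts`` seeded Lloyd k-means (k-means++ initialisation).

    Deterministic given ``seed``; scikit-learn's implementation relocates
    empty clusters internally, so the returned solution always has exactly k
    non-empty parts for k <= n distinct points.
    """
    x = _coords(emb)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {x.shape[0]}")
    km = KMeans(
        n_clusters=k, n_init=restarts, random_state=int(seed) % (2**31)
    ).fit(x)
    labels = pd.Series(km.labels_.astype(int), index=_index(emb, x.shape[0]), name="cluster")
    return ClusteringResult(
        labels=labels,
        k=k,
        wcss=dispersion(x, km.labels_),
        seed=seed,
        restarts=restarts,
    )


def gap_statistic(
    emb,
    k_range=range(1, 11),
    B: int = 50,
    seed: int = 0,
    restarts: int = 10,
    squared: bool = True,
    normalize: bool = True,
) -> GapTable:
    """Gap-statistic scan over a contiguous k range.

    Reference datasets are uniform over the axis-aligned bounding box of the
    embedded points ("fully random uniform model").  The same B reference
    draws are reused across k.  Deterministic given ``seed``.
    """
    ks = list(k_range)
    if ks != list(range(ks[0], ks[0] + len(ks))) or ks[0] not in (1, 2):
        raise ValueError("k_range must be contiguous and start at 1 or 2")
    if B < 10:
        raise ValueError("need at least 10 reference datasets")
    x = _coords(emb)
    n, d = x.shape
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    km_seeds = rng.integers(0, 2**31 - 1, size=(len(ks), B + 1))
    lo, hi = x.min(axis=0), x.max(axis=0)
    refs = [rng.uniform(lo, hi, size=(n, d)) for _ in range(B)]

    def log_w(points, k, s) -> float:
        res = kmeans_cluster(points, k, restarts=restarts, seed=int(s))
        w = dispersion(points, res.labels.values, squared=squared, normalize=normalize)
        return float(np.log(max(w, 1e-300)))

    rows = []
    for ki, k in enumerate(ks):
        lw = log_w(x, k, km_seeds[ki, 0])
        lw_refs = np.array(
            [log_w(refs[b], k, km_seeds[ki, b + 1]) for b in range(B)]
        )
        gap = float(lw_refs.mean() - lw)
        sigma = float(lw_refs.std(ddof=0) * np.sqrt(1.0 + 1.0 / B))
        rows.append((k, lw, gap, sigma))

    table = pd.DataFrame(rows, columns=["k", "log_w", "gap", "sigma"])
    delta = [
        table.gap[i] - table.gap[i + 1] + table.sigma[i + 1]
        for i in range(len(ks) - 1)
    ] + [np.nan]
    table["delta_gap"] = delta

    chosen = None
    for i in range(len(ks) - 1):
        if table.delta_gap[i] >= 0:
            chosen = int(table.k[i])
            break
    return GapTable(table=table, chosen_k=chosen)
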