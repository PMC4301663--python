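"""Forward simulation of gene branch lengths under the multiple-pacemaker model.

The model: every gene ``g_i`` has a constant intrinsic substitution rate
``r_i``.  Each of ``k`` pacemakers sets a per-period pace ``beta_{k,j} ~
N(0, sigma_P^2)``, and each gene deviates from its pacemaker by an error
factor ``alpha_{i,j} ~ N(0, sigma_G^2)``.  The observed branch length of
gene ``i`` on period (tree edge) ``j`` of duration ``t_j`` is

    l_{i,j} = t_j * r_i * exp(alpha_{i,j}) * exp(beta_{PM(i),j})

Genes sharing a pacemaker therefore accelerate and decelerate in unison;
the partition of genes into pacemakers is the quantity the rest of the
package tries to recover.  The simulator also reproduces the low pairwise
tree agreement seen in real data by discarding each gene pair with a fixed
probability ("pair dropout").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "SimulatedDataset",
    "simulate_dataset",
    "drop_pairs",
    "all_gene_pairs",
    "rate_identity_check",
    "trees_from_dataset",
    "write_lengths_tsv",
    "read_lengths_tsv",
    "write_partition_tsv",
    "read_partition_tsv",
    "write_pairs_tsv",
    "read_pairs_tsv",
]

#: distribution specs accepted by :func:`sample_law`:
#: ("constant", v) | ("uniform", lo, hi) | ("loguniform", lo, hi)
#: | ("lognormal", mu, sigma)
Law = tuple


def sample_law(law: Law, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` strictly positive samples from a distribution spec."""
    name, *args = law
    if name == "constant":
        (v,) = args
        out = np.full(size, float(v))
    elif name == "uniform":
        lo, hi = args
        out = rng.uniform(lo, hi, size)
    elif name == "loguniform":
        lo, hi = args
        out = np.exp(rng.uniform(np.log(lo), np.log(hi), size))
    elif name == "lognormal":
        mu, sigma = args
        out = rng.lognormal(mu, sigma, size)
    else:
        raise ValueError(f"unknown distribution law {name!r}")
    if np.any(out <= 0):
        raise ValueError(f"law {law!r} produced non-positive samples")
    return out


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the multiple-pacemaker generative model.

    ``n`` genes split into ``k`` equal blocks of pacemakers, ``tau`` time
    periods (tree edges), gene-error and pace standard deviations on the log
    scale, the laws for intrinsic rates and period durations, and the
    probability that an (unordered) gene pair is discarded before the
    correlation analysis.
    """

    n: int = 100
    k: int = 2
    tau: int = 25
    sigma_g: float = 0.3
    sigma_p: float = 0.4
    rate_law: Law = ("loguniform", 0.5, 2.0)
    period_law: Law = ("uniform", 0.1, 1.0)
    pair_drop_prob: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n >= self.k >= 1):
            raise ValueError(f"need n >= k >= 1, got n={self.n}, k={self.k}")
        if self.tau < 2:
            raise ValueError(f"need tau >= 2, got {self.tau}")
        if self.sigma_g < 0 or self.sigma_p < 0:
            raise ValueError("sigma_g and sigma_p must be non-negative")
        if not (0 <= self.pair_drop_prob < 1):
            raise ValueError("pair_drop_prob must be in [0, 1)")

    def with_ratio(self, ratio: float) -> "ModelParams":
        """Return a copy with sigma_g = ratio * sigma_p (the swept quantity)."""
        return replace(self, sigma_g=ratio * self.sigma_p)


@dataclass
class SimulatedDataset:
    """A simulated branch-length table plus the hidden model state.

    ``lengths`` is the genes x periods table the inference sees; everything
    else (true partition, rates, paces, errors, periods) is ground truth kept
    for scoring.  ``retained_pairs`` is the post-dropout unordered pair set.
    """

    params: ModelParams
    lengths: pd.DataFrame
    true_partition: pd.Series
    rates: pd.Series
    paces: np.ndarray
    errors: np.ndarray
    periods: np.ndarray
    retained_pairs: list = field(default_factory=list)

    @property
    def gene_ids(self) -> list:
        return list(self.lengths.index)


def _gene_ids(n: int) -> list:
    width = max(3, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def block_partition(n: int, k: int) -> np.ndarray:
    """Assign genes to pacemakers in contiguous equal blocks.

    When k does not divide n the remainder genes go one each to the
    lowest-indexed parts, so sizes are ``ceil(n/k)`` for the first ``n % k``
    parts and ``floor(n/k)`` after.
    """
    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    return np.repeat(np.arange(k), sizes)


def all_gene_pairs(genes: Sequence | int) -> list:
    """All C(n, 2) unordered gene pairs, in lexicographic order."""
    if isinstance(genes, int):
        genes = _gene_ids(genes)
    return list(itertools.combinations(genes, 2))


def drop_pairs(pairs: Iterable, p: float, seed=None, rng=None) -> list:
    """Retain each pair independently with probability 1 - p.

    Deterministic given ``seed`` (or an explicit ``rng``); order preserved.
    """
    if not (0 <= p < 1):
        raise ValueError("drop probability must be in [0, 1)")
    pairs = list(pairs)
    if rng is None:
        rng = np.random.default_rng(seed)
    keep = rng.random(len(pairs)) >= p
    return [pair for pair, k in zip(pairs, keep) if k]


def simulate_dataset(params: ModelParams) -> SimulatedDataset:
    """Generate one dataset under the multiple-pacemaker model.

    The multiplicative identity ``l = t * r * exp(alpha) * exp(beta)`` holds
    exactly (bit-wise) for every cell; the returned ground-truth arrays are
    the very factors used.  Independent RNG sub-streams are split per purpose
    (rates / periods / paces / errors / dropout) so that changing one law
    leaves the other draws untouched.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_rates, rng_periods, rng_paces, rng_errors, rng_drop = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    genes = _gene_ids(params.n)
    labels = block_partition(params.n, params.k)
    rates = sample_law(params.rate_law, params.n, rng_rates)
    periods = sample_law(params.period_law, params.tau, rng_periods)
    paces = rng_paces.normal(0.0, params.sigma_p, size=(params.k, params.tau))
    errors = rng_errors.normal(0.0, params.sigma_g, size=(params.n, params.tau))

    lengths = (
        periods[None, :]
        * rates[:, None]
        * np.exp(errors)
        * np.exp(paces[labels, :])
    )
    table = pd.DataFrame(
        lengths,
        index=pd.Index(genes, name="gene_id"),
        columns=[f"period_{j + 1:02d}" for j in range(params.tau)],
    )
    retained = drop_pairs(
        all_gene_pairs(genes), params.pair_drop_prob, rng=rng_drop
    )
    return SimulatedDataset(
        params=params,
        lengths=table,
        true_partition=pd.Series(labels, index=table.index, name="pm_id"),
        rates=pd.Series(rates, index=table.index, name="rate"),
        paces=paces,
        errors=errors,
        periods=periods,
        retained_pairs=retained,
    )


def rate_identity_check(
    ds: SimulatedDataset, gene_a, gene_b, rtol: float = 1e-9
) -> bool:
    """True iff l_a / l_b is constant over periods and equals r_a / r_b.

    Holds exactly when both genes share a pacemaker and have zero error
    factors (sigma_g = 0); fails with probability one otherwise.
    """
    ratio = ds.lengths.loc[gene_a].to_numpy() / ds.lengths.loc[gene_b].to_numpy()
    expected = ds.rates[gene_a] / ds.rates[gene_b]
    return bool(np.allclose(ratio, expected, rtol=rtol))


# ---------------------------------------------------------------------------
# Synthetic gene trees carrying simulated branch lengths
# ---------------------------------------------------------------------------

def trees_from_dataset(ds: SimulatedDataset):
    """Render each simulated gene as a Newick caterpillar tree.

    All genes share one caterpillar topology over m = (tau + 3) / 2 taxa
    (tau must be odd), whose 2m - 3 unrooted edges carry the gene's tau
    branch lengths in a fixed edge order.  Because the topology is shared,
    the maximum agreement subtree of any pair is the full leaf set and the
    aligned edge-length vectors reproduce the table rows exactly — tree mode
    and table mode then see identical data.
    """
    from .trees import GeneTree, TreeNode

    tau = ds.params.tau
    if tau < 3 or tau % 2 == 0:
        raise ValueError(
            f"caterpillar rendering needs an odd tau >= 3, got {tau}"
        )
    m = (tau + 3) // 2
    taxa = [f"t{i + 1:02d}" for i in range(m)]

    trees = []
    for gene in ds.gene_ids:
        ell = ds.lengths.loc[gene].to_numpy()
        # pendant edges: taxa 0..m-1 get periods 0..m-1
        # internal edges above clades {t1..tj}, j=2..m-2: periods m..tau-1
        node = TreeNode(label=taxa[0], length=float(ell[0]), children=[])
        sib = TreeNode(label=taxa[1], length=float(ell[1]), children=[])
        node = TreeNode(label=None, length=0.0, children=[node, sib])
        for j in range(2, m - 1):
            node.length = float(ell[m + j - 2])
            leaf = TreeNode(label=taxa[j], length=float(ell[j]), children=[])
            node = TreeNode(label=None, length=0.0, children=[node, leaf])
        # root pair: the {t1..t_{m-1}} edge and the last pendant form one
        # unrooted split; put the pendant's length on the leaf, zero opposite.
        last = TreeNode(
            label=taxa[m - 1], length=float(ell[m - 1]), children=[]
        )
        root = TreeNode(label=None, length=0.0, children=[node, last])
        trees.append(GeneTree(id=gene, root=root))
    return trees


# ---------------------------------------------------------------------------
# TSV round-trips
# ---------------------------------------------------------------------------

def write_lengths_tsv(lengths: pd.DataFrame, path) -> None:
    lengths.to_csv(path, sep="\t", index_label="gene_id")


def read_lengths_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_partition_tsv(partition: pd.Series, path) -> None:
    partition.rename("pm_id").to_csv(path, sep="\t", index_label="gene_id")


def read_partition_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.iloc[:, 0]


def write_pairs_tsv(pairs: Iterable, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))
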