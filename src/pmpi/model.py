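"""Model/Results interface for pacemaker partition identification.

:class:`PacemakerPartitionModel` holds the data (a branch-length table with
a retained-pair set, or aligned MAST edge-length vectors from gene trees)
and the analysis options; :meth:`~PacemakerPartitionModel.fit` runs the
full procedure —

    pairwise slope-one Deming fits
    -> correlation graph thresholded at delta_r
    -> giant connected component
    -> min-hop-min-weight completion
    -> classical MDS initialisation
    -> Kruskal non-metric MDS on the original partial distances (1 - r)
    -> k-means at a given k, or a gap-statistic scan over a k range

— and returns a :class:`PacemakerPartitionResults` carrying every
intermediate artifact, the cluster labels, and scoring helpers against a
known true partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import corrgraph as _corrgraph
from . import embed as _embed
from . import partdist as _partdist
from . import regression as _regression
from . import simulate as _simulate
from . import trees as _trees

__all__ = ["PacemakerPartitionModel", "PacemakerPartitionResults"]


class PacemakerPartitionModel:
    """Pacemaker partition identification from gene branch lengths.

    Parameters
    ----------
    lengths
        genes x periods branch-length table (NaN for unobserved cells), used
        together with ``pairs`` (default: all unordered pairs).
    pair_vectors
        alternative input: mapping (gene_a, gene_b) -> aligned positive
        length vectors, e.g. MAST edge lengths; exactly one of ``lengths``
        and ``pair_vectors`` must be given.
    delta_r
        correlation threshold for graph admission (default 0: dropout alone
        sparsifies simulated data; raise it for tree collections).
    min_periods
        minimum shared observations for a pair fit.
    mhmw_objective
        'product' (default) or 'sum' path objective for graph completion.
    """

    def __init__(
        self,
        lengths: pd.DataFrame | None = None,
        pairs=None,
        *,
        pair_vectors=None,
        delta_r: float = 0.0,
        min_periods: int = 3,
        mhmw_objective: str = "product",
        true_partition: pd.Series | None = None,
    ):
        if (lengths is None) == (pair_vectors is None):
            raise ValueError("provide exactly one of lengths or pair_vectors")
        self.lengths = lengths
        self.pairs = pairs
        self.pair_vectors = pair_vectors
        self.delta_r = delta_r
        self.min_periods = min_periods
        self.mhmw_objective = mhmw_objective
        self.true_partition = true_partition

    @classmethod
    def from_simulation(
        cls, params_or_dataset, *, delta_r: float = 0.0, **kwargs
    ) -> "PacemakerPartitionModel":
        """Build from ModelParams (simulating now) or a SimulatedDataset."""
        ds = params_or_dataset
        if isinstance(ds, _simulate.ModelParams):
            ds = _simulate.simulate_dataset(ds)
        model = cls(
            lengths=ds.lengths,
            pairs=ds.retained_pairs,
            delta_r=delta_r,
            true_partition=ds.true_partition,
            **kwargs,
        )
        model.dataset = ds
        return model

    @classmethod
    def from_trees(
        cls,
        trees,
        *,
        min_leaves: int = 10,
        outgroup: str | None = None,
        delta_r: float = 0.0,
        **kwargs,
    ) -> "PacemakerPartitionModel":
        """Build from gene trees: all-pairs MAST, leaf filter, aligned lengths."""
        if isinstance(trees, (str, Path)):
            trees = _trees.read_newick_dir(trees)
        results = {}
        for i, t1 in enumerate(trees):
            for t2 in trees[i + 1:]:
                results[(t1.id, t2.id)] = _trees.mast_pair(t1, t2, outgroup=outgroup)
        vectors = _trees.aligned_vectors(results, min_leaves=min_leaves)
        model = cls(pair_vectors=vectors, delta_r=delta_r, **kwargs)
        model.mast_results = results
        return model

    def _fits(self, skipped: list):
        if self.pair_vectors is not None:
            return _regression.fits_from_vectors(
                self.pair_vectors, min_periods=self.min_periods, skipped=skipped
            )
        return _regression.all_pair_fits(
            self.lengths,
            pairs=self.pairs,
            min_periods=self.min_periods,
            skipped=skipped,
        )

    def fit(
        self,
        k: int | None = None,
        k_range=None,
        *,
        n_dims: int | None = None,
        restarts: int = 25,
        gap_B: int = 50,
        gap_restarts: int = 10,
        nmds_max_iter: int = 300,
        nmds_tol: float = 1e-4,
        seed: int = 0,
    ) -> "PacemakerPartitionResults":
        """Run the full procedure and return a results object.

        Give ``k`` when the number of pacemakers is known (the simulation
        protocol); otherwise a gap-statistic scan over ``k_range`` (default
        1..10) selects it.  ``n_dims`` limits the embedding dimension
        (default: the data-determined maximum of classical MDS).
        Deterministic given ``seed``.
        """
        if k is None and k_range is None:
            k_range = range(1, 11)
        ss = np.random.SeedSequence(seed)
        seed_nmds, seed_km, seed_gap = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        )

        skipped: list = []
        fits = self._fits(skipped)
        if not fits:
            raise ValueError("no pair could be fitted")
        graph = _corrgraph.build_graph(fits, delta_r=self.delta_r)
        giant = _corrgraph.giant_component(graph)
        dropped = sorted(set(graph.nodes) - set(giant.nodes), key=str)
        completed = _corrgraph.mhmw_complete(giant, objective=self.mhmw_objective)

        init = _embed.classical_mds(completed, max_dim=n_dims)
        partial = self._partial_distances(fits, list(completed.genes))
        embedding = _embed.nonmetric_mds(
            partial, init, max_iter=nmds_max_iter, tol=nmds_tol, seed=seed_nmds
        )

        gap = None
        if k is None:
            n_giant = len(completed.genes)
            ks = [kk for kk in k_range if kk <= n_giant]
            gap = _cluster.gap_statistic(
                embedding, ks, B=gap_B, seed=seed_gap, restarts=gap_restarts
            )
            k_used = gap.chosen_k if gap.chosen_k is not None else ks[0]
        else:
            k_used = k
        clustering = _cluster.kmeans_cluster(
            embedding, k_used, restarts=restarts, seed=seed_km
        )

        return PacemakerPartitionResults(
            model=self,
            fits=fits,
            skipped=skipped,
            graph=graph,
            giant=giant,
            dropped_genes=dropped,
            completed=completed,
            init_embedding=init,
            embedding=embedding,
            clustering=clustering,
            gap=gap,
            seed=seed,
        )

    @staticmethod
    def _partial_distances(fits, genes) -> pd.DataFrame:
        """Square 1 - r matrix over the giant component, NaN where no fit."""
        index = pd.Index(genes, name="gene_id")
        arr = np.full((len(genes), len(genes)), np.nan)
        pos = {g: i for i, g in enumerate(genes)}
        for f in fits:
            if f.gene_a in pos and f.gene_b in pos:
                d = 1.0 - f.pearson_r
                arr[pos[f.gene_a], pos[f.gene_b]] = d
                arr[pos[f.gene_b], pos[f.gene_a]] = d
        np.fill_diagonal(arr, 0.0)
        return pd.DataFrame(arr, index=index, columns=index)


@dataclass
class PacemakerPartitionResults:
    """Artifacts and estimates of one pacemaker-partition fit."""

    model: PacemakerPartitionModel
    fits: list
    skipped: list
    graph: object
    giant: object
    dropped_genes: list
    completed: _corrgraph.CompletedDistances
    init_embedding: _embed.Embedding
    embedding: _embed.Embedding
    clustering: _cluster.ClusteringResult
    gap: _cluster.GapTable | None
    seed: int
    extra: dict = field(default_factory=dict)

    @property
    def labels(self) -> pd.Series:
        return self.clustering.labels

    @property
    def k(self) -> int:
        return self.clustering.k

    @property
    def chosen_k(self) -> int | None:
        return self.gap.chosen_k if self.gap is not None else self.clustering.k

    def partition(self) -> _partdist.Partition:
        return _partdist.Partition(self.labels)

    def partition_distance(self, truth=None) -> dict:
        """Score the reconstruction against a true partition.

        Restricts the truth to the genes actually clustered (the giant
        component) and reports greedy and exact matching distances, both
        normalized by the clustered gene count.
        """
        if truth is None:
            truth = self.model.true_partition
        if truth is None:
            raise ValueError("no true partition available")
        if isinstance(truth, _partdist.Partition):
            truth = pd.Series(
                {e: truth.color_of(e) for e in truth.universe}
            )
        truth = truth.loc[self.labels.index]
        p_true = _partdist.Partition(truth)
        p_est = _partdist.Partition(self.labels)
        greedy = _partdist.greedy_partdist(p_true, p_est)
        exact = _partdist.exact_partdist(p_true, p_est)
        n = len(self.labels)
        return {
            "n": n,
            "greedy_distance": greedy.distance,
            "exact_distance": exact.distance,
            "greedy_normalized": greedy.distance / n,
            "exact_normalized": exact.distance / n,
        }

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = [
            "Pacemaker Partition Identification",
            "=" * 50,
            f"{'genes (graph / giant)':35s}{self.graph.number_of_nodes()} / "
            f"{self.giant.number_of_nodes()}",
            f"{'pair fits (skipped)':35s}{len(self.fits)} ({len(self.skipped)})",
            f"{'edges >= delta_r=' + format(self.model.delta_r, 'g'):35s}"
            f"{self.giant.number_of_edges()}",
            f"{'embedding dims':35s}{self.embedding.dim}",
            f"{'final stress-1':35s}{self.embedding.stress:.6f}",
            f"{'k (clusters)':35s}{self.k}",
            f"{'W_K (within dispersion)':35s}{self.clustering.wcss:.4f}",
        ]
        if self.gap is not None:
            lines.append(f"{'gap-statistic chosen k':35s}{self.gap.chosen_k}")
            lines.append("-" * 50)
            lines.append(self.gap.table.to_string(index=False, float_format="%.4f"))
        sizes = self.labels.value_counts().sort_index()
        lines.append("-" * 50)
        lines.append(
            "cluster sizes: "
            + ", ".join(f"{c}: {s}" for c, s in sizes.items())
        )
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        out = {
            "n_genes": int(self.graph.number_of_nodes()),
            "n_giant": int(self.giant.number_of_nodes()),
            "n_fits": int(len(self.fits)),
            "n_skipped": int(len(self.skipped)),
            "n_edges": int(self.giant.number_of_edges()),
            "delta_r": float(self.model.delta_r),
            "dims": int(self.embedding.dim),
            "stress": float(self.embedding.stress),
            "k": int(self.k),
            "wcss": float(self.clustering.wcss),
            "chosen_k": None if self.chosen_k is None else int(self.chosen_k),
            "seed": int(self.seed),
            "labels": {str(g): int(c) for g, c in self.labels.items()},
        }
        if self.gap is not None:
            out["gap_table"] = {
                "k": [int(v) for v in self.gap.table.k],
                "log_w": [round(float(v), 10) for v in self.gap.table.log_w],
                "gap": [round(float(v), 10) for v in self.gap.table.gap],
                "sigma": [round(float(v), 10) for v in self.gap.table.sigma],
            }
        if self.model.true_partition is not None:
            out["partition_distance"] = self.partition_distance()
        return out

    def save(self, outdir) -> None:
        """Write every artifact as TSV plus a JSON run summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _regression.write_fits_tsv(self.fits, outdir / "pairs.tsv")
        _corrgraph.write_graph_tsv(self.giant, outdir / "graph.tsv")
        self.completed.write_tsv(outdir / "completed.tsv")
        self.embedding.write_tsv(outdir / "embedding.tsv")
        self.clustering.write_tsv(outdir / "labels.tsv")
        if self.gap is not None:
            self.gap.write_tsv(outdir / "gap.tsv")
        (outdir / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, sort_keys=True) + "\n"
        )
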