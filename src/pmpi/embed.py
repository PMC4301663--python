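"""Euclidean embedding of the gene correlation graph.

Two stages, mirroring the cmdscale / isoMDS workflow: classical
(Torgerson/Mardia) multidimensional scaling of the MHMW-completed matrix
provides the initial configuration, then Kruskal's iterative non-metric MDS
refines it against the *original partial* dissimilarities (only pairs with
an actual fit contribute to the stress).  Non-metric MDS preserves the rank
order of the observed dissimilarities rather than their values: each
iteration fits disparities by isotonic regression of the configuration
distances on the dissimilarities and then takes a descent step on Kruskal's
stress-1,

    S = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

with a backtracking line search so the stress sequence never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = ["Embedding", "classical_mds", "nonmetric_mds", "stress1"]


@dataclass
class Embedding:
    """genes x d coordinates plus the Kruskal stress-1 of the fit.

    ``stress`` is None for a classical-MDS embedding (no disparities were
    fitted).  ``history`` records the stress after every accepted iteration
    of non-metric MDS, ``converged`` whether the relative-change tolerance
    was met before ``max_iter``.
    """

    coords: pd.DataFrame
    stress: float | None = None
    converged: bool = True
    n_iter: int = 0
    history: list = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def genes(self) -> list:
        return list(self.coords.index)

    def values(self) -> np.ndarray:
        return self.coords.to_numpy(dtype=float)

    def write_tsv(self, path) -> None:
        self.coords.to_csv(path, sep="\t", index_label="gene_id")

    @staticmethod
    def read_tsv(path) -> "Embedding":
        return Embedding(coords=pd.read_csv(path, sep="\t", index_col="gene_id"))


def _as_matrix(dist) -> tuple[np.ndarray, pd.Index]:
    if hasattr(dist, "dist"):  # CompletedDistances
        dist = dist.dist
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), dist.index
    arr = np.asarray(dist, dtype=float)
    return arr, pd.Index([f"p{i}" for i in range(arr.shape[0])], name="gene_id")


def classical_mds(dist, max_dim: int | None = None, eig_tol: float = 1e-9) -> Embedding:
    """Classical (Torgerson) MDS of a full symmetric dissimilarity matrix.

    Double-centers B = -1/2 J D^2 J, eigendecomposes, and keeps the
    coordinates of positive eigenvalues up to ``max_dim``; exactly Euclidean
    inputs are reproduced to numerical precision in their intrinsic
    dimension.  ``max_dim=None`` keeps every positive-eigenvalue axis — the
    maximal dimension determined by the data.
    """
    d, index = _as_matrix(dist)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(evals[0], 0.0)
    pos = evals > eig_tol * max(scale, 1.0)
    n_pos = int(pos.sum())
    dim = n_pos if max_dim is None else min(max_dim, n_pos)
    dim = max(dim, 1)
    coords = evecs[:, :dim] * np.sqrt(np.maximum(evals[:dim], 0.0))
    cols = [f"dim_{i + 1}" for i in range(dim)]
    return Embedding(coords=pd.DataFrame(coords, index=index, columns=cols))


def _observed_pairs(partial, index: pd.Index):
    """Extract (i, j, delta) arrays for the finite upper-triangle cells."""
    if isinstance(partial, pd.DataFrame):
        partial = partial.reindex(index=index, columns=index)
        arr = partial.to_numpy(dtype=float)
    else:
        arr = np.asarray(partial, dtype=float)
    iu, ju = np.triu_indices(arr.shape[0], k=1)
    mask = np.isfinite(arr[iu, ju])
    return iu[mask], ju[mask], arr[iu, ju][mask]


def stress1(x: np.ndarray, iu, ju, dhat) -> float:
    d = np.linalg.norm(x[iu] - x[ju], axis=1)
    den = float(d @ d)
    if den == 0:
        return 0.0
    resid = d - dhat
    return float(np.sqrt((resid @ resid) / den))


def nonmetric_mds(
    partial,
    init: Embedding,
    max_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
) -> Embedding:
    """Kruskal's iterative non-metric MDS over the observed pairs only.

    ``partial`` is a square (DataFrame) dissimilarity matrix with NaN in
    unobserved cells; ``init`` supplies the starting configuration (and the
    dimensionality).  Stops when the relative stress change drops below
    ``tol`` or after ``max_iter`` accepted steps; the returned stress history
    is non-increasing by construction.  Non-convergence yields
    ``converged=False`` on the result, not an error.
    """
    index = init.coords.index
    iu, ju, delta = _observed_pairs(partial, index)
    if iu.size == 0:
        raise ValueError("no observed dissimilarities to fit")
    x = init.values().copy()
    rng = np.random.default_rng(seed)

    def config_dist(xx):
        return np.linalg.norm(xx[iu] - xx[ju], axis=1)

    # isotonic step needs distinct configuration points on observed pairs
    d = config_dist(x)
    if np.any(d == 0):
        x = x + 1e-8 * rng.standard_normal(x.shape)
        d = config_dist(x)

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    def disparities(dd):
        return iso.fit_transform(delta, dd)

    dhat = disparities(d)
    stress = stress1(x, iu, ju, dhat)
    history = [stress]
    step = 0.2
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        if stress <= 1e-12:
            converged = True
            break
        d = config_dist(x)
        nz = np.maximum(d, 1e-12)
        num = float((d - dhat) @ (d - dhat))
        den = float(d @ d)
        # dS/dd_p for S = sqrt(num/den), dhat held fixed
        ds_dd = ((d - dhat) / den - num * d / den**2) / max(stress, 1e-12)
        diff = x[iu] - x[ju]
        g = (ds_dd / nz)[:, None] * diff
        grad = np.zeros_like(x)
        np.add.at(grad, iu, g)
        np.add.at(grad, ju, -g)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            converged = True
            break
        scale = np.linalg.norm(x - x.mean(axis=0)) / np.sqrt(x.shape[0])
        base = step * max(scale, 1e-8) / gnorm * np.sqrt(x.shape[0])

        accepted = False
        trial = base
        for _ in range(20):
            x_new = x - trial * grad
            d_new = config_dist(x_new)
            if np.any(d_new == 0):
                trial *= 0.5
                continue
            dhat_new = disparities(d_new)
            s_new = stress1(x_new, iu, ju, dhat_new)
            if s_new < stress:
                accepted = True
                break
            trial *= 0.5
        if not accepted:
            converged = True
            break
        rel = (stress - s_new) / max(stress, 1e-12)
        x, dhat, stress = x_new, dhat_new, s_new
        history.append(stress)
        step = min(step * 1.2, 1.0) if trial == base else max(step * 0.7, 1e-3)
        if rel < tol:
            converged = True
            break

    coords = pd.DataFrame(
        x, index=index, columns=[f"dim_{i + 1}" for i in range(x.shape[1])]
    )
    return Embedding(
        coords=coords,
        stress=stress,
        converged=converged,
        n_iter=it,
        history=history,
    )
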