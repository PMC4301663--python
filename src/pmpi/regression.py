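"""Pairwise rate-ratio and correlation inference for gene branch lengths.

For two genes observed over the same periods, the points
(log l_a, log l_b) scatter around a trend line of slope one (both genes see
the same t_j, and log is what turns the multiplicative error factors into
additive homoscedastic noise).  Because both coordinates carry the same
error variance, the fit is a Deming (errors-in-both-variables) regression
with the slope fixed at 1: the only free parameter is the intercept

    b = mean(log l_b) - mean(log l_a),

which is simultaneously the maximum-likelihood offset and the minimizer of
the orthogonal sum of squares at slope one.  exp(b) estimates the rate
ratio r_b / r_a.  The level of scatter about the line is summarized by the
sample Pearson correlation of the log lengths, which downstream modules
turn into the distance 1 - r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PairFit",
    "DegeneratePairError",
    "log_transform",
    "pearson",
    "fit_pair",
    "all_pair_fits",
    "fits_from_vectors",
    "fits_to_frame",
    "write_fits_tsv",
    "read_fits_tsv",
]


class DegeneratePairError(ValueError):
    """Raised when a correlation is undefined (a constant log-length vector)."""


@dataclass(frozen=True)
class PairFit:
    """Slope-one Deming fit for one gene pair.

    ``intercept`` is the log-scale offset of gene_b relative to gene_a,
    ``rho = exp(intercept)`` the rate ratio r_b / r_a, ``pearson_r`` the
    sample correlation of the log lengths and ``m`` the number of shared
    periods used.
    """

    gene_a: str
    gene_b: str
    intercept: float
    rho: float
    pearson_r: float
    m: int

    def swapped(self) -> "PairFit":
        return PairFit(
            gene_a=self.gene_b,
            gene_b=self.gene_a,
            intercept=-self.intercept,
            rho=1.0 / self.rho,
            pearson_r=self.pearson_r,
            m=self.m,
        )


def log_transform(lengths, labels: Sequence | None = None) -> np.ndarray:
    """Natural log of strictly positive branch lengths.

    ``labels`` (e.g. ``(gene, periods)``) is only used to name the offending
    entry in the error message.
    """
    arr = np.asarray(lengths, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        bad = np.flatnonzero(~(np.isfinite(arr) & (arr > 0)))
        where = (
            f"{labels}" if labels is not None else f"positions {bad.tolist()}"
        )
        raise ValueError(
            f"branch lengths must be strictly positive; offending entries at "
            f"{where}: {arr.ravel()[bad][:5].tolist()}"
        )
    return np.log(arr)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise DegeneratePairError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise DegeneratePairError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def fit_pair(x_log, y_log, gene_a: str = "x", gene_b: str = "y") -> PairFit:
    """Slope-one Deming fit of y_log = x_log + b.

    Antisymmetric in the pair: swapping the arguments negates the intercept
    and leaves pearson_r unchanged.  Raises :class:`DegeneratePairError` when
    either vector is constant (correlation undefined).
    """
    x = np.asarray(x_log, dtype=float)
    y = np.asarray(y_log, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with m >= 2")
    r = pearson(x, y)
    b = float(y.mean() - x.mean())
    return PairFit(
        gene_a=gene_a,
        gene_b=gene_b,
        intercept=b,
        rho=float(np.exp(b)),
        pearson_r=r,
        m=int(x.size),
    )


def all_pair_fits(
    lengths: pd.DataFrame,
    pairs: Iterable | None = None,
    min_periods: int = 3,
    skipped: list | None = None,
) -> list:
    """Fit every retained gene pair from a branch-length table.

    NaN cells mark unobserved lengths; each pair uses only its jointly
    observed periods and is skipped (with a logged reason, and appended to
    ``skipped`` if given) when fewer than ``min_periods`` remain or when the
    correlation is degenerate.
    """
    if pairs is None:
        from .simulate import all_gene_pairs

        pairs = all_gene_pairs(list(lengths.index))
    values = lengths.to_numpy(dtype=float)
    if np.any(np.nan_to_num(values, nan=1.0) <= 0):
        bad = lengths.stack()[lengths.stack() <= 0]
        raise ValueError(
            f"non-positive branch lengths in table: {bad.head().to_dict()}"
        )
    log_values = np.log(values)
    row = {g: i for i, g in enumerate(lengths.index)}
    observed = np.isfinite(log_values)

    fits = []
    for a, b in pairs:
        ia, ib = row[a], row[b]
        mask = observed[ia] & observed[ib]
        m = int(mask.sum())
        if m < max(min_periods, 2):
            _skip(skipped, (a, b), f"only {m} shared periods")
            continue
        try:
            fits.append(
                fit_pair(log_values[ia, mask], log_values[ib, mask], a, b)
            )
        except DegeneratePairError as exc:
            _skip(skipped, (a, b), str(exc))
    return fits


def fits_from_vectors(
    pair_vectors: Mapping, min_periods: int = 3, skipped: list | None = None
) -> list:
    """Fit pairs given raw (not yet logged) aligned length vectors.

    ``pair_vectors`` maps ``(gene_a, gene_b)`` to a pair of equal-length
    positive vectors, e.g. aligned MAST edge lengths from tree mode.
    """
    fits = []
    for (a, b), (xa, xb) in pair_vectors.items():
        xa = np.asarray(xa, dtype=float)
        xb = np.asarray(xb, dtype=float)
        if xa.size != xb.size:
            raise ValueError(f"pair ({a}, {b}): unequal vector lengths")
        if xa.size < max(min_periods, 2):
            _skip(skipped, (a, b), f"only {xa.size} shared edges")
            continue
        try:
            fits.append(
                fit_pair(log_transform(xa, (a,)), log_transform(xb, (b,)), a, b)
            )
        except DegeneratePairError as exc:
            _skip(skipped, (a, b), str(exc))
    return fits


def _skip(skipped, pair, reason: str) -> None:
    logger.info("skipping pair %s: %s", pair, reason)
    if skipped is not None:
        skipped.append((pair, reason))


def fits_to_frame(fits: Iterable[PairFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (f.gene_a, f.gene_b, f.m, f.intercept, f.rho, f.pearson_r)
            for f in fits
        ],
        columns=["gene_a", "gene_b", "m", "intercept", "rho", "pearson_r"],
    )


def write_fits_tsv(fits: Iterable[PairFit], path) -> None:
    fits_to_frame(fits).to_csv(path, sep="\t", index=False)


def read_fits_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        PairFit(
            gene_a=r.gene_a,
            gene_b=r.gene_b,
            intercept=float(r.intercept),
            rho=float(r.rho),
            pearson_r=float(r.pearson_r),
            m=int(r.m),
        )
        for r in df.itertuples(index=False)
    ]
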