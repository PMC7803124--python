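"""Pairwise community dissimilarities (Bray-Curtis, Jaccard, Yue-Clayton).

Abundance-based metrics are computed on per-sample relative abundances by
default: the tables entering the pipeline are rarefied to a common depth, and
working on proportions removes any residual library-size artifact. A
raw-counts mode exists for sensitivity checks. The Yue-Clayton measure is
reported as a distance, 1 - theta_YC, following mothur.
"""

from __future__ import annotations

import numpy as np

from .community_data import CommunityTable, DistanceMatrix, TaxonomyMap, aggregate_to_rank

METRICS = ("bray_curtis", "jaccard", "theta_yc")


def _pair(x, y, proportions: bool) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("zero-total sample in dissimilarity computation")
    if proportions:
        x = x / x.sum()
        y = y / y.sum()
    return x, y


def bray_curtis(x, y, proportions: bool = True) -> float:
    """Bray-Curtis dissimilarity: sum|x_k - y_k| / sum(x_k + y_k).

    With ``proportions=True`` (default) both vectors are first normalised to
    relative abundances, so the denominator is 2.
    """
    x, y = _pair(x, y, proportions)
    return float(np.abs(x - y).sum() / (x + y).sum())


def jaccard(x, y, proportions: bool = True) -> float:
    """Jaccard dissimilarity on presence/absence: 1 - |A & B| / |A | B|."""
    x, y = _pair(x, y, False)
    a = x > 0
    b = y > 0
    union = (a | b).sum()
    return float(1.0 - (a & b).sum() / union)


def theta_yc(x, y, proportions: bool = True) -> float:
    """Yue-Clayton distance 1 - sum(a_i b_i) / (sum(a_i - b_i)^2 + sum(a_i b_i)).

    Computed on proportions a, b; equals 0 for identical compositions and 1
    for disjoint supports.
    """
    a, b = _pair(x, y, True)
    cross = (a * b).sum()
    return float(1.0 - cross / (((a - b) ** 2).sum() + cross))


_SCALAR = {"bray_curtis": bray_curtis, "jaccard": jaccard, "theta_yc": theta_yc}


def pairwise_distances(table: CommunityTable, metric: str = "bray_curtis",
                       tax: TaxonomyMap | None = None, rank: str | None = None,
                       proportions: bool = True) -> DistanceMatrix:
    """Symmetric distance matrix over all samples of a table.

    If ``rank`` is given, counts are first aggregated to that taxonomic rank
    (``tax`` required). Vectorised; equivalent to applying the scalar metric
    to every pair.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if rank is not None:
        if tax is None:
            raise ValueError("rank aggregation requires a taxonomy")
        table = aggregate_to_rank(table, tax, rank)
    counts = table.counts.astype(float)
    if metric == "jaccard":
        b = (counts > 0).astype(float)
        inter = b @ b.T
        sizes = b.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore"):
            d = 1.0 - inter / union
    else:
        p = counts / counts.sum(axis=1, keepdims=True) if proportions else counts
        if metric == "bray_curtis":
            sums = p.sum(axis=1)
            manh = np.abs(p[:, None, :] - p[None, :, :]).sum(axis=2)
            d = manh / (sums[:, None] + sums[None, :])
        else:  # theta_yc (always on proportions)
            q = counts / counts.sum(axis=1, keepdims=True)
            cross = q @ q.T
            sq = (q ** 2).sum(axis=1)
            denom = sq[:, None] + sq[None, :] - cross
            d = 1.0 - cross / denom
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(list(table.sample_ids), d)
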