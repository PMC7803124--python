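"""Distance-matrix hypothesis tests (AMOVA, HOMOVA) and ordination (PCoA).

AMOVA partitions squared pairwise distances among versus within groups,

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within
    F = [SS_among/(k-1)] / [SS_within/(N-k)]

with significance from random relabeling of group membership. HOMOVA tests
homogeneity of within-group dispersions with a Bartlett-style statistic on
the same squared-distance decomposition. Permutation p-values use the
add-one convention p = (b + 1)/(n_perm + 1); passing ``n_perm="all"``
enumerates every distinct relabeling instead (the observed labeling is
included, so p = #{F* >= F}/n_total).

PCoA applies Gower double-centering to -d^2/2 and an eigendecomposition;
negative eigenvalues (non-Euclidean Bray-Curtis / theta_YC matrices) are
reported but excluded from the percent-variance denominator, with no
Lingoes/Cailliez correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import eigh

from .community_data import DistanceMatrix


@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    f_stat: float
    p_value: float
    n_permutations: int


@dataclass
class HomovaResult:
    b_stat: float
    p_value: float
    n_permutations: int


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # (n_samples, n_positive_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    pct_variance: np.ndarray  # per positive axis, sums to <= 100


def _group_labels(dm: DistanceMatrix, groups: Mapping[str, str] | Sequence[str],
                  ) -> np.ndarray:
    if isinstance(groups, Mapping):
        missing = [i for i in dm.ids if i not in groups]
        if missing:
            raise KeyError(f"ids without a group label: {missing}")
        labels = np.array([groups[i] for i in dm.ids])
    else:
        if len(groups) != dm.n:
            raise ValueError("group labels must align with matrix ids")
        labels = np.asarray(list(groups))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = [u for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"singleton group(s): {small}")
    return labels


def _within_ss(d2: np.ndarray, labels: np.ndarray,
               uniq: np.ndarray) -> np.ndarray:
    """Per-group (1/n_g) * sum_{i<j in g} d_ij^2."""
    out = np.empty(len(uniq))
    for gi, g in enumerate(uniq):
        idx = np.flatnonzero(labels == g)
        out[gi] = d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return out


def _distinct_relabelings(labels: np.ndarray) -> list[np.ndarray]:
    """All distinct orderings of a label multiset (small n only)."""
    from itertools import permutations

    seen = set()
    out = []
    for perm in permutations(labels.tolist()):
        if perm not in seen:
            seen.add(perm)
            out.append(np.array(perm))
    return out


def _permutation_pvalue(stat_fn, labels: np.ndarray, observed: float,
                        n_perm, seed) -> tuple[float, int]:
    if n_perm == "all":
        relabelings = _distinct_relabelings(labels)
        stats = np.array([stat_fn(lab) for lab in relabelings])
        hits = int((stats >= observed - 1e-12).sum())
        return hits / len(relabelings), len(relabelings)
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        if stat_fn(perm_labels) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1), n_perm


def amova(dm: DistanceMatrix, groups, n_perm: int | str = 1000,
          seed: int | np.random.Generator = 0) -> AmovaResult:
    """Analysis of molecular variance on a distance matrix.

    ``groups`` maps every id to a group label (or is a sequence aligned with
    ``dm.ids``); every group needs at least two members.
    """
    labels = _group_labels(dm, groups)
    uniq = np.unique(labels)
    d2 = dm.d ** 2
    n = dm.n
    k = len(uniq)
    ss_total = d2.sum() / (2.0 * n)
    df_among = k - 1
    df_within = n - k

    def f_stat_of(lab: np.ndarray) -> float:
        ss_w = _within_ss(d2, lab, uniq).sum()
        ss_a = ss_total - ss_w
        with np.errstate(divide="ignore", invalid="ignore"):
            return float((ss_a / df_among) / (ss_w / df_within))

    ss_within = float(_within_ss(d2, labels, uniq).sum())
    ss_among = float(ss_total - ss_within)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = float((ss_among / df_among) / (ss_within / df_within))
    p, n_used = _permutation_pvalue(f_stat_of, labels, f_obs, n_perm, seed)
    return AmovaResult(ss_among=ss_among, ss_within=ss_within,
                       df_among=df_among, df_within=df_within,
                       f_stat=f_obs, p_value=p, n_permutations=n_used)


def homova(dm: DistanceMatrix, groups, n_perm: int | str = 1000,
           seed: int | np.random.Generator = 0) -> HomovaResult:
    """Homogeneity of molecular variance: Bartlett-style test that
    within-group dispersions SSw_g/(n_g - 1) are equal, with a permutation
    null."""
    labels = _group_labels(dm, groups)
    uniq = np.unique(labels)
    d2 = dm.d ** 2
    n_g = np.array([(labels == g).sum() for g in uniq])
    df = n_g - 1

    def b_stat_of(lab: np.ndarray) -> float:
        ssw = _within_ss(d2, lab, uniq)
        disp = np.maximum(ssw / df, 1e-300)
        pooled = max(ssw.sum() / df.sum(), 1e-300)
        return float(df.sum() * np.log(pooled) - (df * np.log(disp)).sum())

    b_obs = b_stat_of(labels)
    p, n_used = _permutation_pvalue(b_stat_of, labels, b_obs, n_perm, seed)
    return HomovaResult(b_stat=b_obs, p_value=p, n_permutations=n_used)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinate analysis of a distance matrix.

    Coordinates are returned for positive eigenvalues only, scaled so that
    inter-point Euclidean distances reproduce the input distances exactly
    when the matrix is Euclidean-embeddable.
    """
    if dm.n < 2:
        raise ValueError("PCoA needs at least two samples")
    a = -0.5 * dm.d ** 2
    centering = np.eye(dm.n) - np.ones((dm.n, dm.n)) / dm.n
    g = centering @ a @ centering
    g = (g + g.T) / 2.0
    eigvals, eigvecs = eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = 1e-9 * max(1.0, abs(eigvals[0]))
    positive = eigvals > tol
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    pct = 100.0 * pos_vals / pos_vals.sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pct = pct[:n_axes]
    return PcoaResult(coordinates=coords, eigenvalues=eigvals, pct_variance=pct)
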