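"""Anna-Karenina beta-diversity trajectories and their inference.

The Anna-Karenina principle predicts that a stressor increases the
differentiation *between* replicate communities rather than shifting them
all the same way. Here that is measured as the dissimilarity between pairs
of vessels over time (between-vessel series, matched at identical sampling
times) and between samples of one vessel across time lags (within-vessel
series). Slopes of dissimilarity on time (or lag) are fit by OLS; their
significance comes from a permutation test that shuffles time labels within
each vessel pair's sub-series (points sharing a pair are dependent, and
within-pair shuffling preserves that grouping while destroying the trend),
and 95% confidence intervals from a cluster bootstrap that resamples vessel
pairs with replacement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .beta_diversity import pairwise_distances
from .community_data import (
    CommunityTable,
    DistanceMatrix,
    SampleMetadata,
    TaxonomyMap,
)

PAIR_CATEGORIES = ("treatment-treatment", "control-control",
                   "treatment-control", "within-vessel")


@dataclass
class PairSeries:
    """Dissimilarity points for one pair category.

    ``points`` has columns ``vessel_a``, ``vessel_b``, ``time_h`` (the shared
    sampling time for between-vessel categories, the lag |t_a - t_b| for
    within-vessel) and ``dissimilarity``.
    """

    pair_category: str
    points: pd.DataFrame

    @property
    def x(self) -> np.ndarray:
        return self.points["time_h"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.points["dissimilarity"].to_numpy(dtype=float)

    @property
    def pair_ids(self) -> np.ndarray:
        return (self.points["vessel_a"] + "|" + self.points["vessel_b"]).to_numpy()


@dataclass
class SlopeInference:
    """OLS slope of dissimilarity on time/lag with permutation p and
    cluster-bootstrap 95% CI."""

    pair_category: str
    rank: str
    slope: float
    intercept: float
    ci95: tuple[float, float]
    p_value: float
    n_permutations: int
    n_bootstrap: int
    n_points: int


def build_pair_series(table: CommunityTable, tax: TaxonomyMap | None,
                      metadata: SampleMetadata, metric: str = "bray_curtis",
                      rank: str | None = None,
                      pair_category: str = "treatment-treatment",
                      dm: DistanceMatrix | None = None) -> PairSeries:
    """Enumerate qualifying sample pairs and their dissimilarities.

    Between-vessel categories pair distinct vessels of the required
    conditions at identical nominal times (no interpolation); the
    within-vessel category pairs samples of one vessel at distinct times and
    records the lag. A precomputed distance matrix may be passed to avoid
    recomputation across categories.
    """
    if pair_category not in PAIR_CATEGORIES:
        raise ValueError(f"unknown pair category {pair_category!r}")
    if dm is None:
        dm = pairwise_distances(table, metric=metric, tax=tax, rank=rank)
    meta = metadata.frame.set_index("sample_id")
    idx_of = {sid: i for i, sid in enumerate(dm.ids)}
    rows = []
    if pair_category == "within-vessel":
        for vessel, sub in meta.groupby("vessel", sort=True):
            sub = sub.sort_values("time_h")
            for (sa, ta), (sb, tb) in itertools.combinations(
                    zip(sub.index, sub["time_h"]), 2):
                rows.append(dict(vessel_a=vessel, vessel_b=vessel,
                                 time_a=float(ta), time_b=float(tb),
                                 time_h=abs(tb - ta),
                                 dissimilarity=dm.d[idx_of[sa], idx_of[sb]]))
    else:
        want = tuple(sorted(pair_category.split("-")))
        vessels = (meta[["vessel", "condition"]].drop_duplicates()
                   .sort_values("vessel"))
        for (va, ca), (vb, cb) in itertools.combinations(
                vessels.itertuples(index=False), 2):
            if tuple(sorted((ca, cb))) != want:
                continue
            times_a = {t: sid for sid, t in
                       zip(meta.index[meta["vessel"] == va],
                           meta.loc[meta["vessel"] == va, "time_h"])}
            times_b = {t: sid for sid, t in
                       zip(meta.index[meta["vessel"] == vb],
                           meta.loc[meta["vessel"] == vb, "time_h"])}
            for t in sorted(set(times_a) & set(times_b)):
                rows.append(dict(
                    vessel_a=va, vessel_b=vb,
                    time_a=float(t), time_b=float(t), time_h=float(t),
                    dissimilarity=dm.d[idx_of[times_a[t]], idx_of[times_b[t]]]))
    if not rows:
        raise ValueError(f"no qualifying pairs for category {pair_category!r}")
    return PairSeries(pair_category, pd.DataFrame(rows))


def fit_slope(series: PairSeries) -> tuple[float, float]:
    """Ordinary least squares of dissimilarity on time (or lag)."""
    x, y = series.x, series.y
    if len(x) < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("all times equal; slope undefined")
    res = sstats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xbar = x.mean()
    return float(((x - xbar) * (y - y.mean())).sum() / ((x - xbar) ** 2).sum())


def permutation_slope_test(series: PairSeries, n_perm: int | str = 1000,
                           seed: int | np.random.Generator = 0) -> float:
    """Two-sided permutation p for a non-zero slope.

    The null permutes the *time labels of the underlying samples*, not
    individual points, because points are dependent wherever they share a
    sample: for between-vessel series d(A_t, B_t) and d(A_t, C_t) share
    vessel A's sample at t. Between-vessel series therefore get one shared
    permutation of the sampling times per iteration (whole time
    cross-sections are relabeled together); within-vessel series get an
    independent permutation of each vessel's sampling times, with lags
    recomputed. Both preserve the full dependence structure of the points
    while destroying any time trend. p = (#{|slope*| >= |slope|} + 1) /
    (n_perm + 1), or an exact enumeration with ``n_perm="all"``.
    """
    slope, _ = fit_slope(series)
    y = series.y
    target = abs(slope)
    pts = series.points
    within = series.pair_category == "within-vessel"

    if within:
        # per-vessel time relabelings; x* = |pi_v(t_a) - pi_v(t_b)|
        vessels = pd.unique(pts["vessel_a"])
        vessel_times = {v: np.sort(pts.loc[pts["vessel_a"] == v,
                                           ["time_a", "time_b"]]
                                   .to_numpy().ravel()) for v in vessels}
        vessel_times = {v: np.unique(t) for v, t in vessel_times.items()}
        t_index = {
            v: (np.searchsorted(vessel_times[v],
                                pts.loc[pts["vessel_a"] == v, "time_a"]),
                np.searchsorted(vessel_times[v],
                                pts.loc[pts["vessel_a"] == v, "time_b"]),
                np.flatnonzero((pts["vessel_a"] == v).to_numpy()))
            for v in vessels
        }

        def x_of(perms: dict) -> np.ndarray:
            x = np.empty(len(pts))
            for v in vessels:
                ia, ib, rows = t_index[v]
                tv = vessel_times[v][perms[v]]
                x[rows] = np.abs(tv[ia] - tv[ib])
            return x

        if n_perm == "all":
            per_vessel = {v: list(itertools.permutations(
                range(len(vessel_times[v])))) for v in vessels}
            combos = itertools.product(*[per_vessel[v] for v in vessels])
            total = hits = 0
            for combo in combos:
                x = x_of({v: np.array(p) for v, p in zip(vessels, combo)})
                if np.ptp(x) == 0:
                    continue
                total += 1
                if abs(_slope(x, y)) >= target - 1e-12:
                    hits += 1
            return hits / total
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        hits = 0
        for _ in range(int(n_perm)):
            x = x_of({v: rng.permutation(len(vessel_times[v]))
                      for v in vessels})
            if np.ptp(x) == 0 or abs(_slope(x, y)) >= target - 1e-12:
                hits += 1
        return (hits + 1) / (int(n_perm) + 1)

    # between-vessel: one shared permutation of the distinct sampling times
    times = np.unique(pts["time_h"].to_numpy(dtype=float))
    t_idx = np.searchsorted(times, pts["time_h"].to_numpy(dtype=float))
    if n_perm == "all":
        total = hits = 0
        for perm in itertools.permutations(range(len(times))):
            x = times[np.asarray(perm)][t_idx]
            total += 1
            if abs(_slope(x, y)) >= target - 1e-12:
                hits += 1
        return hits / total
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        x = times[rng.permutation(len(times))][t_idx]
        if abs(_slope(x, y)) >= target - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def bootstrap_slope_ci(series: PairSeries, n_boot: int = 1000,
                       seed: int | np.random.Generator = 0,
                       ) -> tuple[float, float]:
    """Percentile 95% CI for the slope by cluster bootstrap over vessel pairs.

    Pairs are resampled with replacement and all points of a resampled pair
    enter the refit, respecting the within-pair dependence.
    """
    groups = series.pair_ids
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("cluster bootstrap needs at least two vessel pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    group_idx = [np.flatnonzero(groups == g) for g in uniq]
    x, y = series.x, series.y
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        chosen = rng.integers(0, len(uniq), size=len(uniq))
        idx = np.concatenate([group_idx[c] for c in chosen])
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:
            slopes[b] = np.nan
            continue
        xbar = xb.mean()
        slopes[b] = ((xb - xbar) * (yb - yb.mean())).sum() / ((xb - xbar) ** 2).sum()
    slopes = slopes[~np.isnan(slopes)]
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return float(lo), float(hi)


def multi_rank_akh(table: CommunityTable, tax: TaxonomyMap,
                   metadata: SampleMetadata, metric: str = "bray_curtis",
                   ranks: tuple[str, ...] = ("genus", "family", "order",
                                             "class", "phylum"),
                   categories: tuple[str, ...] = PAIR_CATEGORIES,
                   n_perm: int = 1000, n_boot: int = 1000,
                   seed: int | np.random.Generator = 0,
                   ) -> list[SlopeInference]:
    """Full grid of (rank x pair category) slope inferences.

    One distance matrix is computed per rank and shared across categories;
    the whole grid is deterministic under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[SlopeInference] = []
    for rank in ranks:
        dm = pairwise_distances(table, metric=metric, tax=tax, rank=rank)
        for category in categories:
            series = build_pair_series(table, tax, metadata, metric=metric,
                                       rank=rank, pair_category=category,
                                       dm=dm)
            slope, intercept = fit_slope(series)
            p = permutation_slope_test(series, n_perm=n_perm, seed=rng)
            ci = bootstrap_slope_ci(series, n_boot=n_boot, seed=rng)
            out.append(SlopeInference(
                pair_category=category, rank=rank, slope=slope,
                intercept=intercept, ci95=ci, p_value=p,
                n_permutations=n_perm, n_bootstrap=n_boot,
                n_points=len(series.points)))
    return out


def slope_table(inferences: list[SlopeInference]) -> pd.DataFrame:
    rows = []
    for inf in inferences:
        rows.append(dict(rank=inf.rank, pair_category=inf.pair_category,
                         slope=inf.slope, intercept=inf.intercept,
                         ci_lo=inf.ci95[0], ci_hi=inf.ci95[1],
                         p_value=inf.p_value, n_points=inf.n_points,
                         n_permutations=inf.n_permutations,
                         n_bootstrap=inf.n_bootstrap))
    return pd.DataFrame(rows)


def dispersion_peak_estimate(tt_series: PairSeries,
                             window_h: float = 24.0) -> float:
    """Time of maximal smoothed between-vessel dissimilarity.

    Per-time mean dissimilarities are smoothed with a centered moving
    average whose window spans one feeding cycle (24 h by default); ties are
    broken to the earliest time.
    """
    pts = tt_series.points
    times = np.sort(pts["time_h"].unique())
    if len(times) < 4:
        raise ValueError("need at least four distinct times")
    means = np.array([pts.loc[pts["time_h"] == t, "dissimilarity"].mean()
                      for t in times])
    smoothed = np.array([
        means[np.abs(times - t) <= window_h / 2.0].mean() for t in times
    ])
    best = np.flatnonzero(smoothed >= smoothed.max() - 1e-12)[0]
    return float(times[best])
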