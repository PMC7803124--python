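"""Within-sample richness, coverage and diversity indices.

Conventions follow mothur: Shannon uses the natural logarithm, Chao1 is the
bias-corrected form (n2 + 1 in the denominator, so samples without doubletons
are defined), Good's coverage is 1 - n1/N with n1 the number of singleton
OTUs in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_data import CommunityTable


@dataclass
class AlphaResult:
    """Per-sample diversity summary."""

    sample_id: str
    s_obs: int
    chao1: float
    goods_coverage: float
    shannon: float
    inv_simpson: float


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if x.sum() <= 0:
        raise ValueError("counts must have a positive total")
    return x


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i over taxa with positive counts."""
    x = _as_counts(counts)
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def inv_simpson(counts) -> float:
    """Inverse Simpson index D = 1 / sum p_i^2."""
    x = _as_counts(counts)
    p = x / x.sum()
    return float(1.0 / (p ** 2).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + n1(n1-1) / (2(n2+1))."""
    x = _as_counts(counts)
    s_obs = int((x > 0).sum())
    n1 = int((x == 1).sum())
    n2 = int((x == 2).sum())
    return s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))


def goods_coverage(counts) -> float:
    """Good's coverage estimate 1 - n1/N."""
    x = _as_counts(counts)
    n1 = int((x == 1).sum())
    return 1.0 - n1 / x.sum()


def alpha_table(table: CommunityTable) -> pd.DataFrame:
    """All indices for every sample of a table, one row per sample."""
    rows = []
    for sid, counts in zip(table.sample_ids, table.counts):
        rows.append(AlphaResult(
            sample_id=sid,
            s_obs=int((counts > 0).sum()),
            chao1=chao1(counts),
            goods_coverage=goods_coverage(counts),
            shannon=shannon(counts),
            inv_simpson=inv_simpson(counts),
        ).__dict__)
    return pd.DataFrame(rows)


def rarefaction_curve(counts, depths, n_reps: int = 100,
                      seed: int | np.random.Generator = 0,
                      ) -> list[tuple[int, float, float]]:
    """Mean and SD of observed richness over seeded subsamples per depth.

    Subsampling is without replacement (multivariate hypergeometric); the
    expected curve is therefore monotone non-decreasing in depth.
    """
    x = _as_counts(counts).astype(np.int64)
    n = int(x.sum())
    depths = [int(d) for d in np.atleast_1d(depths)]
    for d in depths:
        if d > n:
            raise ValueError(f"depth {d} exceeds library size {n}")
        if d <= 0:
            raise ValueError("depths must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for d in depths:
        if d == n:
            richness = np.full(n_reps, float((x > 0).sum()))
        else:
            richness = np.array([
                float((rng.multivariate_hypergeometric(x, d, method="marginals")
                       > 0).sum())
                for _ in range(n_reps)
            ])
        out.append((d, float(richness.mean()), float(richness.std(ddof=0))))
    return out


def expected_richness(counts, depth: int) -> float:
    """Closed-form expected richness at a subsampling depth.

    E[S] = sum_i (1 - C(N - x_i, depth) / C(N, depth)), the hypergeometric
    probability that taxon i appears at least once in the subsample.
    """
    from scipy.special import gammaln

    x = _as_counts(counts).astype(np.int64)
    n = int(x.sum())
    if depth > n:
        raise ValueError("depth exceeds library size")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    probs = []
    for xi in x[x > 0]:
        if n - xi < depth:
            probs.append(1.0)
        else:
            probs.append(1.0 - np.exp(log_comb(n - xi, depth) - log_comb(n, depth)))
    return float(np.sum(probs))
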