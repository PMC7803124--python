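"""Gas and volatile-fatty-acid summaries with permutation-based contrasts.

Gas production is expressed in ml per gram of organic matter fed; VFA
concentrations in ppm. Treatment effects are tested with a vessel-level
permutation contrast: vessels are the exchangeable experimental units, the
statistic is the difference of condition means of per-vessel averages, and
condition labels are permuted across vessels (exactly, by enumeration, when
the number of distinct relabelings is small). This is an assumption-light
substitute for a repeated-measures mixed model and is exact at small vessel
counts.

The propionate:acetate ratio is computed per record and then averaged within
condition (mean of ratios, not ratio of means).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iperm

import numpy as np
import pandas as pd

from .community_data import CommunityTable, SampleMetadata, TaxonomyMap, aggregate_to_rank

GAS_RESPONSES = ("ch4", "co2", "total_gas")
VFA_RESPONSES = ("acetate", "propionate", "butyrate", "isobutyrate",
                 "valerate", "isovalerate")

FERMENTATION_COLUMNS = ("vessel", "condition", "day", "hours_post_feeding",
                        *GAS_RESPONSES, *VFA_RESPONSES)


def validate_fermentation(series: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy fermentation frame: required columns, nonnegative values,
    total gas at least CH4."""
    missing = set(FERMENTATION_COLUMNS) - set(series.columns)
    if missing:
        raise ValueError(f"fermentation series missing columns {sorted(missing)}")
    numeric = [*GAS_RESPONSES, *VFA_RESPONSES]
    if (series[numeric] < 0).any().any():
        raise ValueError("gas and VFA values must be nonnegative")
    if (series["total_gas"] < series["ch4"] - 1e-9).any():
        raise ValueError("total_gas must be at least ch4")
    return series


def read_fermentation(path) -> pd.DataFrame:
    return validate_fermentation(pd.read_csv(path, sep="\t"))


def write_fermentation(series: pd.DataFrame, path) -> None:
    series.to_csv(path, sep="\t", index=False)


def normalize_per_g_om(volume_ml: float, grams_om_fed: float) -> float:
    """Gas volume per gram organic matter fed."""
    if grams_om_fed <= 0:
        raise ValueError("grams of organic matter fed must be positive")
    return volume_ml / grams_om_fed


def percent_reduction(control_mean: float, treatment_mean: float) -> float:
    """100 * (control - treatment) / control."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (control_mean - treatment_mean) / control_mean


def propionate_acetate_ratio(series: pd.DataFrame,
                             ) -> tuple[pd.Series, dict[str, float]]:
    """Per-record propionate/acetate ratios and their condition means.

    The group statistic is the mean of per-record ratios; the ratio of group
    means is a different (and generally smaller) quantity.
    """
    validate_fermentation(series)
    if (series["acetate"] <= 0).any():
        raise ValueError("acetate must be positive in every record")
    ratios = series["propionate"] / series["acetate"]
    means = {cond: float(ratios[series["condition"] == cond].mean())
             for cond in ("control", "treatment")
             if (series["condition"] == cond).any()}
    return ratios, means


@dataclass
class ContrastResult:
    response: str
    effect: float  # mean(treatment) - mean(control) of per-vessel averages
    p_value: float
    n_relabelings: int
    exhaustive: bool


def _distinct_relabelings(labels: list[str]) -> list[tuple[str, ...]]:
    return sorted(set(_iperm(labels)))


def treatment_contrast(series: pd.DataFrame, response: str,
                       n_perm: int = 1000,
                       seed: int | np.random.Generator = 0) -> ContrastResult:
    """Two-sided vessel-level permutation test of a treatment effect.

    Per-vessel averages are the units; the condition labels are permuted
    across vessels. When the number of distinct relabelings is at most
    ``n_perm`` the enumeration is exhaustive and the p-value exact
    (observed labeling included); otherwise relabelings are sampled with the
    add-one convention.
    """
    validate_fermentation(series)
    if response not in series.columns:
        raise KeyError(f"unknown response {response!r}")
    per_vessel = (series.groupby(["vessel", "condition"], sort=True)[response]
                  .mean().reset_index())
    labels = per_vessel["condition"].tolist()
    values = per_vessel[response].to_numpy(dtype=float)
    conds = set(labels)
    if conds != {"control", "treatment"}:
        raise ValueError("both conditions must be present")

    def effect_of(lab) -> float:
        lab = np.asarray(lab)
        return float(values[lab == "treatment"].mean()
                     - values[lab == "control"].mean())

    observed = effect_of(labels)
    target = abs(observed)
    relabelings = _distinct_relabelings(labels)
    if len(relabelings) <= n_perm:
        effects = np.array([effect_of(lab) for lab in relabelings])
        hits = int((np.abs(effects) >= target - 1e-12).sum())
        return ContrastResult(response, observed, hits / len(relabelings),
                              len(relabelings), True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lab_arr = np.asarray(labels)
    hits = 0
    for _ in range(n_perm):
        if abs(effect_of(lab_arr[rng.permutation(len(lab_arr))])) >= target - 1e-12:
            hits += 1
    return ContrastResult(response, observed, (hits + 1) / (n_perm + 1),
                          n_perm, False)


def relative_abundance_summary(table: CommunityTable, tax: TaxonomyMap,
                               metadata: SampleMetadata, taxon: str,
                               rank: str = "phylum") -> dict[str, float]:
    """Mean relative abundance (percent) of one taxon per condition, over all
    samples of the experiment."""
    agg = aggregate_to_rank(table, tax, rank)
    if taxon not in agg.otu_ids:
        raise KeyError(f"taxon {taxon!r} not found at rank {rank!r}")
    j = agg.otu_ids.index(taxon)
    frac = agg.counts[:, j] / agg.library_sizes
    meta = metadata.frame.set_index("sample_id")
    out: dict[str, float] = {}
    for cond in ("control", "treatment"):
        sids = [s for s in agg.sample_ids if meta.loc[s, "condition"] == cond]
        if sids:
            idx = [agg.sample_ids.index(s) for s in sids]
            out[cond] = float(100.0 * frac[idx].mean())
    return out


def summarize_fermentation(series: pd.DataFrame, n_perm: int = 1000,
                           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Group means, SEs and permutation p per response, one row per response.

    SEs are computed over per-vessel averages; both per-group SEs and a
    pooled SE (of the difference of means) are reported, since published
    tables often print only a single pooled value.
    """
    validate_fermentation(series)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ratios, _ = propionate_acetate_ratio(series)
    work = series.copy()
    work["propionate_acetate"] = ratios
    rows = []
    for response in (*GAS_RESPONSES, *VFA_RESPONSES, "propionate_acetate"):
        per_vessel = (work.groupby(["vessel", "condition"], sort=True)[response]
                      .mean().reset_index())
        stats_row: dict[str, object] = {"response": response}
        pooled_var = 0.0
        for cond in ("control", "treatment"):
            vals = per_vessel.loc[per_vessel["condition"] == cond,
                                  response].to_numpy()
            stats_row[f"{cond}_mean"] = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
            stats_row[f"{cond}_se"] = se
            pooled_var += se ** 2
        stats_row["pooled_se"] = float(np.sqrt(pooled_var))
        contrast = treatment_contrast(work, response, n_perm=n_perm, seed=rng)
        stats_row["effect"] = contrast.effect
        stats_row["p_value"] = contrast.p_value
        rows.append(stats_row)
    return pd.DataFrame(rows)
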