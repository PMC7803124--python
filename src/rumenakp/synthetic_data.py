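"""Synthetic rumen-microbiome and fermentation data with the study's structure.

Emulates a semi-continuous in-vitro rumen (RUSITEC) experiment: 3 control and
3 treatment vessels sampled at 4, 12 and 24 h post-feeding on each of 4 days
(12 timepoints, 4-96 h since start). Communities are drawn from a
Dirichlet-multinomial model whose mean composition carries

* a treatment-specific depletion of the five rumen methanogen genera
  (Euryarchaeota), controlled by ``methanogen_log2_depletion``, and
* a shared monotone Bacteroidetes:Firmicutes drift in both conditions,

and whose dispersion carries the Anna-Karenina effect: in treatment vessels
the Dirichlet concentration is divided by a tent-shaped multiplier of time
that peaks at ``akp_peak_h``, so treatment communities scatter more around
the same mean mid-experiment and reconverge afterwards. Mean composition and
dispersion are deliberately separable so downstream dispersion statistics can
be validated against a known effect.

Fermentation series (gas in ml/(g OM), VFA in ppm) are zero-truncated
Gaussian draws around per-condition means; the defaults encode a ~95%
CH4 suppression in treatment at roughly unchanged total VFA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .community_data import (
    CANONICAL_RANKS,
    CommunityTable,
    SampleMetadata,
    TaxonomyMap,
)

#: The five methanogen genera observed in the system, with their lineages and
#: their share of the total methanogen abundance (the first two dominate).
METHANOGEN_GENERA: tuple[tuple[str, tuple[str, ...], float], ...] = (
    ("Methanobrevibacter",
     ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales",
      "Methanobacteriaceae"), 0.700),
    ("Methanosphaera",
     ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales",
      "Methanobacteriaceae"), 0.292),
    ("vadinCA11",
     ("Archaea", "Euryarchaeota", "Thermoplasmata", "Methanomassiliicoccales",
      "Methanomassiliicoccaceae"), 0.004),
    ("Methanoplanus",
     ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanomicrobiales",
      "Methanomicrobiaceae"), 0.002),
    ("Methanimicrococcus",
     ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanosarcinales",
      "Methanosarcinaceae"), 0.002),
)

#: Bacterial phyla and their share of the non-methanogen community, plus the
#: class name used when constructing lineages.
BACTERIAL_PHYLA: tuple[tuple[str, str, float], ...] = (
    ("Bacteroidetes", "Bacteroidia", 0.46),
    ("Firmicutes", "Clostridia", 0.36),
    ("Proteobacteria", "Gammaproteobacteria", 0.12),
    ("Spirochaetes", "Spirochaetia", 0.03),
    ("Fibrobacteres", "Fibrobacteria", 0.03),
)

#: A few real rumen genera used as the leading (most abundant) genera per
#: phylum; remaining genera get systematic names.
SEED_GENERA: Mapping[str, tuple[str, ...]] = {
    "Bacteroidetes": ("Prevotella", "Bacteroides", "Rikenellaceae_RC9"),
    "Firmicutes": ("Ruminococcus", "Butyrivibrio", "Selenomonas", "Lachnospira"),
    "Proteobacteria": ("Succinivibrio", "Desulfovibrio"),
    "Spirochaetes": ("Treponema",),
    "Fibrobacteres": ("Fibrobacter",),
}

#: (control_mean, treatment_mean, control_sd, treatment_sd) per gas response,
#: in ml/(g OM).
DEFAULT_GAS_PARAMS: Mapping[str, tuple[float, float, float, float]] = {
    "ch4": (12.08, 0.59, 1.0, 0.2),
    "co2": (15.67, 14.24, 4.0, 4.0),
    "total_gas": (28.54, 14.81, 4.5, 4.5),
}

#: (control_mean, treatment_mean, sd) per volatile fatty acid, in ppm.
DEFAULT_VFA_PARAMS: Mapping[str, tuple[float, float, float]] = {
    "acetate": (1056.99, 856.77, 234.0),
    "propionate": (481.12, 490.54, 101.0),
    "butyrate": (394.35, 423.01, 93.0),
    "isobutyrate": (84.81, 79.83, 7.5),
    "valerate": (212.79, 168.72, 29.4),
    "isovalerate": (102.44, 86.21, 25.1),
}

DEFAULT_TIMEPOINTS_H: tuple[float, ...] = (
    4, 12, 24, 28, 36, 48, 52, 60, 72, 76, 84, 96,
)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic experiment.

    Defaults encode the study design: 3 vessels per condition, 12 timepoints
    over 4 days, rarefaction depth 6467 reads/sample, 120 genera including
    the five methanogens at a combined baseline of 1.79% relative abundance,
    dispersion (Anna-Karenina) peak at 72 h with a 4-fold concentration
    reduction, and a 0.4 log2 methanogen depletion under treatment.
    """

    n_vessels_per_condition: int = 3
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    depth: int = 6467
    n_genera: int = 120
    base_concentration: float = 50.0
    akp_peak_h: float = 72.0
    akp_strength: float = 4.0
    methanogen_log2_depletion: float = 0.4
    methanogen_rel_abundance: float = 0.0179
    bf_drift_rate: float = 0.10  # per day, applied to Bacteroidetes means
    geometric_decay: float = 0.88  # within-phylum rank-abundance decay
    gas_params: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GAS_PARAMS))
    vfa_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VFA_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.akp_strength < 1:
            raise ConfigError("akp_strength must be >= 1")
        if self.n_genera < len(METHANOGEN_GENERA) + len(BACTERIAL_PHYLA):
            raise ConfigError("n_genera too small for the taxonomy seedlist")
        if not 0 < self.methanogen_rel_abundance < 1:
            raise ConfigError("methanogen_rel_abundance must be in (0,1)")
        if self.base_concentration <= 0:
            raise ConfigError("base_concentration must be positive")
        for name, (mc, mt, sc, st) in self.gas_params.items():
            if sc < 0 or st < 0:
                raise ConfigError(f"negative SD for gas {name}")
        for name, (mc, mt, s) in self.vfa_params.items():
            if s < 0:
                raise ConfigError(f"negative SD for VFA {name}")

    # -- derived structure -------------------------------------------------

    @classmethod
    def null(cls, **overrides) -> "SyntheticConfig":
        """A no-effect configuration: control and treatment exchangeable."""
        overrides.setdefault("akp_strength", 1.0)
        overrides.setdefault("methanogen_log2_depletion", 0.0)
        overrides.setdefault("bf_drift_rate", 0.0)
        return cls(**overrides)

    @property
    def vessels(self) -> list[tuple[str, str]]:
        """(vessel_id, condition) pairs: C1..Cn control, T1..Tn treatment."""
        out = [(f"C{i+1}", "control") for i in range(self.n_vessels_per_condition)]
        out += [(f"T{i+1}", "treatment") for i in range(self.n_vessels_per_condition)]
        return out

    def build_taxonomy(self) -> tuple[list[str], TaxonomyMap]:
        """Genus catalog (one OTU per genus) with a full six-rank lineage.

        Genera are grouped three-per-family and families two-per-order within
        each phylum, so aggregation at coarser ranks genuinely collapses
        columns. The catalog is deterministic and cached per config.
        """
        cached = getattr(self, "_taxonomy_cache", None)
        if cached is not None:
            return cached
        genera: list[tuple[str, tuple[str, ...]]] = []
        for name, lineage, _ in METHANOGEN_GENERA:
            genera.append((name, (*lineage, name)))
        n_bact = self.n_genera - len(METHANOGEN_GENERA)
        shares = np.array([w for _, _, w in BACTERIAL_PHYLA])
        counts = np.maximum(1, np.round(shares / shares.sum() * n_bact).astype(int))
        while counts.sum() > n_bact:
            counts[np.argmax(counts)] -= 1
        while counts.sum() < n_bact:
            counts[np.argmin(counts)] += 1
        for (phylum, cls_name, _), k in zip(BACTERIAL_PHYLA, counts):
            seeds = SEED_GENERA.get(phylum, ())
            names = list(seeds[:k])
            names += [f"{phylum}_genus_{i+1:03d}" for i in range(k - len(names))]
            for gi, gname in enumerate(names):
                fam = f"{phylum}_family_{gi // 3 + 1:02d}"
                order = f"{phylum}_order_{gi // 6 + 1:02d}"
                genera.append((gname, ("Bacteria", phylum, cls_name, order,
                                       fam, gname)))
        otu_ids = [f"Otu{i+1:04d}" for i in range(len(genera))]
        lineages = {
            otu: tuple(zip(CANONICAL_RANKS, lineage))
            for otu, (_, lineage) in zip(otu_ids, genera)
        }
        result = (otu_ids, TaxonomyMap(lineages))
        object.__setattr__(self, "_taxonomy_cache", result)
        return result

    def base_composition(self) -> np.ndarray:
        """Baseline mean relative abundances, aligned with build_taxonomy order."""
        cached = getattr(self, "_base_comp_cache", None)
        if cached is not None:
            return cached
        otu_ids, tax = self.build_taxonomy()
        props = np.empty(len(otu_ids))
        meth_share = np.array([w for _, _, w in METHANOGEN_GENERA])
        props[: len(METHANOGEN_GENERA)] = (
            self.methanogen_rel_abundance * meth_share / meth_share.sum())
        phyla = [tax.name_at(o, "phylum") for o in otu_ids]
        budget = 1.0 - self.methanogen_rel_abundance
        shares = {p: w for p, _, w in BACTERIAL_PHYLA}
        total_share = sum(shares.values())
        for phylum in shares:
            idx = [i for i, p in enumerate(phyla) if p == phylum]
            ranks = np.arange(len(idx))
            weights = self.geometric_decay ** ranks
            props[idx] = (budget * shares[phylum] / total_share
                          * weights / weights.sum())
        props = props / props.sum()
        object.__setattr__(self, "_base_comp_cache", props)
        return props

    def mean_composition(self, condition: str, time_h: float) -> np.ndarray:
        """Expected composition for one condition at one timepoint.

        Treatment multiplies methanogen means by 2^(-depletion) and
        renormalises. Both conditions share a monotone Bacteroidetes ->
        Firmicutes mass transfer at ``bf_drift_rate`` per day (the
        Bacteroidetes:Firmicutes ratio falls over the experiment) which
        leaves the expected share of every other taxon unchanged.
        """
        props = self.base_composition().copy()
        otu_ids, tax = self.build_taxonomy()
        if condition == "treatment":
            props[: len(METHANOGEN_GENERA)] *= 2.0 ** (-self.methanogen_log2_depletion)
            props = props / props.sum()
        elif condition != "control":
            raise ValueError(f"unknown condition {condition!r}")
        if self.bf_drift_rate:
            phyla = np.array([tax.name_at(o, "phylum") for o in otu_ids])
            is_bact = phyla == "Bacteroidetes"
            is_firm = phyla == "Firmicutes"
            decay = np.exp(-self.bf_drift_rate * time_h / 24.0)
            lost = props[is_bact].sum() * (1.0 - decay)
            props[is_bact] *= decay
            firm = props[is_firm]
            props[is_firm] = firm + lost * firm / firm.sum()
        return props / props.sum()

    def dispersion_multiplier(self, condition: str, time_h: float) -> float:
        """Tent-shaped concentration divisor: 1 away from the peak,
        ``akp_strength`` at ``akp_peak_h``, for treatment vessels only."""
        if condition != "treatment" or self.akp_strength == 1.0:
            return 1.0
        width = self.akp_peak_h - min(self.timepoints_h)
        if width <= 0:
            return self.akp_strength
        ramp = max(0.0, 1.0 - abs(time_h - self.akp_peak_h) / width)
        return 1.0 + (self.akp_strength - 1.0) * ramp

    def expected_taxon_pct(self, condition: str, phylum: str) -> float:
        """Analytic mean relative abundance (percent) of a phylum, averaged
        over timepoints — the Dirichlet-multinomial mean equals the mean
        composition, so this is exact for the generator."""
        otu_ids, tax = self.build_taxonomy()
        mask = np.array([tax.name_at(o, "phylum") == phylum for o in otu_ids])
        vals = [self.mean_composition(condition, t)[mask].sum()
                for t in self.timepoints_h]
        return 100.0 * float(np.mean(vals))


def _time_to_day_hpf(time_h: float) -> tuple[int, float]:
    day = int(np.ceil(time_h / 24.0))
    hpf = time_h - 24.0 * (day - 1)
    return day, hpf


def generate_communities(
    config: SyntheticConfig,
) -> tuple[CommunityTable, TaxonomyMap, SampleMetadata]:
    """Draw one Dirichlet-multinomial community per (vessel, timepoint).

    Counts for sample i are Multinomial(depth, p_i) with
    p_i ~ Dirichlet(c/m(t) * mu(condition, t)), where c is
    ``base_concentration``, m the treatment dispersion multiplier and mu the
    condition/time mean composition. Fully reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    otu_ids, tax = config.build_taxonomy()
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    rows: list[np.ndarray] = []
    for vessel, condition in config.vessels:
        for t in config.timepoints_h:
            mu = config.mean_composition(condition, t)
            conc = config.base_concentration / config.dispersion_multiplier(
                condition, t)
            alpha = np.maximum(conc * mu, 1e-9)
            p = rng.dirichlet(alpha)
            counts = rng.multinomial(config.depth, p)
            day, hpf = _time_to_day_hpf(t)
            sid = f"{vessel}_d{day}h{int(hpf):02d}"
            sample_ids.append(sid)
            rows.append(counts)
            meta_rows.append(dict(sample_id=sid, vessel=vessel,
                                  condition=condition, day=day,
                                  hours_post_feeding=hpf, time_h=float(t)))
    table = CommunityTable(sample_ids, otu_ids,
                           np.array(rows, dtype=np.int64))
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    return table, tax, meta


def generate_fermentation(config: SyntheticConfig) -> pd.DataFrame:
    """Per-vessel/timepoint gas and VFA series as a tidy DataFrame.

    Values are zero-truncated Gaussian draws around the configured condition
    means (exactly the means when the SD is zero). ``total_gas`` is clamped
    to at least CH4 so component gases never exceed the total.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xFE)))
    records: list[dict] = []
    for vessel, condition in config.vessels:
        for t in config.timepoints_h:
            day, hpf = _time_to_day_hpf(t)
            rec = dict(vessel=vessel, condition=condition, day=day,
                       hours_post_feeding=hpf, time_h=float(t))
            ci = 0 if condition == "control" else 1
            for gas, (mc, mt, sc, st) in config.gas_params.items():
                mean = (mc, mt)[ci]
                sd = (sc, st)[ci]
                rec[gas] = _truncated_normal(mean, sd, rng)
            rec["total_gas"] = max(rec["total_gas"], rec["ch4"])
            for acid, (mc, mt, sd) in config.vfa_params.items():
                rec[acid] = _truncated_normal((mc, mt)[ci], sd, rng)
            records.append(rec)
    return pd.DataFrame(records)


def _truncated_normal(mean: float, sd: float,
                      rng: np.random.Generator) -> float:
    if sd == 0:
        return float(mean)
    a = -mean / sd  # truncate at zero
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))
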