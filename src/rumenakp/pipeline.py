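"""End-to-end orchestration: simulate or load data, then run every analysis
stage into a deterministic directory layout with a reproducibility manifest.

A run is configured by a :class:`RunConfig` (optionally parsed from a YAML
file). One master seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` spawn keys, so any stage can be rerun in
isolation and the whole run is bit-reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    akh_trajectory,
    alpha_diversity,
    beta_diversity,
    community_data,
    community_stats,
    fermentation_metrics,
    synthetic_data,
)

logger = logging.getLogger(__name__)

STAGE_SEEDS = {"simulate": 1, "rarefy": 2, "alpha": 3, "beta": 4,
               "amova": 5, "homova": 6, "akh": 7, "ferment": 8}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for one stage, stably derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(STAGE_SEEDS[stage],)))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "results/run"
    seed: int = 0
    simulate: synthetic_data.SyntheticConfig | None = None
    shared_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    fermentation_path: str | None = None
    rarefy_depth: int = 6467
    metric: str = "bray_curtis"
    amova_metric: str = "theta_yc"
    ranks: tuple[str, ...] = ("genus", "family", "order", "class", "phylum")
    n_perm: int = 1000
    n_boot: int = 1000

    def validate(self) -> None:
        if self.simulate is None:
            if self.shared_path is None:
                raise ValueError("either 'simulate' or input paths must be given")
            if self.ranks and self.taxonomy_path is None:
                raise ValueError("rank aggregation requested but no taxonomy given")
            if self.metadata_path is None:
                raise ValueError("metadata is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if k == "ranks" else v for k, v in raw.items()})
        if sim is not None:
            if isinstance(sim, dict):
                if "timepoints_h" in sim:
                    sim["timepoints_h"] = tuple(sim["timepoints_h"])
                cfg.simulate = synthetic_data.SyntheticConfig(**sim)
            else:
                cfg.simulate = synthetic_data.SyntheticConfig(seed=cfg.seed)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> filter/rarefy -> alpha -> beta -> AMOVA/
    HOMOVA/PCoA -> trajectory inference -> fermentation summary.

    Returns the manifest (also written as ``manifest.json``) listing every
    input hash, per-stage seed and output file.
    """
    config.validate()
    out = Path(config.output_dir)
    for sub in ("tables", "distances", "stats", "figures-data"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {},
                      "outputs": []}
    timings: dict[str, float] = {}

    def record(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    def stage(name: str):
        timings[name] = time.perf_counter()
        logger.info("stage %s started", name)

    def done(name: str) -> None:
        logger.info("stage %s finished in %.2fs",
                    name, time.perf_counter() - timings[name])
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - timings[name], 3),
            "seed_key": STAGE_SEEDS.get(name),
        }

    # -- acquire data ------------------------------------------------------
    if config.simulate is not None:
        stage("simulate")
        sim = config.simulate
        table, tax, meta = synthetic_data.generate_communities(sim)
        ferm = synthetic_data.generate_fermentation(sim)
        community_data.write_shared(table, record(out / "tables" / "raw.shared"))
        community_data.write_taxonomy(tax, record(out / "tables" / "taxonomy.tsv"))
        community_data.write_metadata(meta, record(out / "tables" / "metadata.tsv"))
        fermentation_metrics.write_fermentation(
            ferm, record(out / "tables" / "fermentation.tsv"))
        manifest["inputs"]["simulate"] = {
            "seed": sim.seed, "depth": sim.depth, "n_genera": sim.n_genera,
            "akp_peak_h": sim.akp_peak_h, "akp_strength": sim.akp_strength,
        }
        done("simulate")
    else:
        table = community_data.read_shared(config.shared_path)
        tax = (community_data.read_taxonomy(config.taxonomy_path)
               if config.taxonomy_path else None)
        meta = community_data.read_metadata(config.metadata_path)
        ferm = (fermentation_metrics.read_fermentation(config.fermentation_path)
                if config.fermentation_path else None)
        for key in ("shared_path", "taxonomy_path", "metadata_path",
                    "fermentation_path"):
            p = getattr(config, key)
            if p:
                manifest["inputs"][key] = _sha256(Path(p))

    # -- filter + rarefy ---------------------------------------------------
    stage("rarefy")
    table = community_data.filter_singletons(table)
    depth = min(config.rarefy_depth, int(table.library_sizes.min()))
    table = community_data.rarefy(table, depth, stage_rng(config.seed, "rarefy"))
    meta = community_data.SampleMetadata(
        meta.frame[meta.frame["sample_id"].isin(table.sample_ids)])
    community_data.write_shared(table, record(out / "tables" / "rarefied.shared"))
    manifest["stages"].setdefault("rarefy", {})
    done("rarefy")
    manifest["stages"]["rarefy"]["depth"] = depth

    # -- alpha -------------------------------------------------------------
    stage("alpha")
    alpha = alpha_diversity.alpha_table(table)
    alpha.to_csv(record(out / "stats" / "alpha.tsv"), sep="\t", index=False)
    done("alpha")

    # -- beta --------------------------------------------------------------
    stage("beta")
    dms: dict[str, community_data.DistanceMatrix] = {}
    for rank in config.ranks:
        dm = beta_diversity.pairwise_distances(table, metric=config.metric,
                                               tax=tax, rank=rank)
        dms[rank] = dm
        community_data.write_distance(
            dm, record(out / "distances" / f"{config.metric}_{rank}.dist"))
    dm_otu = beta_diversity.pairwise_distances(table, metric=config.amova_metric)
    community_data.write_distance(
        dm_otu, record(out / "distances" / f"{config.amova_metric}_otu.dist"))
    done("beta")

    # -- AMOVA / HOMOVA / PCoA --------------------------------------------
    stage("amova")
    meta_idx = meta.frame.set_index("sample_id")
    groups = {sid: str(meta_idx.loc[sid, "condition"]) for sid in dm_otu.ids}
    rng_amova = stage_rng(config.seed, "amova")
    rows = []
    res = community_stats.amova(dm_otu, groups, n_perm=config.n_perm,
                                seed=rng_amova)
    hom = community_stats.homova(dm_otu, groups, n_perm=config.n_perm,
                                 seed=stage_rng(config.seed, "homova"))
    rows.append(dict(scope="all-times", test="amova", stat=res.f_stat,
                     p_value=res.p_value, ss_among=res.ss_among,
                     ss_within=res.ss_within))
    rows.append(dict(scope="all-times", test="homova", stat=hom.b_stat,
                     p_value=hom.p_value, ss_among=np.nan, ss_within=np.nan))
    for t in sorted(meta.frame["time_h"].unique()):
        sids = meta.frame.loc[meta.frame["time_h"] == t, "sample_id"].tolist()
        sub = dm_otu.submatrix(sids)
        sub_groups = {s: groups[s] for s in sids}
        res_t = community_stats.amova(sub, sub_groups, n_perm=config.n_perm,
                                      seed=rng_amova)
        rows.append(dict(scope=f"t={t:g}h", test="amova", stat=res_t.f_stat,
                         p_value=res_t.p_value, ss_among=res_t.ss_among,
                         ss_within=res_t.ss_within))
    pd.DataFrame(rows).to_csv(record(out / "stats" / "amova_homova.tsv"),
                              sep="\t", index=False)
    pc = community_stats.pcoa(dm_otu)
    coords = pd.DataFrame(pc.coordinates[:, :4],
                          columns=[f"axis{i+1}" for i in range(
                              min(4, pc.coordinates.shape[1]))])
    coords.insert(0, "sample_id", dm_otu.ids)
    coords.to_csv(record(out / "stats" / "pcoa_coords.tsv"), sep="\t",
                  index=False)
    pd.DataFrame({"eigenvalue": pc.eigenvalues,
                  "pct_variance": np.concatenate(
                      [pc.pct_variance,
                       np.full(len(pc.eigenvalues) - len(pc.pct_variance),
                               np.nan)])}
                 ).to_csv(record(out / "stats" / "pcoa_eigen.tsv"),
                          sep="\t", index=False)
    done("amova")

    # -- trajectories ------------------------------------------------------
    stage("akh")
    inferences = akh_trajectory.multi_rank_akh(
        table, tax, meta, metric=config.metric, ranks=config.ranks,
        n_perm=config.n_perm, n_boot=config.n_boot,
        seed=stage_rng(config.seed, "akh"))
    akh_trajectory.slope_table(inferences).to_csv(
        record(out / "stats" / "akh_slopes.tsv"), sep="\t", index=False)
    for category in akh_trajectory.PAIR_CATEGORIES:
        series = akh_trajectory.build_pair_series(
            table, tax, meta, metric=config.metric, rank="genus",
            pair_category=category, dm=dms.get("genus"))
        series.points.to_csv(
            record(out / "figures-data" / f"pairs_{category}.tsv"),
            sep="\t", index=False)
    tt = akh_trajectory.build_pair_series(
        table, tax, meta, metric=config.metric, rank="genus",
        pair_category="treatment-treatment", dm=dms.get("genus"))
    peak = akh_trajectory.dispersion_peak_estimate(tt)
    manifest["stages"].setdefault("akh", {})
    done("akh")
    manifest["stages"]["akh"]["dispersion_peak_h"] = peak

    # -- fermentation ------------------------------------------------------
    if ferm is not None:
        stage("ferment")
        summary = fermentation_metrics.summarize_fermentation(
            ferm, n_perm=config.n_perm, seed=stage_rng(config.seed, "ferment"))
        summary["percent_reduction"] = [
            fermentation_metrics.percent_reduction(c, t) if c > 0 else np.nan
            for c, t in zip(summary["control_mean"], summary["treatment_mean"])]
        summary.to_csv(record(out / "stats" / "fermentation_summary.tsv"),
                       sep="\t", index=False)
        done("ferment")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
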