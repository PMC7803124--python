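#!/usr/bin/env python
"""Per-sample alpha diversity of the simulated communities.

Reads results/data/communities.shared, computes observed richness, Chao1,
Good's coverage, Shannon and inverse Simpson per sample, and a rarefaction
curve for the first sample. Writes results/alpha.tsv and
results/rarefaction.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rumenakp import alpha_diversity as ad
from rumenakp import community_data as cd

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    table = cd.read_shared(DATA / "communities.shared")
    alpha = ad.alpha_table(table)
    alpha.to_csv(OUT / "alpha.tsv", sep="\t", index=False)
    print(f"alpha diversity for {len(alpha)} samples -> results/alpha.tsv")
    print(alpha[["chao1", "goods_coverage", "shannon", "inv_simpson"]]
          .describe().loc[["mean", "std"]].round(3).to_string())

    counts = table.counts[0]
    depths = np.unique(np.geomspace(1, counts.sum(), 12).astype(int))
    curve = ad.rarefaction_curve(counts, depths, n_reps=100, seed=1)
    pd.DataFrame(curve, columns=["depth", "mean_s_obs", "sd"]).to_csv(
        OUT / "rarefaction.tsv", sep="\t", index=False)
    print(f"rarefaction curve for sample {table.sample_ids[0]} "
          "-> results/rarefaction.tsv")


if __name__ == "__main__":
    main()
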