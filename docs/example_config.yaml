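# Annotated pipeline configuration for `rumenakp run-all --config <file>`.
# Every field is optional; the values below are the defaults.

output_dir: results/run     # artifact directory: tables/, distances/, stats/, figures-data/
seed: 0                     # master seed; fans out to per-stage child seeds

# Simulate-mode input (remove this block and set the *_path fields below to
# analyse measured data instead).
simulate:
  n_vessels_per_condition: 3        # 3 control (C1..C3) + 3 treatment (T1..T3)
  timepoints_h: [4, 12, 24, 28, 36, 48, 52, 60, 72, 76, 84, 96]
  depth: 6467                       # reads per sample (also the rarefying depth)
  n_genera: 120
  base_concentration: 50.0          # Dirichlet concentration; smaller = noisier
  akp_peak_h: 72.0                  # treatment dispersion peaks here ...
  akp_strength: 4.0                 # ... with this concentration divisor
  methanogen_log2_depletion: 0.4    # treatment methanogen means x 2^-0.4
  methanogen_rel_abundance: 0.0179  # baseline Euryarchaeota share (1.79%)
  bf_drift_rate: 0.10               # shared Bacteroidetes->Firmicutes drift per day
  seed: 0

# File-mode input (used when `simulate` is absent):
# shared_path: data/communities.shared      # mothur .shared OTU table
# taxonomy_path: data/taxonomy.tsv          # otu_id <tab> k;p;c;o;f;g lineage
# metadata_path: data/metadata.tsv          # sample_id vessel condition day hours_post_feeding time_h
# fermentation_path: data/fermentation.tsv  # vessel condition day hours_post_feeding ch4 co2 total_gas + VFA columns

rarefy_depth: 6467          # samples below this library size are dropped
metric: bray_curtis         # trajectory metric: bray_curtis | jaccard | theta_yc
amova_metric: theta_yc      # distance used for AMOVA/HOMOVA/PCoA
ranks: [genus, family, order, class, phylum]
n_perm: 1000                # permutations for AMOVA/HOMOVA/slope tests
n_boot: 1000                # cluster-bootstrap resamples for slope CIs
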