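# Methods

This package analyses microbial community dynamics and fermentation output
of a semi-continuous in-vitro rumen system (RUSITEC): three control vessels
and three vessels amended with the red seaweed *Asparagopsis taxiformis*,
sampled 4, 12 and 24 h after feeding on each of four days (12 timepoints,
4–96 h since the start). Because the deposited sequence data are not needed
to validate the statistical machinery, every stage runs against a
synthetic-data generator with known, controllable structure; all inference
code is agnostic to the data's origin and accepts mothur-style `.shared`
tables, taxonomy TSVs and metadata TSVs.

## Community model

Counts are simulated per (vessel, timepoint) from a Dirichlet-multinomial
(DM) model:

    p ~ Dirichlet( c(t, condition) · μ(t, condition) ),
    x | p ~ Multinomial(depth, p),

with `depth = 6467` reads per sample (the rarefaction depth used downstream)
over 120 genera, each carrying a full six-rank lineage (genera grouped
three-per-family and two-families-per-order within phylum, so aggregation at
coarser ranks genuinely collapses columns). The DM was chosen as the minimal
overdispersed count model for 16S data; its mean equals μ exactly, which
gives closed-form oracles for every mean-abundance statistic.

The mean composition μ carries two effects:

* **Methanogen depletion.** Five methanogen genera (Methanobrevibacter,
  Methanosphaera, vadinCA11, Methanoplanus, Methanimicrococcus — the first
  two carrying >99% of the methanogen reads) sum to 1.79% relative abundance
  at baseline; under treatment their means are multiplied by
  2^(−`methanogen_log2_depletion`) (default 0.4, i.e. a treatment mean of
  ~1.36%) and the vector renormalised.
* **Shared Bacteroidetes:Firmicutes drift.** In both conditions,
  Bacteroidetes mass decays at `bf_drift_rate` = 0.1/day and is transferred
  to Firmicutes proportionally. The transfer formulation (rather than decay
  plus renormalisation) keeps the expected share of every other taxon —
  including the methanogens — exactly at its configured value, so mean
  effects stay separable from the drift. The default halves the B:F ratio
  over four days, a visually plausible magnitude for the reported decline;
  no measured value exists to calibrate against.

The concentration c carries the Anna-Karenina (dispersion) effect: for
treatment vessels the base concentration (default 50) is divided by a
tent-shaped multiplier of time that rises linearly from 1 at the first
sampling time to `akp_strength` = 4 at `akp_peak_h` = 72 h and falls
symmetrically afterwards. Dividing the concentration increases the scatter
of communities around an unchanged mean — stressors increase
between-replicate differentiation rather than shifting every community the
same way — so dispersion statistics can be validated against a known
planted effect without mean confounds.

Fermentation series are zero-truncated Gaussian draws per vessel/timepoint
around per-condition means: gas in ml/(g OM) with control/treatment means
12.08/0.59 (CH₄), 15.67/14.24 (CO₂), 28.54/14.81 (total), VFA in ppm
(acetate 1056.99/856.77, propionate 481.12/490.54, etc.). Published
summaries provide only a pooled SE per response; per-draw SDs are set to
SE·√3 (the per-vessel SD consistent with a 3-vessel SE), except the
treatment CH₄ SD (0.2), kept small relative to its mean so the
zero-truncation bias stays ≈1%. Total gas is drawn at its own configured
mean and clamped to ≥ CH₄ to keep the component/total invariant; the clamp
never binds at default parameters.

## Diversity and distances

α-diversity follows the mothur conventions: Shannon with the natural log,
inverse Simpson 1/Σp², Good's coverage 1−n₁/N, and the bias-corrected Chao1
`S_obs + n1(n1−1)/(2(n2+1))` — the corrected form is defined when a sample
has no doubletons, which matters at small fixture sizes. Rarefying and
rarefaction curves subsample without replacement (multivariate
hypergeometric), so repeated-draw expectations have closed forms used as
test oracles.

Pairwise dissimilarities are Bray-Curtis, Jaccard (presence/absence), and
the Yue-Clayton measure reported as a distance (1−θ_YC). Abundance-based
metrics are computed on per-sample relative abundances after rarefying to a
common depth; a raw-counts mode exists for sensitivity checks. Rank-level
distances aggregate counts to the requested rank first; unclassified
lineage tails propagate the nearest classified parent name so aggregation
is total at every rank.

## Distance-matrix inference

AMOVA partitions squared pairwise distances: SS_total = (1/N)Σ_{i<j}d²,
SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d², F = [SS_among/(k−1)]/[SS_within/(N−k)],
with significance by random relabeling of group membership. HOMOVA tests
equality of within-group dispersions SSw_g/(n_g−1) with a Bartlett-style
log-ratio statistic on the same decomposition. Sampled permutation p-values
use the add-one convention (b+1)/(n_perm+1), never zero; with
`n_perm="all"` every distinct relabeling is enumerated and the p-value is
exact (the observed labeling counts itself, so p ≥ 1/n_total).

A size caveat worth stating explicitly: with 3 vessels per condition there
are only C(6,3) = 20 relabelings, paired by the label-swap symmetry of
|effect|, so the smallest attainable two-sided p is 0.1. Per-timepoint
AMOVA and the vessel contrast at the study size are therefore floored at
p = 0.1; calibration of the procedures is checked at 6v6 samples (AMOVA,
HOMOVA) and 5v5 vessels (contrast), where the 5% level is attainable.

PCoA double-centers −d²/2 (Gower) and eigendecomposes; coordinates are
returned for positive eigenvalues and scaled so Euclidean-embeddable inputs
are reproduced exactly. Negative eigenvalues of non-Euclidean Bray-Curtis /
θ_YC matrices are reported but excluded from the percent-variance
denominator; no Lingoes/Cailliez correction is applied.

## Trajectory inference

Between-vessel series pair distinct vessels of the required conditions at
identical nominal times (no interpolation); within-vessel series pair a
vessel's samples at distinct times and regress on the lag |t_a−t_b|. Slopes
are ordinary least squares; each (rank × pair-category) cell of the grid is
fit separately.

**Permutation unit.** Points are dependent wherever they share a sample:
d(A_t,B_t) and d(A_t,C_t) share vessel A's sample at t. Shuffling time
labels independently within each vessel pair's sub-series destroys that
cross-pair dependence and was measured anticonservative (type-I ≈ 0.11 at
nominal 0.05). The test therefore permutes time labels at the sample level:
between-vessel series receive one shared permutation of the sampling times
per iteration (whole time cross-sections move together), within-vessel
series an independent permutation per vessel with lags recomputed. Both
schemes are exact under exchangeability of the time cross-sections and are
measured to hold the 5% level. Tests are two-sided on |slope|; `n_perm="all"`
enumerates.

**Bootstrap unit.** 95% CIs come from a percentile cluster bootstrap that
resamples vessel pairs with replacement (all points of a resampled pair
enter the refit). Percentile intervals undercover somewhat at very small
cluster counts (measured ≈0.93–0.94 at 20–40 clusters, the usual
small-sample percentile behaviour); with the study's 3 pairs per category
the CI should be read as descriptive.

The dispersion peak is the time maximising a 24 h (one feeding cycle)
centered moving average of the per-time mean treatment-treatment
dissimilarity; ties break to the earliest time, and a monotone series
yields the last timepoint.

## Fermentation statistics

Treatment effects on gas/VFA responses use a vessel-level permutation
contrast: per-vessel averages are the exchangeable units, the statistic is
the difference of condition means, and labels are permuted across vessels
(exhaustively whenever feasible). This is an assumption-light substitute
for a repeated-measures mixed model, exact at small vessel counts; it is a
methodological substitution, not a reproduction of a REML fit. The
propionate:acetate ratio is computed per record and averaged within
condition — the ratio of the group means (0.455 for the control means
481.12/1056.99) differs from the mean of ratios and is not the reported
statistic. Percent reduction is 100·(control−treatment)/control; for total
gas the configured means give 48.1%, and the package makes no attempt to
reproduce a published "51.8%" figure that is inconsistent with its own
group means. Summaries report per-group SEs and a pooled SE side by side
since published tables often print a single pooled value without defining
it.

## Reproducibility and numerics

A single run seed fans out to per-stage child generators through
`numpy.random.SeedSequence` spawn keys, so stages can be rerun in isolation
and a full pipeline run is bit-reproducible from its manifest (input
hashes, per-stage seeds, every output path). Permutation statistics compare
with a 1e-12 slack so exact ties (the identity relabeling) count as
exceedances on every platform. Degenerate inputs fail fast: zero-total
samples, singleton groups, all-equal times, a single vessel pair for the
cluster bootstrap.

Problem sizes in the test-suite simulations (replicate counts of 100–500,
reduced depths/genus counts for null calibration) were chosen to keep
Monte-Carlo error well inside the asserted bands while the whole suite
stays inexpensive on a single CPU; the analysis scripts run the full
default configuration.

## What the generator does and does not emulate

Emulated: the 6-vessel × 12-timepoint design, rarefied library sizes, a
genus→phylum taxonomy containing the five named methanogen genera at a
realistic baseline, treatment-dependent community dispersion peaking near
72 h with reconvergence, methanogen depletion, a shared B:F drift, and
gas/VFA series with strong CH₄ suppression at roughly unchanged total VFA.

Not emulated, hence not demonstrated by passing tests:

* **Within-vessel temporal autocorrelation.** Timepoints are conditionally
  independent given the mean/dispersion trajectories. Consequently the
  generator reproduces the rise-and-fall of between-vessel treatment
  dissimilarity, but *not* the observation that within-vessel dissimilarity
  grows with time lag most strongly in treatment vessels: that pattern is
  the signature of persistent (autocorrelated) per-vessel drift. Under this
  generator the expected treatment lag-slope is slightly negative (the
  dispersion hump elevates mid-lag pairs more than maximum-lag pairs) while
  the control lag-slope is positive via the shared drift. The
  corresponding acceptance check is expected to fail for treatment vessels
  and documents this limitation rather than masking it.
* Mechanistic fermentation chemistry (bromoform kinetics, H₂ balance,
  VFA–gas stoichiometry): gas and VFA responses are drawn independently.
* Protozoa and any taxa outside the 16S assay; washout effects enter only
  implicitly through the shared drift.
* Real sequencing artifacts: chimeras, contamination, variable library
  sizes (all samples are generated exactly at the rarefaction depth), or
  realistic OTU richness (the generator works at genus resolution, so
  observed richness and coverage are far from amplicon-survey values).
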