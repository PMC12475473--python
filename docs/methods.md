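# Methods

This note documents the models, defaults and numerical choices behind
`striaging`, and what the synthetic-data tests do and do not establish
about real data.

## Synthetic data generator

The generator (`striaging.simulate`) draws a two-age spatial single-cell
dataset from an explicit generative model; its defaults are the study
conditions every statistical claim in the test suite refers to.

**Counts.** Gene *g* in cell *c* is negative binomial via the
gamma–Poisson mixture: `x_cg ~ Poisson(Gamma(r, c_i·µ_g/r))` with
dispersion `r = nb_dispersion = 2`. Gene base means `µ_g` are lognormal
around `nb_mean = 0.8` counts (log-sd 1), so the panel spans expression
strata — required for the expression-matched control binning to be
meaningful. The per-cell capture factor `c_i` is lognormal with log-sd
`detection_noise_sd = 0.3`; it multiplies every gene of the cell and is the
mechanism producing the detection-rate variation the hurdle DE adjusts
for. Marker genes of a cell's subtype are elevated `2^marker_log2fc`
(default 4×, 10 disjoint markers per subtype); in aged cells the 20
aging-program genes are elevated `2^aging_log2fc` (default 2×).
Aging-program base means are floored at `nb_mean`: a program is called on
genes the assay robustly detects, and a two-fold change on a gene with
near-zero expression is unidentifiable at any realistic cell number.
Markers are *not* floored — their background detection must stay low for
the in/out ratio criterion to be exercised realistically.

**Space.** Only the dorsal-ventral axis carries signal. Each cell's bin is
multinomial with subtype-and-age-specific weights over six 500 µm bins
(Gaussian bumps whose centers walk dorsal→ventral across subtypes);
y is uniform within the bin and x uniform across a 1 mm width. In the
default aged condition subtype A1 expands by ~10 percentage points and
its peak moves one bin dorsally — a deliberately mild effect. The
dedicated parameter-recovery scenario (`SimulationConfig.dorsal_shift`)
instead moves one mid-tissue subtype two bins dorsally; that magnitude was
chosen from the analytic expected profile difference (≈ 0.3–0.4 per bin,
far above multinomial noise at 2000 cells/age), so sign recovery is a
property of the estimator, not luck.

**Other attributes.** 7 subtypes with mildly decreasing abundances, 4
animals per age group (cells assigned uniformly), cell volumes lognormal
around 100 µm³ (log-sd 0.35, putting a small tail under the 50 µm³
filter), 5 mitochondrial genes (`mt-` prefix) and ~2% of cells with 25×
inflated mitochondrial load so the droplet QC path is exercised. All
randomness flows from one integer seed through a single generator.

**What the generator does not emulate:** segmentation errors, doublets,
ambient RNA, batch structure between animals, 2-D spatial texture,
gene–gene correlation beyond the planted programs, and platform-specific
noise (optical crowding, probe efficiency). Tests passing on this
generator show the estimators are correct and calibrated under the stated
model — not that the model captures every failure mode of real tissue.

## QC and normalization

Droplet filters: cells with ≥ 300 detected genes and mitochondrial
percentage ≤ 20%; afterwards genes detected in > 3 of the retained cells
(cell filter first, so gene prevalence reflects surviving cells). MERFISH
filters: ≥ 10 detected genes and volume ≥ 50 µm³; no gene filter is
applied on MERFISH panels (they are curated, and prevalence filtering a
few-hundred-gene panel would remove designed content). Boundaries are
taken literally: ≥ 300, > 3, < 10 removes, < 50 removes.

Normalization is `ln(1 + s · x_cg / T_c)` with `s = 10,000` and `T_c` the
cell's total counts. The volume-normalized MERFISH variant divides both
counts and totals by cell volume, which cancels algebraically; the flag is
honoured (and validated) for interface fidelity. Zero-total cells stay
all-zero with a logged warning. Both filters are idempotent and the
normalization is invariant to per-cell count scaling.

## Clustering and age dominance

Per-gene z-scoring capped at ±10, PCA (top 30 components, exact SVD for
determinism), a k = 20 nearest-neighbor graph converted to a shared
nearest-neighbor graph with Jaccard edge weights (self counted, weights
below 1/15 pruned — the Seurat convention), and Leiden optimization of
RB-configuration modularity. Resolution defaults: 0.08 for tier 1, 0.10
for tier-2 subclustering within one cell class (tier-2 never touches
tier-1 labels; classes under 20 cells are refused). Cross-sample
integration is deliberately not performed: the pipeline clusters the
pooled normalized matrix, which is the right null for simulated data
without batch structure and keeps the clustering stage self-contained.

Dominance: a cluster with aged fraction strictly above 0.70 is "aged",
young fraction strictly above 0.70 "young", otherwise "common"; ties and
the exact threshold resolve to common. At n = 1000 under random labels
the probability of a spurious dominance call is negligible (binomial tail
beyond 70% at p = ½).

## Hurdle differential expression

For each gene, detection `z = [x > 0]` follows a logistic regression on
group and centered CDR, and log-normalized expression among detected cells
follows a Gaussian linear model on the same design. The group term is
tested in each part by a likelihood ratio; under the hurdle factorization
the two statistics are independent and add to a χ² with df = 2 (df = 1
when a part is degenerate — constant detection or too few detected cells;
df = 0 genes are flagged with p = 1 and log2fc = 0). The logistic MLE is
found by Newton-IRLS with a 1e-8 ridge for separation safety (verified
against `statsmodels.Logit` to 1e-6); the Gaussian LRT is
`n · ln(RSS_reduced / RSS_full)` from closed-form least squares.

Conventions fixed because tools differ: `log2fc` is the difference of
group means of log2-scale normalized expression *including zeros*;
detection percentages `pct_in`/`pct_out` are per-group nonzero fractions;
the marker ratio is `pct_in / pct_out` with add-one smoothing
`pct_out → 1/(n_out + 1)` when zero; the ratio threshold is inclusive
(≥ 2); aging DEGs require |log2FC| strictly > 0.25 and FDR < 0.05;
"top" lists rank by FDR with ties broken by effect size. BH-FDR is the
standard step-up with running-minimum monotonicity, checked exactly
against an independent implementation.

Null calibration (1000 genes, 200 + 200 cells) gives empirical type-I
error near 0.05 across seeds; a planted two-fold change at typical
expression is recovered for ≳ 90% of genes at FDR < 0.05 at that sample
size.

## Regional expression probability

Bins are half-open, `[origin + i·h, origin + (i+1)·h)`, h = 500 µm, six
bins, y increasing ventrally from a caller-supplied dorsal origin; cells
outside are flagged and excluded. The raw statistic divides the subtype's
share of bin-*y* cells by the subtype total; because that quantity has no
fixed normalization, the default *renormalized* mode rescales each
subtype's bin shares to sum to 1, making `P[a,·]` a probability profile
over the axis. This is invariant to overall subtype abundance and to
per-bin density by construction (verified by rescaling experiments), which
is precisely the point of the statistic. The *literal* mode (divide by the
subtype total) is retained for fidelity to the raw definition. Empty bins
contribute share 0 with a warning.

Note an intrinsic subtlety confirmed analytically in the tests: because a
shifting subtype changes the bin totals it is measured against, the
renormalized profile difference understates very small shifts of abundant
subtypes; it is faithful in sign and rank for shifts at or above one bin.

The age×subregion test computes Type II F statistics from nested
least-squares fits on per-sample profiles (verified against
`statsmodels.anova_lm`), with a label-permutation p-value for the
interaction (999 permutations by default) as the primary inference —
repeated-measures ANOVA assumptions are unverifiable at 4–5 animals per
group, so the F is reported but the permutation p decides. When every SS
is rounding noise (exactly replicated profiles) the F is defined as 0.

## Aging module score

Genes are cut into 24 equal-frequency strata by dataset-average
expression (rank-based, like `ntile`); for each program gene, 100 control
genes are sampled from its stratum (program genes excluded, without
replacement; with replacement with a warning when the stratum is small —
common on a few-hundred-gene panel, where strata hold ~10 genes). Controls
are pooled and de-duplicated; the score is the program mean minus the
pooled-control mean per cell. A constant matrix scores exactly 0; the
score is deterministic given the seed and equivariant under cell
permutation. The stratum count (24) and pooling behavior follow the
standard module-score implementation this statistic mirrors; only the
control count (100) is an explicit analysis parameter.

## Detection power

For each target size, cells are subsampled without replacement and
re-clustered from scratch with the tier-1 parameters; a reference subtype
(from full-data clustering or planted truth — never re-derived per
replicate) is detected when some cluster reaches Jaccard ≥ 0.5 with its
subsampled members. Defaults: 20 replicates per size; sizes below the
neighborhood size are skipped. The Jaccard criterion is the simplest
label-free definition of "the subcluster was found"; 0.5 requires the
matching cluster to be mostly that subtype and to contain most of it.

## Set operations

Every element of the union is assigned to its exact membership pattern, so
region counts partition the union; Venn counts and UpSet exclusive
intersections are the same partition presented differently. Symbols are
upper-cased by default so mouse and human lists compare directly;
within-list duplicates are dropped with a warning. The four-way
cross-condition comparison in the acceptance suite uses a synthetic
stand-in collection (`synthetic_cross_dataset_lists`) constructed so the
all-four exclusive intersection is exactly {CD44, EGFR}; it exercises the
machinery at realistic list sizes and is labelled synthetic wherever it
appears.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make each
statistical property measurable with margin: 400–2000 cells per age group,
120–250 genes, 1000-gene DE calibrations over 10 seeds, 10–20 power
replicates over 3–4 subsample sizes, 10,000 BH vectors and 1,000 random
set collections for the exact-agreement checks. The full suite runs in
well under a minute of compute for any single module and a few minutes in
total.

## Known limitations

- No batch/animal random effects anywhere downstream of the generator;
  per-sample structure enters only through the profile permutation test.
- The hurdle model assumes the Gaussian part on log-normalized expression;
  heavy-tailed genes can be anti-conservative at very low detection.
- The renormalized spatial profile attenuates sub-bin shifts of dominant
  subtypes (see above).
- CSV orientation detection relies on the index header name; ambiguous
  headers default to genes × cells.
- Clustering determinism is guaranteed for a fixed seed, BLAS and package
  versions; across versions labels may permute.
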