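# Methods

This note documents the models, parameter choices and numerical conventions
behind `transcohort`, and what the synthetic-data tests do and do not show
about real data.

## Synthetic two-cohort generator

The generator emulates a paired profiling study: two cohorts measured on
the same platform under identical conditions, so that the only systematic
cohort difference is the (optional) additive `batch_shift`.

**Modules.** Each planted co-expression module follows a single-latent-
factor model: gene `g` in module `M` is `x_g = λ·f + σ·ε`, with one factor
draw `f ~ N(0,1)` per cohort, loading `λ = latent_loading` and noise
`σ = noise_sd`. The implied within-module pairwise Pearson correlation is
`λ²/(λ² + σ²)`; with the defaults `λ = 0.9`, `σ = 0.5` this is 0.764, i.e.
comfortably above the gene dendrogram cut of 0.6 but not degenerate.
Shared modules keep identical membership across cohorts with independent
factor draws; private modules exist only in cohort A and are the designed
reason validated fractions sit below 1 (10 shared + 2 private defaults give
an expected planted fraction of 10/12). The two largest default modules are
*subtype-linked*: half the factor variance is a standardized ER-status or
proliferation covariate, mirroring the ER and proliferation-related
co-expression clusters of breast tumors. This matters for subclass mapping:
with it, subtype marker lists contain dozens of genuinely informative genes
rather than only the 45-gene panel, which is what real tumor data look
like. The linkage leaves the within-module correlation unchanged because
the factor keeps unit variance.

**Subtypes and markers.** Sample labels are drawn from
`subtype_mixture` (defaults 0.35/0.25/0.20/0.20 for LumA/LumB/ERBB2/Basal,
i.e. a luminal-A-depleted mixture typical of younger-onset series). Panel
genes receive an additive centroid of amplitude `subtype_separation/2`
(default separation 2 log2 units) following the canonical block structure:
luminal A = luminal-high/proliferation-low, luminal B = luminal-high/
proliferation-high, HER2-enriched = amplicon-high/basal-low, basal-like =
luminal-low/proliferation-high/basal-high. ESR1 and ERBB2 are excluded
from the centroid and instead given explicitly bimodal distributions: ER-
positive (luminal) samples sit `marker_separation` (default 4) log2 units
above the gene's baseline, so the true threshold is baseline + separation/2
and is recorded in the ground truth. A small fraction (15%) of basal-like
samples lose the epithelial claudin/E-cadherin block and gain the
mesenchymal block — the claudin-low stand-ins.

**ECM blocks, storage, miRNAs.** Two disjoint gene×sample blocks receive
an additive shift (defaults 25×25 and 20×20 at +2): the ECM3 rows carry
collagen/stromal seed symbols and draw their sample columns preferentially
from ER-positive samples; ECM1 rows carry immune/protease seed symbols and
ER-negative columns. Six genes (0.3% of the default 2,000) depend linearly
on a per-sample storage-hours covariate (U(1,4) h, slope 0.5/h). The miRNA
matrices get their own modules plus three 12-member subtype-tracking groups,
so that miRNA-space PCA separates subtypes better than cohorts when no
batch shift is planted.

**What the generator does not emulate:** probe-level bead structure, dye or
spatial artifacts, heavy-tailed or intensity-dependent noise, correlated
(non-block) covariance beyond single factors, missing values, and outlier
samples. Passing tests therefore demonstrate algorithmic correctness and
calibration under a clean Gaussian world, not robustness to array-level
artifacts.

## Preprocessing

Fixed order: log2 (applied with a warning only when values exceed 30) →
quantile normalization → detection filter (p < 0.01 in ≥ 1 sample) →
probe collapse (highest detection rate, ties by larger IQR, then smallest
probe id). Quantile normalization replaces the bead platform's
spline-based normalization: both align full per-sample distributions, and
quantile normalization is exactly specifiable and idempotent (verified to
1e-12). Quartiles everywhere use linear interpolation between order
statistics (NumPy's default); this is stated because IQR thresholds (0.4
for clustering input) are decision boundaries — under this rule the vector
{0,0,0,1,1,1} has IQR exactly 1. The IQR filter uses a strict `>`.

## Cluster conservation

Discovery: average linkage on `1 − r`, cut at `1 − corr_cut`, keep groups
≥ `min_size`, ids `C1, C2, …` by descending size (ties by smallest member)
for determinism. Validation re-clusters only the cluster's members in the
second cohort at the same cut and counts the largest group formed; ≥ 3
confirms. Among readings of "at least three members re-correlate", the
largest-co-clustered-group rule was chosen because it is the direct
dendrogram analogue of the discovery rule; counting members with any
pairwise r above the cut would validate more liberally. Only the largest
group counts when a cluster splits. The enrichment universe is the
IQR-filtered feature set of the seed cohort, since that is the population
that was clustered. Under the independence null (1,000 features, n = 100,
200 replicates) the spurious validation rate of random 10-member clusters
is ≤ 5%.

## Subtyping

The bimodal threshold uses a Gaussian KDE (Scott bandwidth) on a 512-point
grid spanning the data range ± 1 bandwidth; turning points are sign changes
of successive density differences; the threshold is the deepest minimum
between the two highest maxima, and a unimodal density raises an error
naming the gene. At n = 400 the threshold lands within ±0.5 of the analytic
minimum of a 0.6/0.4 two-Gaussian mixture.

Intrinsic assignment clusters samples (average linkage, Euclidean) on the
median-centered panel and cuts at k = 6 groups; each group of ≥ 3 samples
is named by the majority of per-sample Spearman matches against bundled
centroid patterns, requiring a median correlation ≥ 0.1; smaller or poorly
matching groups stay Unclassified. The bundled centroid file is a
synthetic ±1 block-pattern stand-in (see its docstring), not published
numeric centroids; rank-based matching makes the calls depend only on the
pattern ordering. Centroid rows are median-centered across subtypes before
matching so that data and centroids are compared as like-for-like
deviations — without this, groups whose population median absorbs part of
the pattern (e.g. HER2-enriched vs basal-like) are systematically
misassigned. k, the group-size floor and the correlation floor are
configuration keys.

Frequency tables use round-half-up integer percentages, and the luminal
A/B ratio is the ratio of the *rounded* percentages to two decimals (21
and 23 of 78 → 27%/29% → 0.93, not the raw 0.91); this is the convention
that reproduces the published cohort tables.

## LAS biclustering

The score `−[log C(m,k) + log C(n,l) + log Φ(−τ√(kl))]` is computed with
log-gamma binomials and `norm.logsf` (asymptotic expansion for large
arguments); it matches a 50-digit arbitrary-precision oracle to < 1e-6.
The search alternates row and column updates (sort by means, take the
score-maximizing prefix) from random column starts to a fixed point; the
best of `n_restarts = 20` starts is kept, its submatrix mean subtracted,
and up to 5 biclusters extracted, stopping when the best score falls below
that of a single cell at τ = 3. Genes are mean-centered before the global
z-scoring: without baseline removal the search finds high-intensity rows
rather than high-deviation blocks. ECM1/ECM3 labels require hypergeometric
seed overlap at p < 0.01; stability is the mean pairwise Jaccard of the
target cluster's gene set over 20 seeded re-runs with a 0.6 floor — a
concrete protocol standing in for externally described stability
statistics.

## Subclass mapping

Marker ranking uses SNR `(μ_in − μ_out)/(σ_in + σ_out)` with each σ floored
at `0.2·|μ|`; marker sets are the top 50. Enrichment is the weighted KS
running-sum score. Two nulls coexist deliberately:

* `enrichment_pvalue` permutes *gene-set membership* — the correct null
  for "is this fixed gene set enriched in this fixed ranking", and it is
  calibrated for random marker sets.
* `submap` permutes *sample labels of dataset B* — one ensemble per run;
  the forward test rebuilds the B ranking per permutation, the reverse test
  rebuilds the B marker set per permutation. This is essential: a random
  grouping of structured data inherits real signal through chance group
  composition, so the gene-permutation null declares permuted-label runs
  significant essentially always, while the label-permutation null is
  calibrated (0–1 of 20 permuted-label replicates show any cell at
  FDR < 0.05).

The two direction p-values share the permutation ensemble and are strongly
dependent, so the default per-cell combination is the intersection–union
rule `p = max(p_fwd, p_rev)` — a valid level-α test under arbitrary
dependence — with Fisher's chi-square combination available as an option
(it is anti-conservative here). FDR is Benjamini–Hochberg across cells.
With 500 permutations the smallest achievable cell p is 1/501, which still
drives identity diagonals to FDR < 0.01 while off-diagonal cells stay
above 0.05.

## Differential expression and cohort statistics

Per-feature OLS against intercept + ethnicity + subtype dummies, vectorized
across features; contrasts are the ethnicity coefficient and all pairwise
subtype differences, each with an unmoderated t (no empirical-Bayes
variance shrinkage — with ~200 samples the moderation would move only
borderline calls, and plain OLS keeps the estimator fully specified).
Unclassified samples are excluded from the subtype covariate by default
(toggle available). Significance: BH-FDR < 0.05 within contrast and
|log2FC| ≥ 1, with the union rule over subtype contrasts; boundary
semantics are ≥ for fold change and < for FDR. The storage screen is a
per-feature simple regression on hours, flagged at nominal p < 0.001.

2×2 chi-square applies the Yates correction by default — the convention
that reproduces the published cohort-table p-values (0.162, 0.780) — with
a flag to disable; Fisher's two-sided p sums the probabilities of tables
no more probable than the observed. Cohen's κ is computed from the k×k
table; partial correlation residualizes both variables on the covariates
and uses a t reference with df = n − #covariates − 2.

## Problem sizes

The default study conditions are 100 samples per cohort, 2,000 genes and
300 miRNAs, 12 gene modules (10 shared), 500 label permutations for
subclass mapping (300 inside replicate loops), 200 replicates for the null
spurious-validation rate, 20 permuted-label subclass-mapping replicates,
20 LAS restarts and 6 stability re-runs. These sizes keep the full test
suite and the acceptance script to a few minutes on one CPU while leaving
every Monte-Carlo margin comfortably away from its threshold.

## Known limitations

* The centroid patterns and the claudin-low/ECM panels are synthetic
  stand-ins with real gene symbols; on real data users should substitute
  published centroid/signature files via the corresponding arguments.
* Quantile normalization, not spline-based normalization; plain OLS, not
  moderated t — both substitutions are logged and affect borderline calls
  only.
* The subclass-mapping transpose property holds approximately: with small
  subclasses (~20 samples) one borderline diagonal cell can flip decision
  between A→B and B→A runs.
* The generator's Gaussian, block-structured world understates the tail
  behavior and annotation noise of real arrays; accession-scale claims
  require the optional GEO reproduction script.
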