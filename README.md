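# transcohort

A tested Python pipeline for comparing the breast-cancer transcriptomes of
two patient cohorts profiled on the same platform — for example a Chinese
and a Caucasian consecutive series — and asking whether the two share the
same transcriptional architecture even when subtype prevalences differ.

It is aimed at computational biologists running cross-cohort (transethnic
or cross-site) expression studies: the pipeline covers microarray-style
preprocessing, conservation of co-expression modules across cohorts,
molecular subtyping, subtype-correspondence testing, differential
expression, and the clinical contingency statistics such studies report.

## What it computes

**Cluster conservation.** Genes with IQR > 0.4 are clustered by
average-linkage hierarchical clustering on distance `d = 1 − r` (Pearson);
the tree is cut at `1 − 0.6` and groups of ≥ 10 genes kept (miRNAs: cut
0.4, ≥ 5 members). Each cluster is re-clustered in the second cohort: it is
*validated* when its largest co-clustered subgroup there still has ≥ 3
members. Conservation is summarized as the validated fraction and the
Pearson correlation between seed and confirmed cluster sizes; cluster
content is annotated by hypergeometric over-representation of gene lists.

**Molecular subtyping.** ER and ERBB2 expression status is called per
sample at the local minimum between the two dominant modes of the gene's
kernel density estimate. Intrinsic subtypes (luminal A/B, HER2-enriched,
basal-like) come from average-linkage/Euclidean clustering of samples on
the 45 usable PAM50 genes, with groups named by rank-correlation to bundled
centroid patterns; unclassified samples can be rescued into the claudin-low
class on a claudin/E-cadherin–low, EMT-high panel. Clinical surrogate
classes follow the standard ER/PR/HER2 immunohistochemistry rules.

**ECM biclustering.** Large-Average-Submatrices (LAS) search over
extracellular-matrix genes, scoring a k×l submatrix of an m×n matrix with
mean τ as

```
score = −[ log C(m,k) + log C(n,l) + log Φ(−τ·√(k·l)) ]
```

computed in log space. Returned biclusters are labeled ECM1
(immune/protease) or ECM3 (collagen/stromal) by overlap with seed gene
lists, with run-to-run stability measured by gene-set Jaccard across seeds.

**Subclass mapping.** Whether subtypes found independently in two datasets
correspond: each subtype's top SNR marker genes are tested for weighted
Kolmogorov–Smirnov enrichment at the top of the other dataset's
subtype-vs-rest ranking, with significance from sample-label permutations,
per-cell combination of the two directions, and Benjamini–Hochberg FDR
across cells.

**Differential expression and cohort statistics.** Per-gene OLS with
ethnicity and subtype covariates (significant: FDR < 0.05 and |log2FC| ≥
1), a storage-time screen at nominal p < 0.001, chi-square (Yates for 2×2)
and Fisher exact contingency tests, Cohen's κ, partial correlation, and
round-half-up percentage/ratio arithmetic for cohort tables.

A synthetic two-cohort generator (`transcohort.synthetic`) plants all of
this structure — correlated modules, subtype centroids, bimodal markers,
ECM blocks, storage effects — with recoverable ground truth, so every stage
is tested end-to-end against known answers.

## Worked example

```python
from transcohort import (SimulationConfig, generate_cohort_pair,
                         discover_clusters, validate_cluster,
                         assign_intrinsic_subtypes)
from transcohort.clusters import conservation_summary
from transcohort.preprocess import iqr_filter

cfg = SimulationConfig(seed=1)            # two cohorts, 100 samples each
ds_a, ds_b, truth = generate_cohort_pair(cfg)

fa = iqr_filter(ds_a, 0.4)
fb = ds_b.subset_features(fa.feature_ids)
clusters = discover_clusters(fa, corr_cut=0.6, min_size=10)
pairs = [(c, validate_cluster(c, fb)) for c in clusters]
print(conservation_summary(pairs))
# {'n_discovered': 16, 'n_validated': 14, 'fraction': 0.875,
#  'size_pearson_r': 0.9999999999999999}

calls = assign_intrinsic_subtypes(ds_a)
lab = {c.sample_id: c.intrinsic for c in calls}
t = truth.subtype_labels["A"]
print(sum(lab[s] == t[s] for s in t) / len(t))
# 0.98
```

16 clusters are discovered (the 12 planted modules plus the ER,
proliferation and ECM structure the generator also plants); the 14
validated ones are exactly those with a counterpart in the second cohort —
the two cohort-private modules fail validation, as they should. Seed and
confirmed cluster sizes correlate at r ≈ 1, and intrinsic subtype calls
agree with the planted labels for 98 of 100 samples.

The same stages are available from the shell:

```bash
transcohort simulate --out fixture/ --seed 1
transcohort clusters --a fixture/gene_A_expression.tsv \
                     --b fixture/gene_B_expression.tsv --out out/
transcohort subtypes --expression fixture/gene_A_expression.tsv --out out/
```

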