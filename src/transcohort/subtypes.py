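"""Molecular subtyping: bimodal marker thresholds, intrinsic-subtype
assignment by hierarchical clustering on the PAM50-usable panel,
claudin-low rescue of unclassified samples, clinical IHC surrogate
classes, and subtype frequency tables.

ER and ERBB2 expression status is called per sample against a threshold
placed at the local minimum between the two dominant modes of the gene's
kernel density estimate.  Intrinsic subtypes come from cutting an
average-linkage / Euclidean dendrogram of samples over the panel genes
(rows median-centered) into k groups; each group is then named by the
majority of per-sample rank-correlation matches against bundled subtype
centroid patterns, with small or poorly matching groups left Unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import gaussian_kde, spearmanr

from .datasets import ExpressionDataset, GeneSet, TranscohortError
from . import panels

__all__ = [
    "BimodalThreshold",
    "SubtypeCall",
    "NonBimodalError",
    "bimodal_threshold",
    "classify_marker_status",
    "assign_intrinsic_subtypes",
    "assign_claudin_low",
    "ihc_subtype",
    "frequency_table",
    "pca_group_separation",
    "round_half_up_pct",
]

INTRINSIC_LABELS = ("LumA", "LumB", "ERBB2", "Basal", "ClaudinLow", "Unclassified")


class NonBimodalError(TranscohortError):
    """Raised when a marker gene's density has no interior minimum."""


@dataclass(frozen=True)
class BimodalThreshold:
    gene: str
    threshold: float
    density_minima: tuple[float, ...]
    bandwidth: float


@dataclass
class SubtypeCall:
    sample_id: str
    intrinsic: str = "Unclassified"
    er_expr: bool | None = None
    erbb2_expr: bool | None = None
    ihc_class: str | None = None


def bimodal_threshold(values, gene: str = "") -> BimodalThreshold:
    """Threshold at the density minimum between the two dominant modes.

    A Gaussian KDE is evaluated on a 512-point grid spanning the data range
    extended by one bandwidth on each side; turning points are sign changes
    of successive density differences.  The threshold is the deepest local
    minimum lying between the two highest maxima.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise TranscohortError(f"{gene}: need >=20 values for density estimation")
    if np.std(x) == 0:
        raise TranscohortError(f"{gene}: constant values")
    kde = gaussian_kde(x)
    bw = float(kde.factor * np.std(x, ddof=1))
    grid = np.linspace(x.min() - bw, x.max() + bw, 512)
    dens = kde(grid)
    diff = np.sign(np.diff(dens))
    # indices of interior turning points
    turns = np.flatnonzero(diff[:-1] != diff[1:]) + 1
    maxima = [i for i in turns if diff[i - 1] > 0 and diff[i] < 0]
    minima = [i for i in turns if diff[i - 1] < 0 and diff[i] > 0]
    if len(maxima) < 2 or not minima:
        raise NonBimodalError(f"{gene or 'gene'}: density is not bimodal")
    top2 = sorted(sorted(maxima, key=lambda i: -dens[i])[:2])
    between = [i for i in minima if top2[0] < i < top2[1]]
    if not between:
        raise NonBimodalError(f"{gene or 'gene'}: no minimum between dominant modes")
    pit = min(between, key=lambda i: dens[i])
    return BimodalThreshold(
        gene=gene,
        threshold=float(grid[pit]),
        density_minima=tuple(float(grid[i]) for i in minima),
        bandwidth=bw,
    )


def classify_marker_status(ds: ExpressionDataset, gene: str) -> pd.Series:
    """Per-sample positive/negative expression call for one marker gene."""
    if gene not in ds.values.index:
        raise TranscohortError(f"marker gene {gene!r} not in dataset")
    vals = ds.values.loc[gene]
    th = bimodal_threshold(vals.to_numpy(), gene=gene)
    return vals > th.threshold


def _centroid_label(sample_vec: pd.Series, centroids: pd.DataFrame):
    """Best-matching subtype and its Spearman correlation for one sample."""
    best, best_r = None, -np.inf
    for subtype in centroids.columns:
        r = spearmanr(sample_vec.to_numpy(), centroids[subtype].to_numpy())[0]
        if np.isnan(r):
            continue
        if r > best_r:
            best, best_r = subtype, float(r)
    return best, best_r


def assign_intrinsic_subtypes(
    ds: ExpressionDataset,
    pam50_panel: GeneSet | None = None,
    centroids: pd.DataFrame | None = None,
    k: int = 6,
    min_group: int = 3,
    min_corr: float = 0.1,
    min_panel_coverage: float = 0.6,
) -> list[SubtypeCall]:
    """Assign intrinsic subtypes by panel-gene hierarchical clustering.

    Samples are clustered (average linkage, Euclidean distance) on the
    median-centered panel genes and the tree is cut into ``k`` groups; each
    group is labeled by the majority of per-sample nearest-centroid matches
    (Spearman) against the bundled centroid patterns.  Groups smaller than
    ``min_group`` or whose majority correlation falls below ``min_corr``
    stay Unclassified.
    """
    panel = pam50_panel or panels.pam50_panel()
    present = [g for g in sorted(panel.members) if g in ds.values.index]
    coverage = len(present) / len(panel.members)
    if coverage < min_panel_coverage:
        missing = sorted(panel.members - set(present))
        raise TranscohortError(
            f"panel coverage {coverage:.0%} below floor; missing genes: {missing}"
        )
    cents = centroids if centroids is not None else panels.load_intrinsic_centroids()
    cents = cents.loc[[g for g in present if g in cents.index]]
    # center centroid rows the same way the data rows are centered, so the
    # rank comparison is between like-for-like deviations
    cents = cents.sub(cents.median(axis=1), axis=0)
    M = ds.values.loc[present]
    M = M.sub(M.median(axis=1), axis=0)  # median-center each gene
    S = M.to_numpy().T  # samples x genes
    Z = linkage(pdist(S, metric="euclidean"), method="average")
    groups = fcluster(Z, t=k, criterion="maxclust")

    calls = {s: SubtypeCall(sample_id=s) for s in ds.sample_ids}
    samples = np.array(ds.sample_ids)
    for g in np.unique(groups):
        in_g = samples[groups == g]
        if len(in_g) < min_group:
            continue
        votes, rs = [], []
        for s in in_g:
            lab, r = _centroid_label(M.loc[cents.index, s], cents)
            votes.append(lab)
            rs.append(r)
        counts = pd.Series(votes).value_counts()
        majority = counts.index[0]
        maj_r = float(np.median([r for v, r in zip(votes, rs) if v == majority]))
        if maj_r < min_corr:
            continue
        for s in in_g:
            calls[s].intrinsic = majority
    return [calls[s] for s in ds.sample_ids]


def assign_claudin_low(
    ds: ExpressionDataset,
    claudin_panel: GeneSet | None = None,
    candidates=(),
    epithelial_markers=None,
) -> list[str]:
    """Relabel Unclassified candidates falling in the low-claudin group.

    Samples are split into two groups by average-linkage clustering on the
    claudin-low recognition panel; the group with the lower mean
    claudin/E-cadherin expression is the claudin-low side.  Only the given
    candidate samples are relabeled; the function returns the sample ids
    (subset of candidates) called ClaudinLow.
    """
    panel = claudin_panel or panels.claudin_low_panel()
    present = [g for g in sorted(panel.members) if g in ds.values.index]
    if not present:
        raise TranscohortError("no claudin-low panel genes present in dataset")
    candidates = [s for s in candidates if s in ds.values.columns]
    if not candidates:
        return []
    epi = epithelial_markers or [g for g in panels.CLAUDIN_EPITHELIAL if g in present]
    if not epi:
        epi = present
    M = ds.values.loc[present]
    M = M.sub(M.median(axis=1), axis=0)
    S = M.to_numpy().T
    Z = linkage(pdist(S, metric="euclidean"), method="average")
    groups = fcluster(Z, t=2, criterion="maxclust")
    samples = np.array(ds.sample_ids)
    epi_mean = {
        g: float(ds.values.loc[epi, samples[groups == g]].to_numpy().mean())
        for g in np.unique(groups)
    }
    low_group = min(epi_mean, key=epi_mean.get)
    low_samples = set(samples[groups == low_group])
    return [s for s in candidates if s in low_samples]


def ihc_subtype(er: bool | None, pr: bool | None, her2: bool | None) -> str | None:
    """Clinical surrogate class from ER/PR/HER2 immunohistochemistry.

    Luminal HER2- (ER+ and/or PR+, HER2-), Luminal HER2+ (ER+ and/or PR+,
    HER2+), HER2+/ER- (ER-, PR-, HER2+), triple negative (ER-, PR-, HER2-).
    Missing status gives a missing class.
    """
    if er is None or pr is None or her2 is None:
        return None
    if er or pr:
        return "LumHER2pos" if her2 else "LumHER2neg"
    return "HER2posERneg" if her2 else "TripleNeg"


def round_half_up_pct(count: int, total: int) -> int:
    """Integer percentage with exact round-half-up (5.5% -> 6%)."""
    if total <= 0:
        raise TranscohortError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def frequency_table(calls: dict[str, str], cohort_labels: dict[str, str]) -> pd.DataFrame:
    """Cohort x subtype counts, round-half-up percentages and luminal ratio.

    Unclassified/ClaudinLow-free inputs are not required: Unclassified is
    reported as "Undetermined".  The luminal A / luminal B ratio is the
    ratio of the *rounded* percentages, to two decimals; it is NaN when the
    rounded luminal B percentage is zero.
    """
    order = ["Basal", "ERBB2", "LumA", "LumB", "ClaudinLow", "Undetermined"]
    rows = {}
    for cohort in sorted(set(cohort_labels.values())):
        samples = [s for s, c in cohort_labels.items() if c == cohort]
        n = len(samples)
        labs = ["Undetermined" if calls[s] == "Unclassified" else calls[s] for s in samples]
        counts = {o: labs.count(o) for o in order}
        pcts = {o: round_half_up_pct(counts[o], n) for o in order}
        la, lb = pcts["LumA"], pcts["LumB"]
        ratio = round(la / lb, 2) if lb > 0 else float("nan")
        row = {"n": n}
        for o in order:
            row[f"{o}_count"] = counts[o]
            row[f"{o}_pct"] = pcts[o]
        row["luminal_ratio"] = ratio
        rows[cohort] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def pca_group_separation(ds: ExpressionDataset, labels_a: dict[str, str],
                         labels_b: dict[str, str]):
    """First-two-PC embedding and mean silhouette width for two labelings.

    Used to ask which grouping (e.g. intrinsic subtype vs cohort) better
    explains the global structure of, say, the miRNA transcriptome.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    X = ds.values.to_numpy().T  # samples x features
    X = X - X.mean(axis=0)
    if min(X.shape) < 2 or np.linalg.matrix_rank(X) < 2:
        raise TranscohortError("data rank < 2; PCA embedding degenerate")
    emb = PCA(n_components=2).fit_transform(X)
    emb_df = pd.DataFrame(emb, index=ds.sample_ids, columns=["PC1", "PC2"])

    def _sil(labels: dict[str, str]) -> float:
        y = [labels[s] for s in ds.sample_ids]
        counts = pd.Series(y).value_counts()
        if (counts < 3).any() or counts.size < 2:
            raise TranscohortError("each compared label needs >=3 samples")
        return float(silhouette_score(emb, y))

    return emb_df, _sil(labels_a), _sil(labels_b)
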