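"""Cross-cohort conservation of correlated gene/miRNA clusters.

Clusters are discovered in one cohort by average-linkage hierarchical
clustering on distance 1 - Pearson r, cutting the dendrogram at height
1 - corr_cut (0.6 for genes, 0.4 for miRNAs) and keeping groups of at
least ``min_size`` features (10 genes, 5 miRNAs).  A cluster is validated
in a second cohort if, re-clustering only its members there at the same
cut, the largest group formed still holds at least ``min_confirm`` members
(default 3).  Gene-list over-representation in a cluster is scored with the
hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom, pearsonr

from .datasets import ExpressionDataset, GeneSet, TranscohortError

__all__ = [
    "CorrelatedCluster",
    "ClusterValidation",
    "EnrichmentResult",
    "discover_clusters",
    "validate_cluster",
    "conservation_summary",
    "hypergeometric_enrichment",
    "bidirectional_conservation",
]


@dataclass(frozen=True)
class CorrelatedCluster:
    id: str
    members: frozenset[str]
    seed_cohort: str
    corr_cut: float
    min_size: int


@dataclass(frozen=True)
class ClusterValidation:
    cluster_id: str
    n_confirmed: int
    min_confirm: int

    @property
    def validated(self) -> bool:
        return self.n_confirmed >= self.min_confirm


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: str
    gene_set: str
    overlap: int  # k
    cluster_size: int  # n
    set_size: int  # K
    universe_size: int  # N
    p: float


def _correlation_distance(values: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson r distances between feature rows."""
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = values.index[np.flatnonzero(sd == 0)[:5]].tolist()
        raise TranscohortError(f"constant feature(s), correlation undefined: {bad}")
    d = pdist(X, metric="correlation")
    return np.clip(d, 0.0, 2.0)


def _cut_groups(values: pd.DataFrame, corr_cut: float) -> pd.Series:
    """Flat group labels from the average-linkage tree cut at 1 - corr_cut."""
    if values.shape[0] < 2:
        return pd.Series([1] * values.shape[0], index=values.index)
    d = _correlation_distance(values)
    Z = linkage(d, method="average")
    labels = fcluster(Z, t=1.0 - corr_cut, criterion="distance")
    return pd.Series(labels, index=values.index)


def discover_clusters(ds: ExpressionDataset, corr_cut: float = 0.6,
                      min_size: int = 10) -> list[CorrelatedCluster]:
    """Cut the cohort dendrogram and return clusters of >= min_size features.

    Clusters are ordered by descending size (ties by lexicographically
    smallest member) and named C1, C2, ... deterministically.
    """
    if not (0 < corr_cut < 1):
        raise TranscohortError("corr_cut must lie in (0, 1)")
    if ds.n_samples < 3:
        raise TranscohortError("need >=3 samples to correlate features")
    groups = _cut_groups(ds.values, corr_cut)
    raw = [frozenset(groups.index[groups == g]) for g in groups.unique()]
    big = [m for m in raw if len(m) >= min_size]
    big.sort(key=lambda m: (-len(m), min(m)))
    return [
        CorrelatedCluster(f"C{i + 1}", members, ds.cohort, corr_cut, min_size)
        for i, members in enumerate(big)
    ]


def validate_cluster(cluster: CorrelatedCluster, ds_b: ExpressionDataset,
                     min_confirm: int = 3) -> ClusterValidation:
    """Re-cluster the cluster's members in a second cohort at the same cut.

    ``n_confirmed`` is the size of the largest group the members still form
    at the cut height 1 - corr_cut in the validation data; the cluster is
    validated when n_confirmed >= min_confirm.
    """
    present = [g for g in sorted(cluster.members) if g in ds_b.values.index]
    if len(present) < 2:
        raise TranscohortError(
            f"cluster {cluster.id}: only {len(present)} members present in validation data"
        )
    groups = _cut_groups(ds_b.values.loc[present], cluster.corr_cut)
    n_confirmed = int(groups.value_counts().max())
    return ClusterValidation(cluster.id, n_confirmed, min_confirm)


def conservation_summary(pairs) -> dict:
    """Summarize discovery/validation pairs across one direction.

    Returns n_discovered, n_validated, the validated fraction, and the
    Pearson correlation between seed-cluster size and confirmed size across
    validated clusters (NaN when fewer than 3 validated pairs).
    """
    pairs = list(pairs)
    if not pairs:
        raise TranscohortError("no discovered clusters; conservation undefined")
    n_disc = len(pairs)
    validated = [(c, v) for c, v in pairs if v.validated]
    n_val = len(validated)
    if n_val >= 3:
        sizes = np.array([len(c.members) for c, _ in validated], dtype=float)
        confirmed = np.array([v.n_confirmed for _, v in validated], dtype=float)
        if np.std(sizes) == 0 or np.std(confirmed) == 0:
            r = float("nan")
        else:
            r = float(pearsonr(sizes, confirmed)[0])
    else:
        r = float("nan")
    return {
        "n_discovered": n_disc,
        "n_validated": n_val,
        "fraction": n_val / n_disc,
        "size_pearson_r": r,
    }


def hypergeometric_enrichment(cluster_members, gene_set: GeneSet,
                              universe) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation of a gene set in a cluster.

    p = P(X >= k) for X ~ Hypergeom(N=universe, K=set size, n=cluster size),
    including the observed overlap k.
    """
    universe = set(universe)
    if not universe:
        raise TranscohortError("empty universe")
    members = set(cluster_members) & universe
    setg = gene_set.members & universe
    k = len(members & setg)
    N, K, n = len(universe), len(setg), len(members)
    p = float(hypergeom.sf(k - 1, N, K, n))
    name = getattr(gene_set, "name", "set")
    return EnrichmentResult(cluster_id="", gene_set=name, overlap=k,
                            cluster_size=n, set_size=K, universe_size=N,
                            p=min(max(p, 0.0), 1.0))


def bidirectional_conservation(ds_a: ExpressionDataset, ds_b: ExpressionDataset,
                               corr_cut: float = 0.6, min_size: int = 10,
                               min_confirm: int = 3,
                               ds_c: ExpressionDataset | None = None) -> dict:
    """Discover+validate in both directions (and optionally from a third set).

    Returns one conservation summary per direction, keyed "A_to_B",
    "B_to_A" and, when a third dataset is supplied, "C_to_A" / "C_to_B".
    """
    report = {}

    def _direction(seed, target):
        clusters = discover_clusters(seed, corr_cut, min_size)
        pairs = [(c, validate_cluster(c, target, min_confirm)) for c in clusters]
        return conservation_summary(pairs), clusters, pairs

    report["A_to_B"], _, _ = _direction(ds_a, ds_b)
    report["B_to_A"], _, _ = _direction(ds_b, ds_a)
    if ds_c is not None:
        clusters = discover_clusters(ds_c, corr_cut, min_size)
        for key, target in (("C_to_A", ds_a), ("C_to_B", ds_b)):
            pairs = []
            for c in clusters:
                present = [g for g in c.members if g in target.values.index]
                if len(present) >= 2:
                    pairs.append((c, validate_cluster(c, target, min_confirm)))
                else:
                    pairs.append((c, ClusterValidation(c.id, 0, min_confirm)))
            report[key] = conservation_summary(pairs)
    return report
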