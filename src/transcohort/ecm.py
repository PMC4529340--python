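"""Large-Average-Submatrices (LAS) biclustering of extracellular-matrix genes.

LAS searches a globally standardized matrix for k x l submatrices whose
average tau is improbably large under a Gaussian null.  The significance
score of a submatrix is

    score = -[ log C(m,k) + log C(n,l) + log Phi(-tau * sqrt(k*l)) ]

for an m x n matrix, computed entirely in log space (log-gamma binomials and
the normal tail's asymptotic log).  The search alternates row and column
updates from random column-subset starts until a fixed point, keeps the best
bicluster, subtracts its mean, and repeats.

Returned biclusters over an ECM gene universe are labeled ECM1 (immune/
protease) or ECM3 (collagen/stromal) by hypergeometric overlap with the
respective seed gene lists; samples in a labeled bicluster's column set get
that ECM class.  Stability is assessed by re-running the search with
distinct seeds and measuring pairwise Jaccard overlap of the target
cluster's gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .datasets import ExpressionDataset, GeneSet, TranscohortError
from .clusters import hypergeometric_enrichment

__all__ = [
    "Bicluster",
    "StabilityReport",
    "las_score",
    "las_search",
    "identify_ecm_clusters",
    "stability_analysis",
]


@dataclass(frozen=True)
class Bicluster:
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    tau: float
    score: float
    label: str | None = None


@dataclass(frozen=True)
class StabilityReport:
    n_runs: int
    jaccard: np.ndarray  # pairwise row-set Jaccard, diagonal 1
    mean_jaccard: float
    n_identified: int
    stable: bool


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def las_score(k: int, l: int, tau: float, m: int, n: int) -> float:
    """Significance score of a k x l submatrix with mean tau in an m x n matrix."""
    if not (1 <= k <= m and 1 <= l <= n):
        raise TranscohortError(f"invalid submatrix dims k={k}, l={l} for {m}x{n}")
    # Phi(-tau*sqrt(kl)) = upper tail at tau*sqrt(kl); logsf is asymptotically stable
    log_tail = norm.logsf(tau * np.sqrt(k * l))
    return float(-(_log_binom(m, k) + _log_binom(n, l) + log_tail))


def _best_k(sorted_means: np.ndarray, l: int, m: int, n: int):
    """Best prefix size along the sorted axis, maximizing the LAS score."""
    csum = np.cumsum(sorted_means)
    ks = np.arange(1, sorted_means.size + 1)
    taus = csum / ks
    lb = gammaln(m + 1) - gammaln(ks + 1) - gammaln(m - ks + 1)
    scores = -(lb + _log_binom(n, l) + norm.logsf(taus * np.sqrt(ks * l)))
    i = int(np.argmax(scores))
    return i + 1, float(scores[i]), float(taus[i])


def _search_once(X: np.ndarray, rng: np.random.Generator, max_iter: int = 50):
    m, n = X.shape
    l0 = max(1, int(rng.integers(1, max(2, n // 2 + 1))))
    cols = np.sort(rng.choice(n, size=l0, replace=False))
    rows = np.array([], dtype=int)
    score = -np.inf
    for _ in range(max_iter):
        # rows given cols
        row_means = X[:, cols].mean(axis=1)
        order = np.argsort(-row_means, kind="stable")
        k, s_rows, _ = _best_k(row_means[order], cols.size, m, n)
        new_rows = np.sort(order[:k])
        # cols given rows
        col_means = X[new_rows, :].mean(axis=0)
        order_c = np.argsort(-col_means, kind="stable")
        lbest, s_cols, tau = _best_k(col_means[order_c], new_rows.size, n, m)
        new_cols = np.sort(order_c[:lbest])
        if (np.array_equal(new_rows, rows) and np.array_equal(new_cols, cols)):
            score = s_cols
            break
        rows, cols, score = new_rows, new_cols, s_cols
    tau = float(X[np.ix_(rows, cols)].mean())
    return rows, cols, tau, float(score)


def las_search(matrix: pd.DataFrame, n_biclusters: int = 5, n_restarts: int = 20,
               seed: int = 0, min_score: float | None = None) -> list[Bicluster]:
    """Extract successive high-average biclusters from a standardized matrix.

    The matrix is globally z-scored (mean 0, sd 1 over all cells) before the
    search, matching the score's Gaussian-null assumption.  Per bicluster,
    the best fixed point over ``n_restarts`` random starts is kept and its
    submatrix mean removed before searching for the next.  Extraction stops
    early when the best score falls below ``min_score`` (default: the score
    of a single cell at tau = 3).
    """
    X = matrix.to_numpy(dtype=float).copy()
    if not np.isfinite(X).all():
        raise TranscohortError("matrix contains non-finite values")
    if n_restarts < 1:
        raise TranscohortError("n_restarts must be >= 1")
    m, n = X.shape
    X = (X - X.mean()) / X.std()
    if min_score is None:
        min_score = las_score(1, 1, 3.0, m, n)
    rng = np.random.default_rng(seed)
    found: list[Bicluster] = []
    for _ in range(n_biclusters):
        best = None
        for _ in range(n_restarts):
            rows, cols, tau, score = _search_once(X, rng)
            if best is None or score > best[3]:
                best = (rows, cols, tau, score)
        rows, cols, tau, score = best
        if score < min_score:
            break
        found.append(Bicluster(
            rows=tuple(matrix.index[rows]),
            cols=tuple(matrix.columns[cols]),
            tau=tau,
            score=score,
        ))
        X[np.ix_(rows, cols)] -= X[np.ix_(rows, cols)].mean()
    return found


def identify_ecm_clusters(
    ds: ExpressionDataset,
    ecm_universe: GeneSet,
    ecm1_seed: GeneSet,
    ecm3_seed: GeneSet,
    n_biclusters: int = 5,
    n_restarts: int = 20,
    seed: int = 0,
    p_cut: float = 0.01,
):
    """LAS over the ECM gene universe, with marker-seeded ECM1/ECM3 labeling.

    Each bicluster is labeled ECM1 or ECM3 when its hypergeometric overlap
    with that seed list (universe = ECM genes present in the data) reaches
    p < ``p_cut``; ties go to the smaller p.  Returns the labeled bicluster
    list and a per-sample ECM class series ("ECM1"/"ECM3"/"unassigned").
    """
    universe = sorted(ecm_universe.members & set(ds.values.index))
    if not universe:
        raise TranscohortError("ECM universe has no genes in the dataset")
    for name, seed_set in (("ECM1", ecm1_seed), ("ECM3", ecm3_seed)):
        if not (seed_set.members & set(universe)):
            raise TranscohortError(f"{name} seed genes absent from ECM universe")
    sub = ds.values.loc[universe]
    # remove per-gene baseline so the Gaussian-null z-scoring reflects
    # within-gene variation, not absolute intensity differences
    sub = sub.sub(sub.mean(axis=1), axis=0)
    biclusters = las_search(sub, n_biclusters=n_biclusters,
                            n_restarts=n_restarts, seed=seed)
    labeled = []
    classes = pd.Series("unassigned", index=ds.sample_ids)
    assigned = {"ECM1": False, "ECM3": False}
    for bc in biclusters:
        ps = {}
        for name, seed_set in (("ECM1", ecm1_seed), ("ECM3", ecm3_seed)):
            res = hypergeometric_enrichment(bc.rows, seed_set, universe)
            ps[name] = res.p
        label = min(ps, key=ps.get)
        if ps[label] < p_cut and not assigned[label]:
            bc = Bicluster(bc.rows, bc.cols, bc.tau, bc.score, label=label)
            assigned[label] = True
            for s in bc.cols:
                if classes[s] == "unassigned":
                    classes[s] = label
        labeled.append(bc)
    return labeled, classes


def stability_analysis(
    ds: ExpressionDataset,
    ecm_universe: GeneSet,
    ecm1_seed: GeneSet,
    ecm3_seed: GeneSet,
    target: str = "ECM3",
    n_runs: int = 20,
    seeds=None,
    stability_floor: float = 0.6,
    **params,
) -> StabilityReport:
    """Run-to-run stability of the target ECM cluster's gene set.

    The search is repeated with distinct seeds; stability is the mean
    pairwise Jaccard overlap of the target cluster's row sets across the
    runs where it was identified.  The cluster is flagged unstable when it
    is missed in more than half the runs or the mean Jaccard falls below
    the floor.
    """
    if n_runs < 2:
        raise TranscohortError("stability analysis needs n_runs >= 2")
    seeds = list(seeds) if seeds is not None else list(range(n_runs))
    gene_sets = []
    for s in seeds[:n_runs]:
        labeled, _ = identify_ecm_clusters(ds, ecm_universe, ecm1_seed, ecm3_seed,
                                           seed=s, **params)
        hit = [set(bc.rows) for bc in labeled if bc.label == target]
        gene_sets.append(hit[0] if hit else None)
    found = [g for g in gene_sets if g is not None]
    n_id = len(found)
    J = np.eye(len(found))
    for i in range(len(found)):
        for j in range(i + 1, len(found)):
            inter = len(found[i] & found[j])
            union = len(found[i] | found[j])
            J[i, j] = J[j, i] = inter / union if union else 0.0
    if len(found) >= 2:
        iu = np.triu_indices(len(found), k=1)
        mean_j = float(J[iu].mean())
    else:
        mean_j = 0.0
    stable = (n_id > n_runs / 2) and (mean_j >= stability_floor)
    return StabilityReport(n_runs=n_runs, jaccard=J, mean_jaccard=mean_j,
                           n_identified=n_id, stable=stable)
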