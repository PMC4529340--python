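"""Subclass mapping: do subtypes found independently in two datasets match?

For each subclass pair (A_i, B_j) the top marker genes of A_i (ranked by
signal-to-noise ratio against the rest of dataset A) are tested for
enrichment at the top of dataset B's B_j-vs-rest SNR ranking with a
weighted Kolmogorov-Smirnov running-sum statistic; the nominal p comes from
random gene-set placements.  The reverse test (B_j markers in A's ranking)
is combined with the forward one by Fisher's method, and the matrix of
combined p-values is corrected across cells by Benjamini-Hochberg.  A low
FDR on the diagonal and high FDR off it is the signature of corresponding
subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset, TranscohortError
from .de import bh_fdr

__all__ = [
    "AssociationMatrix",
    "snr_marker_ranking",
    "enrichment_pvalue",
    "submap",
]


@dataclass
class AssociationMatrix:
    fdr: pd.DataFrame  # subtypes of A x subtypes of B
    nominal_p: pd.DataFrame
    n_permutations: int
    seed: int


def snr_marker_ranking(ds: ExpressionDataset, labels: dict[str, str],
                       subclass: str, sd_floor_frac: float = 0.2) -> pd.Series:
    """Features ranked by signal-to-noise ratio for subclass vs rest.

    SNR = (mu_in - mu_out) / (sd_in + sd_out), with each sd floored at
    ``sd_floor_frac * |mu|`` of its group (the floor guards near-constant
    features).  Returned sorted descending.
    """
    y = np.array([labels[s] for s in ds.sample_ids])
    in_mask = y == subclass
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise TranscohortError(
            f"subclass {subclass!r} needs >=3 samples in and out "
            f"(has {in_mask.sum()} in, {(~in_mask).sum()} out)"
        )
    X = ds.values.to_numpy(dtype=float)
    mu_in = X[:, in_mask].mean(axis=1)
    mu_out = X[:, ~in_mask].mean(axis=1)
    sd_in = X[:, in_mask].std(axis=1, ddof=1)
    sd_out = X[:, ~in_mask].std(axis=1, ddof=1)
    sd_in = np.maximum(sd_in, sd_floor_frac * np.abs(mu_in))
    sd_out = np.maximum(sd_out, sd_floor_frac * np.abs(mu_out))
    denom = sd_in + sd_out
    denom[denom == 0] = np.finfo(float).eps
    snr = (mu_in - mu_out) / denom
    return pd.Series(snr, index=ds.values.index).sort_values(
        ascending=False, kind="stable"
    )


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, total_w: float,
                       n_features: int) -> float:
    """Max positive deviation of the weighted KS running sum.

    ``pos`` are the (sorted) 0-based rank positions of the set's members in
    the ranking; ``weights`` the matching |score| weights.  Between hits the
    sum decreases by 1/(N - nh) per miss, so the maximum is attained just
    after a hit.
    """
    nh = pos.size
    miss_pen = 1.0 / (n_features - nh)
    cum_w = np.cumsum(weights) / total_w
    misses_before = pos - np.arange(nh)  # misses encountered up to each hit
    dev = cum_w - (misses_before + 0) * miss_pen
    return float(np.max(dev))


def enrichment_pvalue(ranked: pd.Series, marker_set, n_perm: int = 500,
                      seed: int = 0) -> float:
    """Permutation p-value for marker-set enrichment at the top of a ranking.

    The observed statistic is the weighted KS enrichment score (weights =
    |SNR|); the null redraws the gene-set positions uniformly, and
    p = (1 + #{perm ES >= obs}) / (1 + n_perm).
    """
    markers = [m for m in marker_set]
    if not markers:
        raise TranscohortError("empty marker set")
    missing = [m for m in markers if m not in ranked.index]
    if missing:
        raise TranscohortError(f"markers absent from ranking: {missing[:5]}")
    if n_perm < 100:
        raise TranscohortError("n_perm must be >= 100")
    N = ranked.size
    w = np.abs(ranked.to_numpy(dtype=float))
    w = np.maximum(w, np.finfo(float).eps)
    rank_of = {f: i for i, f in enumerate(ranked.index)}
    pos = np.sort(np.array([rank_of[m] for m in markers]))
    obs = _es_from_positions(pos, w[pos], w[pos].sum(), N)
    rng = np.random.default_rng(seed)
    nh = pos.size
    count = 0
    for _ in range(n_perm):
        p = np.sort(rng.choice(N, size=nh, replace=False))
        if _es_from_positions(p, w[p], w[p].sum(), N) >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def _snr_matrix(X: np.ndarray, masks: np.ndarray, sd_floor_frac: float = 0.2):
    """SNR of in-group vs rest for many group indicator columns at once.

    ``X`` is features x samples; ``masks`` is samples x n_draws of 0/1 group
    indicators with a fixed column sum.  Returns features x n_draws SNRs.
    """
    n_in = masks.sum(axis=0)
    n_out = masks.shape[0] - n_in
    S1 = X @ masks
    S2 = (X**2) @ masks
    T1 = X.sum(axis=1, keepdims=True)
    T2 = (X**2).sum(axis=1, keepdims=True)
    mu_in = S1 / n_in
    mu_out = (T1 - S1) / n_out
    var_in = np.maximum((S2 - n_in * mu_in**2) / (n_in - 1), 0.0)
    var_out = np.maximum((T2 - S2 - n_out * mu_out**2) / (n_out - 1), 0.0)
    sd_in = np.maximum(np.sqrt(var_in), sd_floor_frac * np.abs(mu_in))
    sd_out = np.maximum(np.sqrt(var_out), sd_floor_frac * np.abs(mu_out))
    denom = sd_in + sd_out
    denom[denom == 0] = np.finfo(float).eps
    return (mu_in - mu_out) / denom


def _es_from_pos(P: np.ndarray, W: np.ndarray, N: int) -> np.ndarray:
    """Weighted-KS ES per column from marker rank positions and weights."""
    nh = P.shape[0]
    W = np.maximum(W, np.finfo(float).eps)
    sort_idx = np.argsort(P, axis=0)
    P = np.take_along_axis(P, sort_idx, axis=0)
    W = np.take_along_axis(W, sort_idx, axis=0)
    cum = np.cumsum(W, axis=0) / W.sum(axis=0, keepdims=True)
    dev = cum - (P - np.arange(nh)[:, None]) / (N - nh)
    return dev.max(axis=0)


def _rank_positions(snr: np.ndarray) -> np.ndarray:
    """Descending rank position of every feature, per SNR column."""
    N, n_draws = snr.shape
    order = np.argsort(-snr, axis=0, kind="stable")
    pos_of = np.empty_like(order)
    np.put_along_axis(pos_of, order, np.arange(N)[:, None].repeat(n_draws, 1), axis=0)
    return pos_of


def submap(
    ds_a: ExpressionDataset,
    labels_a: dict[str, str],
    ds_b: ExpressionDataset,
    labels_b: dict[str, str],
    n_markers: int = 50,
    n_perm: int = 500,
    seed: int = 0,
    min_common_features: int = 500,
    min_class_size: int = 3,
    combine: str = "iut",
) -> AssociationMatrix:
    """Mutual marker-enrichment association matrix between two labelings.

    For each subtype pair (A_i, B_j), the forward p asks whether A_i's top
    ``n_markers`` SNR markers are enriched at the top of B's B_j-vs-rest
    ranking, and the reverse p whether B_j's markers are enriched in A's
    A_i-vs-rest ranking.  Both are calibrated against one ensemble of
    random re-drawings of B's subclass labels: the forward null rebuilds
    the ranking, the reverse null rebuilds the marker set.  This absorbs
    the enrichment a random grouping of structured data inherits by chance
    composition, which a gene-set permutation null does not.  The two
    directions are combined per cell -- by default the intersection-union
    rule p = max(p_fwd, p_rev), which stays a valid level-alpha test under
    the strong dependence the shared permutation ensemble induces
    (``combine="fisher"`` gives the classical chi-square combination) --
    and the cell matrix is BH-adjusted to FDRs.  Deterministic under
    ``seed``.
    """
    common = sorted(set(ds_a.values.index) & set(ds_b.values.index))
    if not common:
        raise TranscohortError("datasets share no features")
    if len(common) < min_common_features:
        raise TranscohortError(
            f"only {len(common)} common features (< {min_common_features})"
        )
    A = ds_a.subset_features(common)
    B = ds_b.subset_features(common)
    subs_a = sorted({labels_a[s] for s in A.sample_ids})
    subs_b = sorted({labels_b[s] for s in B.sample_ids})
    for subs, labels, ds in ((subs_a, labels_a, A), (subs_b, labels_b, B)):
        counts = pd.Series([labels[s] for s in ds.sample_ids]).value_counts()
        small = counts[counts < min_class_size]
        if not small.empty:
            raise TranscohortError(f"subclasses below size floor: {dict(small)}")

    rank_a = {i: snr_marker_ranking(A, labels_a, i) for i in subs_a}
    rank_b = {j: snr_marker_ranking(B, labels_b, j) for j in subs_b}
    markers_a = {i: list(rank_a[i].index[:n_markers]) for i in subs_a}
    markers_b = {j: list(rank_b[j].index[:n_markers]) for j in subs_b}

    rng = np.random.default_rng(seed)
    feat_pos = {f: i for i, f in enumerate(common)}
    N = len(common)

    XB = B.values.to_numpy(dtype=float)
    yB = np.array([labels_b[s] for s in B.sample_ids])
    nB = yB.size
    perm_idx = np.array([rng.permutation(nB) for _ in range(n_perm)]).T

    # fixed A-side rankings: per subclass i, position and |SNR| per feature
    pos_a = {i: _rank_positions(rank_a[i].reindex(common).to_numpy()[:, None])[:, 0]
             for i in subs_a}
    w_a = {i: np.abs(rank_a[i].reindex(common).to_numpy()) for i in subs_a}

    p_fwd: dict[tuple[str, str], float] = {}
    p_rev: dict[tuple[str, str], float] = {}
    for j in subs_b:
        obs_mask = (yB == j).astype(float)[:, None]
        null_masks = (yB[perm_idx] == j).astype(float)
        snr_obs = _snr_matrix(XB, obs_mask)
        snr_null = _snr_matrix(XB, null_masks)
        pos_obs = _rank_positions(snr_obs)
        pos_null = _rank_positions(snr_null)
        # null/observed marker sets of B_j: top rows of each ranking
        order_obs = np.argsort(pos_obs[:, 0])[:n_markers]
        order_null = np.argsort(pos_null, axis=0, kind="stable")[:n_markers, :]
        for i in subs_a:
            rows = np.array([feat_pos[m] for m in markers_a[i]])
            # forward: A_i markers in B_j-vs-rest rankings
            es_obs = _es_from_pos(pos_obs[rows], np.abs(snr_obs[rows]), N)[0]
            es_null = _es_from_pos(pos_null[rows], np.abs(snr_null[rows]), N)
            p_fwd[(i, j)] = (1 + int((es_null >= es_obs).sum())) / (1 + n_perm)
            # reverse: B_j markers (observed / per-permutation) in A_i ranking
            pa, wa = pos_a[i], w_a[i]
            es_r_obs = _es_from_pos(pa[order_obs][:, None], wa[order_obs][:, None], N)[0]
            es_r_null = _es_from_pos(pa[order_null], wa[order_null], N)
            p_rev[(i, j)] = (1 + int((es_r_null >= es_r_obs).sum())) / (1 + n_perm)

    P = pd.DataFrame(np.ones((len(subs_a), len(subs_b))), index=subs_a, columns=subs_b)
    for i in subs_a:
        for j in subs_b:
            pf, pr = p_fwd[(i, j)], p_rev[(i, j)]
            if combine == "fisher":
                x2 = -2.0 * (np.log(pf) + np.log(pr))
                P.loc[i, j] = float(stats.chi2.sf(x2, df=4))
            elif combine == "iut":
                P.loc[i, j] = max(pf, pr)
            else:
                raise TranscohortError(f"unknown combine rule {combine!r}")
    flat = P.to_numpy().ravel()
    fdr = bh_fdr(np.clip(flat, np.finfo(float).tiny, 1.0))
    F = pd.DataFrame(fdr.reshape(P.shape), index=subs_a, columns=subs_b)
    return AssociationMatrix(fdr=F, nominal_p=P, n_permutations=n_perm, seed=seed)
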