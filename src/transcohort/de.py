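"""Per-feature linear modeling with ethnicity and subtype covariates.

Each feature is fit by ordinary least squares against a shared design
matrix (cohort/ethnicity factor plus intrinsic-subtype factor); contrasts
of interest are the ethnicity coefficient and every pairwise subtype
difference.  Calls use the joint rule FDR < 0.05 AND |log2 fold change|
>= 1 (i.e. fold change >= 2 on the natural scale; log2FC is the difference
of group means on the log2 scale).  A plain (unmoderated) per-feature OLS
t statistic is used.  The storage screen regresses every feature on
storage hours and flags nominal p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset, GeneSet, TranscohortError

__all__ = [
    "DEResult",
    "fit_linear_models",
    "bh_fdr",
    "call_de",
    "storage_screen",
]


@dataclass(frozen=True)
class DEResult:
    feature: str
    contrast: str
    log2fc: float
    t: float
    p: float
    fdr: float

    @property
    def significant(self) -> bool:
        return self.fdr < 0.05 and abs(self.log2fc) >= 1.0


def _design_matrix(ethnicity: np.ndarray, subtype: np.ndarray | None):
    """Full-rank design: intercept + ethnicity dummy (+ subtype dummies)."""
    eth_levels = sorted(set(ethnicity))
    cols = {"intercept": np.ones(ethnicity.size)}
    contrast_info = {}
    for lev in eth_levels[1:]:
        cols[f"eth_{lev}"] = (ethnicity == lev).astype(float)
    if len(eth_levels) == 2:
        contrast_info["ethnicity"] = (f"eth_{eth_levels[1]}",)
    sub_levels = []
    if subtype is not None:
        sub_levels = sorted(set(subtype))
        for lev in sub_levels[1:]:
            cols[f"sub_{lev}"] = (subtype == lev).astype(float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased columns for the error message
        _, R = np.linalg.qr(X)
        aliased = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-10]
        raise TranscohortError(f"rank-deficient design; aliased terms: {aliased}")
    return X, names, eth_levels, sub_levels


def fit_linear_models(ds: ExpressionDataset, ethnicity: dict[str, str],
                      subtype: dict[str, str] | None = None,
                      exclude_unclassified: bool = True) -> pd.DataFrame:
    """OLS fits per feature; one row per feature x contrast.

    Contrasts: the ethnicity difference (second level minus first), and all
    pairwise subtype differences when a subtype covariate is given.
    Unclassified samples are dropped from the model by default.
    """
    samples = ds.sample_ids
    eth = np.array([ethnicity[s] for s in samples])
    sub = np.array([subtype[s] for s in samples]) if subtype is not None else None
    keep = np.ones(len(samples), dtype=bool)
    if sub is not None and exclude_unclassified:
        keep = ~np.isin(sub, ["Unclassified", "Undetermined"])
    Y = ds.values.to_numpy(dtype=float)[:, keep]
    eth = eth[keep]
    sub = sub[keep] if sub is not None else None

    X, names, eth_levels, sub_levels = _design_matrix(eth, sub)
    n, p = X.shape
    if n - p < 2:
        raise TranscohortError("fewer than 2 residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T  # features x coefficients
    resid = Y - B @ X.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df

    contrasts: dict[str, np.ndarray] = {}
    if len(eth_levels) == 2:
        c = np.zeros(p)
        c[names.index(f"eth_{eth_levels[1]}")] = 1.0
        contrasts[f"ethnicity:{eth_levels[1]}-{eth_levels[0]}"] = c
    for a, b in combinations(sub_levels, 2):
        c = np.zeros(p)
        if f"sub_{b}" in names:
            c[names.index(f"sub_{b}")] += 1.0
        if f"sub_{a}" in names:
            c[names.index(f"sub_{a}")] -= 1.0
        contrasts[f"subtype:{b}-{a}"] = c

    rows = []
    for cname, c in contrasts.items():
        est = B @ c
        se = np.sqrt(sigma2 * float(c @ XtX_inv @ c))
        se[se == 0] = np.finfo(float).eps
        t = est / se
        pv = 2.0 * stats.t.sf(np.abs(t), df)
        rows.append(pd.DataFrame({
            "feature": ds.feature_ids,
            "contrast": cname,
            "log2fc": est,
            "t": t,
            "p": np.clip(pv, np.finfo(float).tiny, 1.0),
        }))
    return pd.concat(rows, ignore_index=True)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise TranscohortError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(fits: pd.DataFrame, fdr_cut: float = 0.05,
            fc_cut: float = 2.0) -> tuple[list[DEResult], dict[str, int]]:
    """Apply the joint FDR/fold-change rule per contrast.

    FDR is computed within each contrast.  Subtype significance follows the
    union-over-contrasts rule (a feature counts as subtype-DE when it passes
    in at least one pairwise subtype comparison).  Returns all per-feature
    results plus a per-contrast count dict including ``ethnicity_union`` and
    ``subtype_union`` totals.
    """
    lfc_cut = np.log2(fc_cut)
    results: list[DEResult] = []
    counts: dict[str, int] = {}
    union_sig: dict[str, set] = {"ethnicity": set(), "subtype": set()}
    for cname, grp in fits.groupby("contrast", sort=True):
        fdr = bh_fdr(grp["p"].to_numpy())
        sig = (fdr < fdr_cut) & (np.abs(grp["log2fc"].to_numpy()) >= lfc_cut)
        counts[cname] = int(sig.sum())
        kind = "ethnicity" if cname.startswith("ethnicity") else "subtype"
        union_sig[kind] |= set(grp["feature"].to_numpy()[sig])
        for row, q in zip(grp.itertuples(index=False), fdr):
            results.append(DEResult(row.feature, cname, float(row.log2fc),
                                    float(row.t), float(row.p), float(q)))
    counts["ethnicity_union"] = len(union_sig["ethnicity"])
    counts["subtype_union"] = len(union_sig["subtype"])
    return results, counts


def storage_screen(ds: ExpressionDataset, storage_hours: dict[str, float],
                   p_cut: float = 0.001,
                   signatures: list[GeneSet] | None = None):
    """Per-feature simple regression on storage time before freezing.

    Flags features with nominal p < ``p_cut``; when breast-cancer signature
    gene sets are supplied, also reports how many flagged genes each
    signature contains.
    """
    hours = np.array([storage_hours[s] for s in ds.sample_ids], dtype=float)
    if np.std(hours) == 0:
        raise TranscohortError("storage hours are constant; slope undefined")
    Y = ds.values.to_numpy(dtype=float)
    n = hours.size
    hc = hours - hours.mean()
    sxx = float((hc**2).sum())
    slope = (Y @ hc) / sxx
    resid = Y - Y.mean(axis=1, keepdims=True) - np.outer(slope, hc)
    df = n - 2
    se = np.sqrt((resid**2).sum(axis=1) / df / sxx)
    se[se == 0] = np.finfo(float).eps
    t = slope / se
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame({
        "feature": ds.feature_ids,
        "slope_per_hour": slope,
        "p": pv,
        "flagged": pv < p_cut,
    }).set_index("feature")
    overlaps = {}
    if signatures:
        flagged = set(out.index[out["flagged"]])
        for sig in signatures:
            overlaps[sig.name] = len(flagged & sig.members)
    return out, overlaps
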