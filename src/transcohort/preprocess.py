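"""Matrix-level preprocessing: log2, normalization, detection filter,
probe-to-gene collapse and variability filtering.

The fixed stage order is log2 -> quantile normalization -> detection filter
-> probe collapse; variability (IQR) filtering happens later, at the start
of unsupervised analysis.  Quantile normalization stands in for the bead
platform's spline-based normalization: it aligns the full per-sample
intensity distributions, which is the property downstream stages rely on.

Quartiles use linear interpolation between order statistics (NumPy's
default, the "type 7" rule); this matters because IQR thresholds such as
0.4 are decision boundaries.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, TranscohortError

log = logging.getLogger("transcohort")

__all__ = [
    "maybe_log2",
    "quantile_normalize",
    "filter_by_detection",
    "collapse_probes",
    "iqr_filter",
    "probe_stats",
    "preprocess_pipeline",
]


def maybe_log2(ds: ExpressionDataset) -> ExpressionDataset:
    """Apply log2(x+1) unless values already look log-scaled (max <= 30)."""
    if ds.values.to_numpy().max() <= 30:
        return ds
    warnings.warn("values exceed 30; applying log2(x+1)", stacklevel=2)
    if ds.values.to_numpy().min() < 0:
        raise TranscohortError("negative intensities cannot be log2-transformed")
    return ExpressionDataset(np.log2(ds.values + 1.0), ds.detection_p, ds.cohort)


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample onto the mean distribution (rank-wise column means).

    After normalization every column holds the same multiset of values (the
    mean of the per-rank values across samples) and within-column ranks are
    preserved.  Ties share the mean of their rank range.  Idempotent.
    """
    if ds.n_samples < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input",
                      stacklevel=2)
        return ds
    X = ds.values.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    ranked = np.take_along_axis(X, order, axis=0)
    mean_dist = ranked.mean(axis=1)
    out = np.empty_like(X)
    # average rank handling for ties: use pandas ranks
    for j in range(X.shape[1]):
        ranks = pd.Series(X[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (mean_dist[lo] + mean_dist[hi])
    values = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(values, ds.detection_p, ds.cohort)


def filter_by_detection(ds: ExpressionDataset, alpha: float = 0.01,
                        min_samples: int = 1) -> ExpressionDataset:
    """Keep features detected (p < alpha) in at least ``min_samples`` samples."""
    if ds.detection_p is None:
        raise TranscohortError("filter_by_detection requires a detection_p matrix")
    detected = (ds.detection_p.to_numpy() < alpha).sum(axis=1) >= min_samples
    keep = ds.values.index[detected]
    log.info("detection filter: kept %d/%d features", detected.sum(), ds.n_features)
    return ds.subset_features(keep)


def probe_stats(ds: ExpressionDataset, alpha: float = 0.01) -> pd.DataFrame:
    """Per-probe detection rate (fraction of samples with p < alpha) and IQR."""
    iqr = ds.values.quantile(0.75, axis=1) - ds.values.quantile(0.25, axis=1)
    if ds.detection_p is not None:
        rate = (ds.detection_p < alpha).mean(axis=1)
    else:
        rate = pd.Series(1.0, index=ds.values.index)
    return pd.DataFrame({"detection_rate": rate, "iqr": iqr})


def collapse_probes(ds: ExpressionDataset, annotation: dict[str, str] | pd.Series,
                    alpha: float = 0.01) -> ExpressionDataset:
    """Collapse multiple probes per gene symbol to a single representative row.

    The probe with the highest detection rate wins; equal rates fall back to
    the larger IQR, remaining ties to the lexicographically smallest probe
    id.  Every probe must be annotated.
    """
    ann = pd.Series(annotation) if not isinstance(annotation, pd.Series) else annotation
    missing = [p for p in ds.values.index if p not in ann.index]
    if missing:
        raise TranscohortError(f"unannotated probes: {missing[:10]}")
    stats = probe_stats(ds, alpha=alpha)
    tbl = pd.DataFrame({
        "probe": ds.values.index,
        "symbol": ann.loc[ds.values.index].to_numpy(),
        "rate": stats["detection_rate"].to_numpy(),
        "iqr": stats["iqr"].to_numpy(),
    })
    # argmax rate, tie -> larger IQR, tie -> smaller probe id
    tbl = tbl.sort_values(["symbol", "rate", "iqr", "probe"],
                          ascending=[True, False, False, True], kind="stable")
    chosen = tbl.drop_duplicates("symbol", keep="first")
    out = ds.values.loc[chosen["probe"]]
    out.index = chosen["symbol"].to_numpy()
    detp = None
    if ds.detection_p is not None:
        detp = ds.detection_p.loc[chosen["probe"]]
        detp.index = chosen["symbol"].to_numpy()
    return ExpressionDataset(out, detp, ds.cohort)


def iqr_filter(ds: ExpressionDataset, min_iqr: float) -> ExpressionDataset:
    """Keep features with interquartile range strictly greater than ``min_iqr``."""
    if min_iqr < 0:
        raise TranscohortError("min_iqr must be >= 0")
    iqr = ds.values.quantile(0.75, axis=1) - ds.values.quantile(0.25, axis=1)
    keep = ds.values.index[iqr > min_iqr]
    return ds.subset_features(keep)


def preprocess_pipeline(ds: ExpressionDataset, annotation=None,
                        alpha: float = 0.01) -> ExpressionDataset:
    """log2 -> quantile normalize -> detection filter -> collapse (if annotated)."""
    ds = maybe_log2(ds)
    ds = quantile_normalize(ds)
    if ds.detection_p is not None:
        ds = filter_by_detection(ds, alpha=alpha)
    if annotation is not None:
        ds = collapse_probes(ds, annotation, alpha=alpha)
    return ds
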