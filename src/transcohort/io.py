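"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (first column = feature id, header =
sample ids), gene sets as GMT, configuration as YAML (JSON is a subset of
YAML and is accepted transparently).  Every reader rejects malformed input
with an error naming the offending line; writer/reader pairs are lossless
at full float precision.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import ExpressionDataset, GeneSet, TranscohortError

log = logging.getLogger("transcohort")

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_sample_annotation",
    "load_config",
]


def read_expression_tsv(
    path,
    detection_path=None,
    cohort: str = "",
    allow_na: bool = False,
) -> ExpressionDataset:
    """Read a feature x sample TSV matrix (and optional detection-p TSV).

    The first column holds feature ids, the header row sample ids.
    Duplicate feature ids are rejected here: collapsing multiple probes per
    gene is the preprocessing stage's job and requires an annotation table.
    """
    path = Path(path)
    if not path.exists():
        raise TranscohortError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) < len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise TranscohortError(f"{path}: duplicate sample ids in header: {dup}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pandas errors carry the line number
        raise TranscohortError(f"{path}: parse error: {exc}") from exc
    df.index.name = None
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise TranscohortError(f"{path}: duplicate feature ids: {dup}")
    arr = df.apply(pd.to_numeric, errors="coerce")
    bad = arr.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TranscohortError(
            f"{path}: non-numeric cell at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r} (line {r + 2})"
        )
    if arr.isna().to_numpy().any() and not allow_na:
        r, c = np.argwhere(arr.isna().to_numpy())[0]
        raise TranscohortError(
            f"{path}: missing value at feature {df.index[r]!r} (line {r + 2}); "
            "pass allow_na=True to impute by feature median"
        )
    if allow_na:
        arr = arr.apply(lambda row: row.fillna(row.median()), axis=1)
    detp = None
    if detection_path is not None:
        detp = pd.read_csv(detection_path, sep="\t", index_col=0,
                           float_precision="round_trip")
        detp = detp.apply(pd.to_numeric, errors="raise")
    return ExpressionDataset(values=arr.astype(float), detection_p=detp, cohort=cohort)


def write_expression_tsv(ds: ExpressionDataset, path, detection_path=None) -> None:
    """Write the matrix (and optionally its detection-p matrix) as TSV."""
    if ds.n_features == 0 or ds.n_samples == 0:
        raise TranscohortError(f"refusing to write empty dataset to {path}")
    ds.values.to_csv(path, sep="\t", float_format="%.17g", index_label="feature_id")
    if detection_path is not None:
        if ds.detection_p is None:
            raise TranscohortError("dataset has no detection_p matrix to write")
        ds.detection_p.to_csv(
            detection_path, sep="\t", float_format="%.17g", index_label="feature_id"
        )


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per line, `name<TAB>desc<TAB>members...`."""
    path = Path(path)
    if not path.exists():
        raise TranscohortError(f"no such file: {path}")
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TranscohortError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            members = [m for m in fields[2:] if m]
            if len(set(members)) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {fields[0]!r}; "
                    "deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(fields[0], fields[1], frozenset(members)))
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_sample_annotation(path) -> pd.DataFrame:
    """Read the sample-annotation TSV (sample_id, cohort, IHC columns...)."""
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in ann.columns:
        raise TranscohortError(f"{path}: missing required column 'sample_id'")
    if ann["sample_id"].duplicated().any():
        raise TranscohortError(f"{path}: duplicate sample_id entries")
    return ann.set_index("sample_id")


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise TranscohortError(f"{path}: config must be a mapping")
    return cfg
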