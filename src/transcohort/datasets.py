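"""Core in-memory containers shared by every pipeline stage.

The unit of work is an :class:`ExpressionDataset`: a feature x sample matrix
of log2 intensities, optionally paired with a same-shape matrix of per-probe
detection p-values, and tagged with the cohort it came from.  Gene panels and
signatures travel as :class:`GeneSet` objects read from GMT files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "GeneSet", "TranscohortError"]


class TranscohortError(ValueError):
    """Base class for input-contract violations raised by this package."""


@dataclass
class ExpressionDataset:
    """A feature x sample log2 expression matrix with optional detection p.

    Parameters
    ----------
    values
        DataFrame of log2 intensities; index = feature ids, columns = sample
        ids.  Both must be unique; all values must be finite.
    detection_p
        Optional DataFrame of detection p-values with identical index and
        columns; entries in [0, 1].
    cohort
        Free-form label for the cohort the samples belong to.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    cohort: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TranscohortError("values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise TranscohortError(f"duplicate feature ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()[:5]
            raise TranscohortError(f"duplicate sample ids: {dup}")
        if v.size and not np.isfinite(v.to_numpy(dtype=float)).all():
            raise TranscohortError("expression values must be finite (no NA)")
        if self.detection_p is not None:
            p = self.detection_p
            if p.shape != v.shape:
                raise TranscohortError(
                    f"detection_p shape {p.shape} != values shape {v.shape}"
                )
            arr = p.to_numpy(dtype=float)
            if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
                raise TranscohortError("detection p-values must lie in [0, 1]")
            # align labels so positional and label indexing agree downstream
            self.detection_p = p.loc[v.index, v.columns]

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features) -> "ExpressionDataset":
        """Dataset restricted to ``features`` (order of the given list)."""
        feats = [f for f in features if f in self.values.index]
        return ExpressionDataset(
            values=self.values.loc[feats],
            detection_p=None if self.detection_p is None else self.detection_p.loc[feats],
            cohort=self.cohort,
        )

    def subset_samples(self, samples) -> "ExpressionDataset":
        cols = [s for s in samples if s in self.values.columns]
        return ExpressionDataset(
            values=self.values[cols],
            detection_p=None if self.detection_p is None else self.detection_p[cols],
            cohort=self.cohort,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of feature ids (one GMT line)."""

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise TranscohortError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, universe) -> frozenset[str]:
        return self.members & set(universe)
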