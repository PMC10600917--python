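"""Core data containers for abundance tables and derived feature matrices.

Orientation is fixed throughout the package: samples are rows, taxa/features
are columns, matching the on-disk TSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical 7-rank taxonomic lineage, coarsest to finest.
TAXONOMIC_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Allowed provenance stages of a FeatureMatrix.
FEATURE_STAGES = ("log_transformed", "scaled", "mapped", "noise_augmented")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class CountMatrix:
    """Sample x taxon table of nonnegative integer abundances.

    Parameters
    ----------
    counts
        DataFrame of shape (n_samples, n_taxa) with unique sample ids as
        index and unique taxon ids as columns; nonnegative integers.
    taxonomy
        Optional DataFrame indexed by taxon id with the 7 rank columns of
        :data:`TAXONOMIC_RANKS`; missing ranks may be empty strings or NaN.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if not self.counts.columns.is_unique:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise ValidationError("negative abundance counts are not allowed")
        if self.taxonomy is not None:
            missing = [c for c in TAXONOMIC_RANKS if c not in self.taxonomy.columns]
            if missing:
                raise ValidationError(f"taxonomy is missing rank columns: {missing}")
            if not self.taxonomy.index.equals(self.counts.columns):
                extra = self.taxonomy.index.symmetric_difference(self.counts.columns)
                raise ValidationError(
                    f"taxonomy index does not match taxon ids (mismatch: {list(extra)[:5]})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class FeatureMatrix:
    """Real-valued sample x feature matrix with a provenance stage tag."""

    values: pd.DataFrame
    stage: str = "log_transformed"

    def __post_init__(self) -> None:
        if self.stage not in FEATURE_STAGES:
            raise ValidationError(
                f"unknown stage {self.stage!r}; expected one of {FEATURE_STAGES}"
            )
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate feature ids")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("feature matrix contains non-finite entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def validate_labels(y: pd.Series | np.ndarray, require_both_classes: bool = True) -> np.ndarray:
    """Validate a binary case/control label vector (1 = case, 0 = control).

    Returns the labels as an int array; raises :class:`ValidationError` on
    non-binary values or, when ``require_both_classes``, a single-class vector.
    """
    arr = np.asarray(y)
    if arr.ndim != 1:
        raise ValidationError("label vector must be one-dimensional")
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise ValidationError(f"labels must be binary 0/1, got values {sorted(uniq)}")
    if require_both_classes and uniq != {0, 1}:
        raise ValidationError("both classes must be present")
    return arr.astype(int)
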