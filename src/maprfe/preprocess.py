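"""Preprocessing chain for abundance tables.

The chain mirrors common practice for 16S case/control studies: aggregate
taxa at a chosen rank, drop near-absent taxa, log-transform relative to the
per-sample geometric mean (a clr-style transform with a pseudocount), keep
the features shared across cohorts, split stratified by class, and min-max
scale using training data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from maprfe.types import (
    TAXONOMIC_RANKS,
    CountMatrix,
    FeatureMatrix,
    ValidationError,
    validate_labels,
)


class EmptyResultError(ValueError):
    """A filtering or intersection step removed every feature."""


def aggregate_taxa(counts: CountMatrix, level: str) -> CountMatrix:
    """Sum counts of taxa sharing the same lineage truncated at ``level``.

    Total counts per sample are conserved exactly. Output taxon ids are the
    truncated lineages joined as ``rank:value`` segments with ``;``.
    """
    if level not in TAXONOMIC_RANKS:
        raise ValidationError(f"unknown taxonomic rank {level!r}; expected one of {TAXONOMIC_RANKS}")
    if counts.taxonomy is None:
        raise ValidationError("taxonomy is required for aggregation")
    depth = TAXONOMIC_RANKS.index(level) + 1
    ranks = list(TAXONOMIC_RANKS[:depth])
    tax = counts.taxonomy[ranks].fillna("").astype(str)
    lineage = tax.apply(
        lambda row: ";".join(f"{r[0]}:{row[r]}" for r in ranks), axis=1
    )
    agg = counts.counts.T.groupby(lineage.reindex(counts.counts.columns)).sum().T
    agg = agg[sorted(agg.columns)]
    new_tax = tax.copy()
    new_tax.index = lineage
    new_tax = new_tax[~new_tax.index.duplicated()]
    for r in TAXONOMIC_RANKS[depth:]:
        new_tax[r] = ""
    return CountMatrix(agg, new_tax.loc[agg.columns, list(TAXONOMIC_RANKS)])


def prevalence_filter(counts: CountMatrix, max_zero_fraction: float = 0.99) -> CountMatrix:
    """Drop taxa whose fraction of zero abundances exceeds ``max_zero_fraction``.

    A taxon with a zero fraction exactly equal to the threshold is kept.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValidationError("max_zero_fraction must lie in [0, 1]")
    zero_frac = (counts.counts == 0).mean(axis=0)
    keep = zero_frac[zero_frac <= max_zero_fraction].index
    if len(keep) == 0:
        raise EmptyResultError("prevalence filter removed every taxon")
    tax = counts.taxonomy.loc[keep] if counts.taxonomy is not None else None
    return CountMatrix(counts.counts[keep], tax)


def clr_log_transform(counts: CountMatrix) -> FeatureMatrix:
    """Log2 of each abundance relative to its sample's geometric mean.

    A pseudocount c — the global minimum nonzero count of the matrix — is
    added to every entry; each sample i is then transformed as
    ``y_ij = log2((x_ij + c) / g_i)`` with ``g_i`` the geometric mean of the
    shifted sample. Every output row sums to zero (clr property).
    """
    x = counts.counts.to_numpy(dtype=float)
    nonzero = x[x > 0]
    if nonzero.size == 0:
        raise ValidationError("all-zero count matrix: pseudocount undefined")
    c = nonzero.min()
    logx = np.log2(x + c)
    y = logx - logx.mean(axis=1, keepdims=True)
    return FeatureMatrix(
        pd.DataFrame(y, index=counts.counts.index, columns=counts.counts.columns),
        stage="log_transformed",
    )


def intersect_features(tables: list[CountMatrix]) -> list[CountMatrix]:
    """Restrict every table to the (sorted) intersection of their taxon sets."""
    if len(tables) < 2:
        raise ValidationError("need at least two tables to intersect")
    common = set(tables[0].taxon_ids)
    for t in tables[1:]:
        common &= set(t.taxon_ids)
    if not common:
        raise EmptyResultError("no features are common to all tables")
    order = sorted(common)
    out = []
    for t in tables:
        tax = t.taxonomy.loc[order] if t.taxonomy is not None else None
        out.append(CountMatrix(t.counts[order], tax))
    return out


def stratified_split(
    X: FeatureMatrix,
    y: pd.Series | np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test split; returns positional index arrays."""
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie strictly between 0 and 1")
    arr = validate_labels(y)
    counts = np.bincount(arr)
    if counts.min() < 2:
        raise ValidationError("each class needs at least 2 samples to stratify")
    idx = np.arange(len(arr))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=arr, random_state=seed
    )
    return np.sort(train), np.sort(test)


@dataclass
class ScalerState:
    """Per-feature min and max learned on a training matrix."""

    mins: pd.Series
    maxs: pd.Series

    def __post_init__(self) -> None:
        if (self.maxs < self.mins).any():
            raise ValidationError("scaler max < min for some feature")


def fit_minmax(X_train: FeatureMatrix) -> ScalerState:
    """Learn per-feature min/max from training data only."""
    return ScalerState(X_train.values.min(axis=0), X_train.values.max(axis=0))


def apply_minmax(X: FeatureMatrix, state: ScalerState) -> FeatureMatrix:
    """Map features into [0, 1] with the learned range, clipping new data.

    Constant features (max == min) map to 0.
    """
    if list(X.values.columns) != list(state.mins.index):
        raise ValidationError("feature ids do not match the scaler state")
    span = (state.maxs - state.mins).to_numpy()
    safe = np.where(span > 0, span, 1.0)
    scaled = (X.values.to_numpy() - state.mins.to_numpy()) / safe
    scaled[:, span == 0] = 0.0
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureMatrix(
        pd.DataFrame(scaled, index=X.values.index, columns=X.values.columns),
        stage="scaled",
    )
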