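"""Model-agnostic Shapley attributions for selected biomarkers.

The value of a feature coalition C for a sample x is the model's mean output
over a background sample with the coordinates in C taken from x and the rest
from the background rows (marginal/interventional imputation). The exact
estimator enumerates all 2^k coalitions (feasible for the biomarker-scale
k <= 14); the sampling estimator averages marginal contributions over random
feature orderings and is unbiased for the exact value.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from maprfe.types import FeatureMatrix, ValidationError

_MAX_EXACT = 14


@dataclass
class ShapleyAttribution:
    """Per-sample, per-feature contributions plus the background base value."""

    values: pd.DataFrame  # samples x features
    base_value: float
    background_means: pd.Series


@dataclass
class ShapSummary:
    """Feature ranking by mean absolute attribution with sign directions."""

    mean_abs: pd.Series
    direction: pd.Series  # +1 high values push toward case, -1 away, 0 flat
    total_rank: pd.Series  # permutation of 1..k


def _coalition_values(predict_fn, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    """v(C) for every coalition mask 0..2^k-1, batched through predict_fn."""
    m, k = background.shape
    n_masks = 1 << k
    values = np.empty(n_masks)
    chunk = max(1, 4096 // max(m, 1))
    for start in range(0, n_masks, chunk):
        masks = range(start, min(start + chunk, n_masks))
        rows = []
        for mask in masks:
            block = background.copy()
            for j in range(k):
                if mask >> j & 1:
                    block[:, j] = x[j]
            rows.append(block)
        preds = np.asarray(predict_fn(np.vstack(rows)), dtype=float)
        values[start : start + len(rows)] = preds.reshape(len(rows), m).mean(axis=1)
    return values


def exact_shapley(
    predict_fn, background: FeatureMatrix | np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact Shapley attributions by full coalition enumeration (k <= 14).

    Returns (phi, base_value) with base_value = mean model output on the
    background; phi sums to predict(x) - base_value (efficiency).
    """
    bg = background.values.to_numpy() if isinstance(background, FeatureMatrix) else np.asarray(background, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    m, k = bg.shape
    if x.shape[0] != k:
        raise ValidationError("sample dimension does not match the background")
    if k > _MAX_EXACT:
        raise ValidationError(
            f"{k} features exceeds the exact-enumeration limit {_MAX_EXACT}; "
            "use sampling_shapley"
        )
    v = _coalition_values(predict_fn, bg, x)
    # Shapley kernel weights w(s) = s! (k-1-s)! / k!
    w = np.array([factorial(s) * factorial(k - 1 - s) / factorial(k) for s in range(k)])
    sizes = np.array([bin(mask).count("1") for mask in range(1 << k)])
    phi = np.zeros(k)
    for mask in range(1 << k):
        s = sizes[mask]
        for j in range(k):
            if not mask >> j & 1:
                phi[j] += w[s] * (v[mask | (1 << j)] - v[mask])
    return phi, float(v[0])


def sampling_shapley(
    predict_fn,
    background: FeatureMatrix | np.ndarray,
    x: np.ndarray,
    n_permutations: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo Shapley: average marginal contributions over orderings."""
    if n_permutations < 1:
        raise ValidationError("n_permutations must be at least 1")
    bg = background.values.to_numpy() if isinstance(background, FeatureMatrix) else np.asarray(background, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    m, k = bg.shape
    rng = np.random.default_rng(seed)
    base = float(np.mean(np.asarray(predict_fn(bg), dtype=float)))
    phi = np.zeros(k)
    chunk = max(1, 64 // max(1, k))  # permutations per predict batch
    done = 0
    while done < n_permutations:
        batch = min(chunk, n_permutations - done)
        perms = [rng.permutation(k) for _ in range(batch)]
        rows = []
        for perm in perms:
            block = bg.copy()
            for j in perm:
                block[:, j] = x[j]
                rows.append(block.copy())
        preds = np.asarray(predict_fn(np.vstack(rows)), dtype=float)
        preds = preds.reshape(batch, k, m).mean(axis=2)
        for p, perm in enumerate(perms):
            prev = base
            for step, j in enumerate(perm):
                phi[j] += preds[p, step] - prev
                prev = preds[p, step]
        done += batch
    return phi / n_permutations


def explain_samples(
    predict_fn,
    background: FeatureMatrix,
    X: FeatureMatrix,
    exact: bool | None = None,
    n_permutations: int = 2000,
    seed: int = 0,
) -> ShapleyAttribution:
    """Attribute every sample in X; exact when k <= 14 unless overridden."""
    k = background.values.shape[1]
    if exact is None:
        exact = k <= _MAX_EXACT
    bg = background.values.to_numpy()
    base = float(np.mean(np.asarray(predict_fn(bg), dtype=float)))
    rows = []
    for i, (_, x) in enumerate(X.values.iterrows()):
        if exact:
            phi, base = exact_shapley(predict_fn, bg, x.to_numpy())
        else:
            phi = sampling_shapley(
                predict_fn, bg, x.to_numpy(), n_permutations, seed + i
            )
        rows.append(phi)
    values = pd.DataFrame(rows, index=X.values.index, columns=X.values.columns)
    return ShapleyAttribution(
        values=values, base_value=base, background_means=background.values.mean(axis=0)
    )


def shap_summary(attr: ShapleyAttribution, X: FeatureMatrix) -> ShapSummary:
    """Rank features by mean |attribution|; direction from value-attribution corr.

    Ties in the ranking are broken lexicographically by feature id.
    """
    if list(attr.values.columns) != list(X.values.columns):
        raise ValidationError("attributions and data must share the feature set")
    mean_abs = attr.values.abs().mean(axis=0)
    ids = np.array(attr.values.columns)
    order = np.lexsort((ids, -mean_abs.to_numpy()))
    total_rank = pd.Series(0, index=attr.values.columns, dtype=int)
    total_rank.iloc[order] = np.arange(1, len(ids) + 1)
    directions = []
    for col in attr.values.columns:
        xv = X.values[col].to_numpy()
        av = attr.values[col].to_numpy()
        if np.std(xv) == 0 or np.std(av) == 0:
            directions.append(0)
        else:
            directions.append(int(np.sign(np.corrcoef(xv, av)[0, 1])))
    return ShapSummary(
        mean_abs=mean_abs,
        direction=pd.Series(directions, index=attr.values.columns),
        total_rank=total_rank,
    )
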