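"""Feature-feature similarity matrices and the kernel mapping transformation.

The mapping smooths each feature toward the features it resembles in an
external cohort before recursive feature elimination. With similarity matrix
S and tuning parameter alpha, the transformation matrix is

    P = D^-1 (I + alpha * (S - I))

where D is the diagonal of row sums of I + alpha*(S - I), so P is
row-stochastic. Data are transformed as X' = X P^T: each mapped feature is a
weighted average of similar features, which spreads the SVM weight evenly
over correlated feature groups and stabilizes elimination order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from maprfe.types import FeatureMatrix, ValidationError, validate_labels

#: The default alpha search grid: 0.01 and 0.05 to 1.00 in steps of 0.05.
DEFAULT_ALPHA_GRID = tuple([0.01] + [round(0.05 * i, 2) for i in range(1, 21)])


@dataclass
class SimilarityMatrix:
    """Symmetric feature x feature similarity with unit diagonal."""

    values: pd.DataFrame
    kind: str  # pearson | bray_curtis

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")
        if self.kind not in ("pearson", "bray_curtis"):
            raise ValidationError(f"unknown similarity kind {self.kind!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MappingOperator:
    """Row-stochastic transformation P = D^-1(I + alpha*(S - I))."""

    P: np.ndarray
    alpha: float
    source_kind: str
    feature_ids: list[str]


def pearson_similarity(X: FeatureMatrix) -> SimilarityMatrix:
    """Pearson correlation between features over samples.

    Zero-variance features get similarity 0 to every other feature (their
    correlation is undefined) and 1 on the diagonal.
    """
    arr = X.values.to_numpy()
    if arr.shape[0] < 2:
        raise ValidationError("need at least 2 samples for Pearson similarity")
    degenerate = arr.max(axis=0) == arr.min(axis=0)  # exactly constant features
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(arr, rowvar=False)
    S = np.atleast_2d(S)
    S[degenerate, :] = 0.0
    S[:, degenerate] = 0.0
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(
        pd.DataFrame(S, index=X.values.columns, columns=X.values.columns), "pearson"
    )


def braycurtis_similarity(X: FeatureMatrix) -> SimilarityMatrix:
    """Bray-Curtis similarity 2*sum(min)/(sum A + sum B) between features.

    Requires nonnegative input (e.g. min-max scaled data). Conventions for
    degenerate features: two all-zero features are identical (similarity 1);
    an all-zero vs a nonzero feature share nothing (similarity 0).
    """
    arr = X.values.to_numpy()
    if arr.size and arr.min() < 0:
        raise ValidationError("Bray-Curtis similarity requires nonnegative data")
    tot = arr.sum(axis=0)
    zero = tot == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(arr.T, metric="braycurtis"))
    S = 1.0 - D
    # scipy yields nan when both vectors are all-zero
    S = np.nan_to_num(S, nan=0.0)
    if zero.any():
        S[zero, :] = 0.0
        S[:, zero] = 0.0
        zz = np.outer(zero, zero)
        S[zz] = 1.0
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(
        pd.DataFrame(S, index=X.values.columns, columns=X.values.columns), "bray_curtis"
    )


def build_mapping(S: SimilarityMatrix, alpha: float) -> MappingOperator:
    """Form P = D^-1(I + alpha*(S - I)); raises if a row sum vanishes."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    arr = S.values.to_numpy()
    n = arr.shape[0]
    M = np.eye(n) + alpha * (arr - np.eye(n))
    row_sums = M.sum(axis=1)
    bad = np.isclose(row_sums, 0.0, atol=1e-12)
    if bad.any():
        feat = S.feature_ids[int(np.argmax(bad))]
        raise ValidationError(
            f"row sum of I + alpha*(S - I) vanishes for feature {feat!r}; "
            "normalization is singular"
        )
    P = M / row_sums[:, None]
    return MappingOperator(P, alpha, S.kind, S.feature_ids)


def apply_mapping(X: FeatureMatrix, op: MappingOperator) -> FeatureMatrix:
    """Transform each sample row x to P x (i.e. X' = X P^T); stage -> mapped."""
    if X.values.shape[1] != op.P.shape[0]:
        raise ValidationError(
            f"feature count {X.values.shape[1]} does not match operator dim {op.P.shape[0]}"
        )
    if op.alpha == 0.0:
        mapped = X.values.to_numpy().copy()  # P = I exactly
    else:
        mapped = X.values.to_numpy() @ op.P.T
    return FeatureMatrix(
        pd.DataFrame(mapped, index=X.values.index, columns=X.values.columns),
        stage="mapped",
    )


def _mapped_arrays(X: np.ndarray, S: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return X
    n = S.shape[0]
    M = np.eye(n) + alpha * (S - np.eye(n))
    P = M / M.sum(axis=1)[:, None]
    return X @ P.T


def tune_alpha(
    X: FeatureMatrix,
    y,
    S: SimilarityMatrix,
    grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[float, list[tuple[float, float]]]:
    """Pick alpha by cross-validated MCC of a linear SVM on mapped data.

    Returns the argmax alpha (ties resolved to the smallest alpha, i.e. the
    least transformation) and the full (alpha, mean MCC) curve.
    """
    if not grid:
        raise ValidationError("alpha grid must be nonempty")
    labels = validate_labels(y)
    if np.bincount(labels).min() < cv_folds:
        raise ValidationError(
            f"smallest class has fewer samples than cv_folds={cv_folds}; "
            "stratified folds would be degenerate"
        )
    arr = X.values.to_numpy()
    Sarr = S.values.to_numpy()
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(arr, labels))
    curve: list[tuple[float, float]] = []
    best_alpha, best_score = None, -np.inf
    for alpha in sorted(grid):
        mapped = _mapped_arrays(arr, Sarr, alpha)
        scores = []
        for tr, te in folds:
            clf = LinearSVC(C=C, random_state=seed)
            clf.fit(mapped[tr], labels[tr])
            scores.append(matthews_corrcoef(labels[te], clf.predict(mapped[te])))
        mean = float(np.mean(scores))
        curve.append((float(alpha), mean))
        if mean > best_score:  # strict: ties keep the smaller alpha
            best_alpha, best_score = float(alpha), mean
    return best_alpha, curve
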