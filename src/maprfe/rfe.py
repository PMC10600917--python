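"""Bootstrapped linear-SVM recursive feature elimination.

Per bootstrap replicate the training data are resampled with replacement
(out-of-bag samples form the internal test set), the SVM regularization
parameter is tuned once by stratified cross-validated MCC, and features are
eliminated one at a time by smallest absolute weight until one remains. The
elimination order, reversed, gives a rank permutation (rank 1 = last
eliminated = most important). Across replicates this yields the rank matrix,
the MCC-vs-feature-count curve with its argmax (the optimal feature number),
and the per-feature global average rank.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from maprfe.mapping import DEFAULT_ALPHA_GRID, SimilarityMatrix, build_mapping, tune_alpha
from maprfe.types import FeatureMatrix, ValidationError, validate_labels

#: Default C grid: 2^-5 .. 2^15, odd powers of two.
DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-5, 16, 2))

_MAX_REDRAWS = 100


class NoConvergenceWarning(UserWarning):
    """The delta-MCC rule found no convergence point on the curve."""


@dataclass
class BootstrapSplit:
    """One bootstrap resample: in-bag training indices and out-of-bag test."""

    replicate_id: int
    internal_train: np.ndarray
    internal_test: np.ndarray
    seed: int


@dataclass
class RfeResult:
    """Everything a bootstrapped RFE run produces."""

    rank_matrix: pd.DataFrame  # features x replicates, each column a permutation
    mcc_mean: np.ndarray | None  # per k = 1..n_features
    mcc_sd: np.ndarray | None
    optimal_k: int | None
    global_rank: pd.Series  # per-feature mean rank, in feature order
    ordering: list[str]  # feature ids sorted by global rank (best first)
    mapping_used: str  # none | pearson | bray_curtis
    tuned_alpha: list[float] | None  # per replicate, when mapping was used
    tuned_C: list[float] = field(default_factory=list)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rank_matrix.to_csv(outdir / "ranks.tsv", sep="\t", index_label="feature_id")
        if self.mcc_mean is not None:
            pd.DataFrame(
                {
                    "k": np.arange(1, len(self.mcc_mean) + 1),
                    "mcc_mean": self.mcc_mean,
                    "mcc_sd": self.mcc_sd,
                }
            ).to_csv(outdir / "mcc_curve.tsv", sep="\t", index=False)
        summary = {
            "optimal_k": self.optimal_k,
            "mapping_used": self.mapping_used,
            "tuned_alpha": self.tuned_alpha,
            "tuned_C": self.tuned_C,
            "ordering": self.ordering,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def make_bootstraps(y, B: int, seed: int = 0) -> list[BootstrapSplit]:
    """Draw B bootstrap resamples; out-of-bag samples are the internal test.

    Draws are repeated (up to 100 times) until both classes appear in both
    the in-bag and out-of-bag parts.
    """
    if B < 2:
        raise ValidationError("need at least B=2 bootstrap replicates")
    labels = validate_labels(y)
    n = len(labels)
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=B)
    splits = []
    for b in range(B):
        rng = np.random.default_rng(rep_seeds[b])
        for attempt in range(_MAX_REDRAWS):
            inbag = np.sort(rng.integers(0, n, size=n))
            oob = np.setdiff1d(np.arange(n), inbag)
            if (
                oob.size > 0
                and len(np.unique(labels[inbag])) == 2
                and len(np.unique(labels[oob])) == 2
            ):
                break
        else:
            raise ValidationError(
                f"replicate {b}: could not draw a bootstrap with both classes "
                f"in-bag and out-of-bag after {_MAX_REDRAWS} attempts"
            )
        splits.append(BootstrapSplit(b, inbag, oob, int(rep_seeds[b])))
    return splits


def _fit_linear_svc(X: np.ndarray, y: np.ndarray, C: float, seed: int) -> LinearSVC:
    """Fit LinearSVC, retrying once with a relaxed tolerance on non-convergence."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf = LinearSVC(C=C, random_state=seed, max_iter=2000)
        clf.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            clf = LinearSVC(C=C, random_state=seed, tol=1e-2, max_iter=10000)
            with warnings.catch_warnings(record=True) as caught2:
                warnings.simplefilter("always", ConvergenceWarning)
                clf.fit(X, y)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught2):
                raise RuntimeError(
                    f"linear SVM failed to converge at C={C} even with relaxed tolerance"
                )
    return clf


def tune_C(
    X: np.ndarray, y: np.ndarray, C_grid=DEFAULT_C_GRID, cv_folds: int = 5, seed: int = 0
) -> float:
    """Pick C maximizing mean stratified-CV MCC; ties keep the smaller C."""
    if len(C_grid) == 1:
        return float(C_grid[0])
    n_folds = min(cv_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        return float(C_grid[0])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_C, best = float(C_grid[0]), -np.inf
    for C in sorted(C_grid):
        scores = []
        for tr, te in folds:
            clf = _fit_linear_svc(X[tr], y[tr], C, seed)
            scores.append(matthews_corrcoef(y[te], clf.predict(X[te])))
        mean = float(np.mean(scores))
        if mean > best:
            best_C, best = float(C), mean
    return best_C


def svm_rfe(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Rank features by recursive elimination of the smallest |SVM weight|.

    C is tuned once on the full internal training set; one feature is removed
    per iteration (ties eliminate the feature later in the current ordering);
    returns ranks 1..n with rank 1 = last eliminated.
    """
    ytr = np.asarray(ytr)
    n_features = Xtr.shape[1]
    if n_features == 1:
        return np.array([1])
    C = tune_C(Xtr, ytr, C_grid, cv_folds, seed)
    remaining = list(range(n_features))
    elimination_order: list[int] = []
    while len(remaining) > 1:
        clf = _fit_linear_svc(Xtr[:, remaining], ytr, C, seed)
        aw = np.abs(clf.coef_[0])
        # ties -> the feature later in the current ordering
        pos = len(aw) - 1 - int(np.argmin(aw[::-1]))
        elimination_order.append(remaining.pop(pos))
    elimination_order.append(remaining[0])
    ranks = np.empty(n_features, dtype=int)
    # first eliminated gets the worst rank n, last eliminated gets rank 1
    for order_pos, feat in enumerate(elimination_order):
        ranks[feat] = n_features - order_pos
    return ranks


def _curve_for_replicate(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, yte: np.ndarray,
    ranks: np.ndarray, C: float, seed: int,
) -> np.ndarray:
    """MCC on the internal test at every top-k, k = 1..n_features."""
    order = np.argsort(ranks, kind="stable")  # rank 1 first
    n = len(ranks)
    out = np.empty(n)
    for k in range(1, n + 1):
        cols = order[:k]
        clf = _fit_linear_svc(Xtr[:, cols], ytr, C, seed)
        out[k - 1] = matthews_corrcoef(yte, clf.predict(Xte[:, cols]))
    return out


def run_bootstrap_rfe(
    X: FeatureMatrix,
    y,
    B: int = 100,
    mapping_kind: str = "none",
    S: SimilarityMatrix | None = None,
    alpha_grid=DEFAULT_ALPHA_GRID,
    C_grid=DEFAULT_C_GRID,
    seed: int = 0,
    compute_curve: bool = True,
    splits: list[BootstrapSplit] | None = None,
) -> RfeResult:
    """Full bootstrapped RFE: optional mapping, ranks, MCC curve, global rank.

    When ``mapping_kind`` is not "none", alpha is tuned within each
    replicate's internal training set and the same operator P transforms both
    the internal training and internal test data. ``splits`` may be supplied
    to share bootstrap draws across pipeline variants.
    """
    if mapping_kind not in ("none", "pearson", "bray_curtis"):
        raise ValidationError(f"unknown mapping kind {mapping_kind!r}")
    if mapping_kind != "none" and S is None:
        raise ValidationError("a similarity matrix is required when mapping is enabled")
    labels = validate_labels(y)
    arr = X.values.to_numpy()
    feature_ids = X.feature_ids
    n_features = arr.shape[1]
    if splits is None:
        splits = make_bootstraps(labels, B, seed)
    B = len(splits)

    rank_cols = np.empty((n_features, B), dtype=int)
    curves = np.empty((B, n_features)) if compute_curve else None
    alphas: list[float] = []
    Cs: list[float] = []
    for b, sp in enumerate(splits):
        Xtr, ytr = arr[sp.internal_train], labels[sp.internal_train]
        Xte, yte = arr[sp.internal_test], labels[sp.internal_test]
        if mapping_kind != "none":
            alpha, _ = tune_alpha(
                FeatureMatrix(
                    pd.DataFrame(Xtr, columns=X.values.columns), stage=X.stage
                ),
                ytr, S, grid=alpha_grid, seed=sp.seed,
            )
            alphas.append(alpha)
            if alpha > 0.0:
                P = build_mapping(S, alpha).P
                Xtr = Xtr @ P.T
                Xte = Xte @ P.T
        C = tune_C(Xtr, ytr, C_grid, 5, sp.seed)
        Cs.append(C)
        ranks = svm_rfe(Xtr, ytr, C_grid=(C,), seed=sp.seed)
        rank_cols[:, b] = ranks
        if compute_curve:
            curves[b] = _curve_for_replicate(Xtr, ytr, Xte, yte, ranks, C, sp.seed)

    rank_matrix = pd.DataFrame(
        rank_cols, index=pd.Index(feature_ids, name="feature_id"),
        columns=[f"bootstrap_{b:03d}" for b in range(B)],
    )
    if compute_curve:
        mcc_mean = curves.mean(axis=0)
        mcc_sd = curves.std(axis=0, ddof=0)
        optimal_k = int(np.argmax(mcc_mean)) + 1  # argmax -> smallest k on ties
    else:
        mcc_mean = mcc_sd = optimal_k = None
    global_rank = rank_matrix.mean(axis=1)
    order = np.lexsort((np.array(feature_ids), global_rank.to_numpy()))
    ordering = [feature_ids[i] for i in order]
    return RfeResult(
        rank_matrix=rank_matrix,
        mcc_mean=mcc_mean,
        mcc_sd=mcc_sd,
        optimal_k=optimal_k,
        global_rank=global_rank,
        ordering=ordering,
        mapping_used=mapping_kind,
        tuned_alpha=alphas if mapping_kind != "none" else None,
        tuned_C=Cs,
    )


def top_k_by_delta_mcc(
    mcc_mean: np.ndarray, epsilon: float = 0.005, window: int = 5
) -> int:
    """Smallest k after which the MCC curve stops changing.

    delta(k) = mean MCC(k) - mean MCC(k-1); returns the smallest k such that
    |delta| < epsilon for all of the next ``window`` steps. If the curve
    never settles, returns n_features and emits :class:`NoConvergenceWarning`.
    """
    curve = np.asarray(mcc_mean, dtype=float)
    n = len(curve)
    if n < window + 1:
        raise ValidationError(f"curve of length {n} is too short for window={window}")
    delta = np.abs(np.diff(curve))  # delta[i] = |MCC(i+2) - MCC(i+1)| at k=i+2
    for k in range(1, n - window + 1):
        # deltas at k+1 .. k+window are delta[k-1 .. k+window-2]
        if np.all(delta[k - 1 : k + window - 1] < epsilon):
            return k
    warnings.warn(
        "delta-MCC never stayed below epsilon; returning the full feature count",
        NoConvergenceWarning,
        stacklevel=2,
    )
    return n
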