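"""Rank-stability evaluation of bootstrapped feature selection.

Five pairwise indexes are computed between the rank permutations of every
pair of bootstrap replicates and averaged over all B(B-1)/2 pairs: Spearman
rank correlation (closed form for distinct integer ranks), Pearson
correlation of the rank vectors, Hamming distance (fraction of disagreeing
positions), Bray-Curtis dissimilarity of the rank vectors, and Euclidean
distance. A common-feature curve counts, for each top-r cutoff, the features
present in the top-r set of at least a threshold number of replicates. The
noise-injection experiment appends uniform-noise features and measures how
far down the ranking they land.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from maprfe.mapping import SimilarityMatrix, DEFAULT_ALPHA_GRID
from maprfe.rfe import DEFAULT_C_GRID, run_bootstrap_rfe
from maprfe.types import FeatureMatrix, ValidationError


def _check_permutation(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    n = len(a)
    if n < 2 or not np.array_equal(np.sort(a), np.arange(1, n + 1)):
        raise ValidationError("rank vector must be a permutation of 1..n with n >= 2")
    return a


def srcc(a, b) -> float:
    """Spearman rank correlation for distinct integer ranks: 1 - 6*sum(d^2)/(n^3-n)."""
    a, b = _check_permutation(a), _check_permutation(b)
    if len(a) != len(b):
        raise ValidationError("rank vectors must have equal length")
    n = len(a)
    d2 = float(np.sum((a - b) ** 2))
    return 1.0 - 6.0 * d2 / (n**3 - n)


def hamming(a, b) -> float:
    """Fraction of positions where the two rank vectors disagree."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("rank vectors must have equal length")
    return float(np.mean(a != b))


def rank_pearson(a, b) -> float:
    """Pearson correlation of two rank vectors (equals SRCC on permutations)."""
    a, b = _check_permutation(a), _check_permutation(b)
    return float(np.corrcoef(a, b)[0, 1])


def rank_braycurtis_dissim(a, b) -> float:
    """1 - Bray-Curtis similarity of the two rank vectors."""
    a, b = _check_permutation(a), _check_permutation(b)
    return 1.0 - 2.0 * float(np.minimum(a, b).sum()) / float(a.sum() + b.sum())


def rank_euclidean(a, b) -> float:
    """Euclidean distance between the two rank vectors."""
    a, b = _check_permutation(a), _check_permutation(b)
    return float(np.sqrt(np.sum((a - b) ** 2)))


@dataclass
class StabilityReport:
    """Pairwise rank-stability indexes averaged over all replicate pairs."""

    srcc: float
    pearson: float
    hamming: float
    bray_curtis_dissimilarity: float
    euclidean: float
    n_pairs: int

    def as_dict(self) -> dict:
        return {
            "srcc": self.srcc,
            "pearson": self.pearson,
            "hamming": self.hamming,
            "bray_curtis_dissimilarity": self.bray_curtis_dissimilarity,
            "euclidean": self.euclidean,
            "n_pairs": self.n_pairs,
        }


def pairwise_stability(rank_matrix: pd.DataFrame) -> StabilityReport:
    """Average each stability index over all unordered replicate pairs."""
    R = rank_matrix.to_numpy()
    n, B = R.shape
    if B < 2:
        raise ValidationError("need at least 2 replicates")
    for b in range(B):
        _check_permutation(R[:, b])
    pairs = list(combinations(range(B), 2))
    sq = (R.astype(float) ** 2).sum(axis=0)
    G = R.T.astype(float) @ R
    half = n * (n + 1) / 2.0
    s_srcc = s_pear = s_ham = s_bc = s_euc = 0.0
    C = np.corrcoef(R.T)
    for i, j in pairs:
        d2 = sq[i] + sq[j] - 2.0 * G[i, j]
        s_srcc += 1.0 - 6.0 * d2 / (n**3 - n)
        s_pear += C[i, j]
        s_ham += np.mean(R[:, i] != R[:, j])
        s_bc += 1.0 - np.minimum(R[:, i], R[:, j]).sum() / half
        s_euc += np.sqrt(d2)
    m = len(pairs)
    return StabilityReport(
        srcc=s_srcc / m,
        pearson=s_pear / m,
        hamming=s_ham / m,
        bray_curtis_dissimilarity=s_bc / m,
        euclidean=s_euc / m,
        n_pairs=m,
    )


@dataclass
class CommonFeatureCurve:
    """Number of consistently top-ranked features as the cutoff r grows."""

    threshold: int  # minimum replicates whose top-r set must contain the feature
    counts: np.ndarray  # per r = 1..n_features


def common_feature_curve(rank_matrix: pd.DataFrame, threshold: int | str) -> CommonFeatureCurve:
    """Count features in the top-r set of at least ``threshold`` replicates.

    ``threshold`` may be "all" (every replicate) or an integer <= B.
    """
    R = rank_matrix.to_numpy()
    n, B = R.shape
    if threshold == "all":
        threshold = B
    threshold = int(threshold)
    if not 1 <= threshold <= B:
        raise ValidationError(f"threshold must lie in 1..{B}")
    # a feature is counted at cutoff r iff its threshold-th smallest rank <= r
    kth = np.sort(R, axis=1)[:, threshold - 1]
    rs = np.arange(1, n + 1)
    counts = (kth[None, :] <= rs[:, None]).sum(axis=1)
    return CommonFeatureCurve(threshold=threshold, counts=counts)


@dataclass
class NoiseEvalResult:
    """Outcome of the noise-injection filtering experiment."""

    noise_filter_score: float  # avg rank of noise - avg rank of real features
    n_noise: int
    mapping_kind: str
    mean_rank_real: float
    mean_rank_noise: float


def noise_filter_experiment(
    X: FeatureMatrix,
    y,
    n_noise: int = 100,
    mapping_kind: str = "none",
    S: SimilarityMatrix | None = None,
    B: int = 100,
    alpha_grid=DEFAULT_ALPHA_GRID,
    C_grid=DEFAULT_C_GRID,
    seed: int = 0,
) -> NoiseEvalResult:
    """Append uniform(0,1) noise features, rerun RFE, and score the demotion.

    The score is the mean global rank of the injected noise features minus
    the mean global rank of the real features; positive values mean noise is
    correctly pushed to the bottom of the ranking. The similarity matrix is
    extended with zero off-diagonal rows/columns for the noise features
    (uniform noise is uncorrelated with everything in expectation).
    """
    if n_noise < 1:
        raise ValidationError("n_noise must be at least 1")
    if X.stage not in ("scaled",):
        raise ValidationError("noise injection expects min-max scaled data (stage='scaled')")
    rng = np.random.default_rng(seed)
    n, p = X.values.shape
    noise = rng.uniform(0.0, 1.0, size=(n, n_noise))
    noise_ids = [f"noise_{j:04d}" for j in range(n_noise)]
    aug = pd.concat(
        [X.values, pd.DataFrame(noise, index=X.values.index, columns=noise_ids)], axis=1
    )
    X_aug = FeatureMatrix(aug, stage="noise_augmented")
    S_aug = None
    if mapping_kind != "none":
        if S is None:
            raise ValidationError("a similarity matrix is required when mapping is enabled")
        big = np.eye(p + n_noise)
        big[:p, :p] = S.values.to_numpy()
        S_aug = SimilarityMatrix(
            pd.DataFrame(big, index=aug.columns, columns=aug.columns), S.kind
        )
    result = run_bootstrap_rfe(
        X_aug, y, B=B, mapping_kind=mapping_kind, S=S_aug,
        alpha_grid=alpha_grid, C_grid=C_grid, seed=seed, compute_curve=False,
    )
    gr = result.global_rank
    mean_noise = float(gr.loc[noise_ids].mean())
    mean_real = float(gr.drop(index=noise_ids).mean())
    return NoiseEvalResult(
        noise_filter_score=mean_noise - mean_real,
        n_noise=n_noise,
        mapping_kind=mapping_kind,
        mean_rank_real=mean_real,
        mean_rank_noise=mean_noise,
    )
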