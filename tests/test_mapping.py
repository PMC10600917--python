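"""Similarity matrices and the kernel mapping P = D^-1(I + alpha(S - I))."""

import numpy as np
import pandas as pd
import pytest

from maprfe.mapping import (
    DEFAULT_ALPHA_GRID,
    SimilarityMatrix,
    apply_mapping,
    braycurtis_similarity,
    build_mapping,
    pearson_similarity,
    tune_alpha,
)
from maprfe.types import ValidationError
from tests.conftest import make_features


def _brute_pearson(arr):
    n, p = arr.shape
    S = np.eye(p)
    for a in range(p):
        for b in range(p):
            if a == b:
                continue
            A, B = arr[:, a], arr[:, b]
            cov = np.mean((A - A.mean()) * (B - B.mean()))
            S[a, b] = cov / (A.std() * B.std())
    return S


def _brute_braycurtis(arr):
    p = arr.shape[1]
    S = np.eye(p)
    for a in range(p):
        for b in range(p):
            A, B = arr[:, a], arr[:, b]
            S[a, b] = 2 * np.minimum(A, B).sum() / (A.sum() + B.sum())
    return S


class TestPearsonSimilarity:
    def test_perfect_linear_and_antilinear(self):
        X = make_features(np.array([[1, 2, 3], [2, 4, 2], [3, 6, 1]]).astype(float))
        S = pearson_similarity(X).values.to_numpy()
        assert S[0, 1] == pytest.approx(1.0)
        assert S[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        arr = rng.random((20, 5))
        S = pearson_similarity(make_features(arr)).values.to_numpy()
        assert np.allclose(S, _brute_pearson(arr), atol=1e-12)

    def test_zero_variance_feature_gets_zero(self, rng):
        arr = rng.random((10, 3))
        arr[:, 1] = 0.7
        S = pearson_similarity(make_features(arr)).values.to_numpy()
        assert S[1, 0] == 0.0 and S[1, 2] == 0.0 and S[1, 1] == 1.0
        assert np.all(np.isfinite(S))


class TestBrayCurtisSimilarity:
    def test_identical_vectors(self):
        X = make_features(np.array([[0.2, 0.2], [0.8, 0.8]]))
        assert braycurtis_similarity(X).values.to_numpy()[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # A=[1,2,3], B=[3,2,1] -> 2(1+2+1)/(6+6) = 2/3
        X = make_features(np.array([[1, 3], [2, 2], [3, 1]]).astype(float))
        assert braycurtis_similarity(X).values.to_numpy()[0, 1] == pytest.approx(2 / 3)

    def test_disjoint_supports(self):
        X = make_features(np.array([[1, 0], [0, 1]]).astype(float))
        assert braycurtis_similarity(X).values.to_numpy()[0, 1] == pytest.approx(0.0)

    def test_zero_vector_conventions(self):
        X = make_features(np.array([[0, 0, 1], [0, 0, 2]]).astype(float))
        S = braycurtis_similarity(X).values.to_numpy()
        assert S[0, 1] == pytest.approx(1.0)  # two all-zero features: identical
        assert S[0, 2] == pytest.approx(0.0)  # zero vs nonzero: nothing shared
        assert np.all(np.diag(S) == 1.0)

    def test_matches_direct_formula(self, rng):
        arr = rng.random((15, 30))
        S = braycurtis_similarity(make_features(arr)).values.to_numpy()
        assert np.allclose(S, _brute_braycurtis(arr), atol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            braycurtis_similarity(make_features([[-1.0, 1.0]], stage="log_transformed"))


def _random_similarity(rng, p=10):
    arr = rng.random((30, p))
    return braycurtis_similarity(make_features(arr))


class TestBuildMapping:
    def test_alpha_zero_gives_identity(self, rng):
        S = _random_similarity(rng)
        P = build_mapping(S, 0.0).P
        assert np.array_equal(P, np.eye(10))

    def test_worked_two_by_two_example(self):
        S = SimilarityMatrix(
            pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"]),
            "bray_curtis",
        )
        P = build_mapping(S, 0.2).P
        expected = np.array([[10 / 11, 1 / 11], [1 / 11, 10 / 11]])
        assert np.allclose(P, expected, atol=1e-15)

    def test_row_stochastic_across_grid(self, rng):
        for _ in range(5):
            S = _random_similarity(rng)
            for alpha in DEFAULT_ALPHA_GRID:
                P = build_mapping(S, alpha).P
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_singular_row_sum_names_the_feature(self):
        # with strongly negative Pearson entries a row sum can vanish
        S = SimilarityMatrix(
            pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=["fA", "fB"], columns=["fA", "fB"]),
            "pearson",
        )
        with pytest.raises(ValidationError, match="fA"):
            build_mapping(S, 1.0)


class TestApplyMapping:
    def test_identity_operator_is_identity(self, rng):
        S = _random_similarity(rng)
        X = make_features(rng.random((6, 10)))
        out = apply_mapping(X, build_mapping(S, 0.0))
        assert np.array_equal(out.values.to_numpy(), X.values.to_numpy())
        assert out.stage == "mapped"

    def test_matches_double_loop(self, rng):
        S = _random_similarity(rng, p=7)
        op = build_mapping(S, 0.6)
        arr = rng.random((5, 7))
        out = apply_mapping(make_features(arr), op).values.to_numpy()
        expected = np.empty_like(out)
        for i in range(5):
            for j in range(7):
                expected[i, j] = sum(op.P[j, k] * arr[i, k] for k in range(7))
        assert np.allclose(out, expected, atol=1e-12)

    def test_linearity(self, rng):
        S = _random_similarity(rng, p=6)
        op = build_mapping(S, 0.4)
        a, b = rng.random((4, 6)), rng.random((4, 6))
        lhs = apply_mapping(make_features(a + b), op).values.to_numpy()
        rhs = (
            apply_mapping(make_features(a), op).values.to_numpy()
            + apply_mapping(make_features(b), op).values.to_numpy()
        )
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_constant_rows_are_fixed_points(self, rng):
        S = _random_similarity(rng, p=6)
        op = build_mapping(S, 0.7)
        const = np.full((3, 6), 0.42)
        out = apply_mapping(make_features(const), op).values.to_numpy()
        assert np.allclose(out, const, atol=1e-12)
        assert np.allclose(out.var(axis=1), 0.0, atol=1e-24)

    def test_dimension_mismatch(self, rng):
        S = _random_similarity(rng, p=6)
        with pytest.raises(ValidationError):
            apply_mapping(make_features(rng.random((3, 5))), build_mapping(S, 0.5))


class TestTuneAlpha:
    def test_grid_of_length_one(self, rng, separable_task):
        X, y = separable_task(0)
        S = braycurtis_similarity(X)
        alpha, curve = tune_alpha(X, y, S, grid=(0.25,), seed=0)
        assert alpha == 0.25 and len(curve) == 1

    def test_iid_features_flat_curve_ties_to_smallest_alpha(self, separable_task):
        # with S ~ I the mapping barely changes the data; ties resolve down
        for seed in range(3):
            X, y = separable_task(seed)
            S = SimilarityMatrix(
                pd.DataFrame(np.eye(5), index=X.feature_ids, columns=X.feature_ids),
                "bray_curtis",
            )
            alpha, curve = tune_alpha(X, y, S, grid=(0.0, 0.3, 0.9), seed=seed)
            scores = [s for _, s in curve]
            assert max(scores) - min(scores) < 1e-9  # S=I: mapping is exactly inert
            assert alpha == 0.0

    def test_degenerate_stratification_rejected(self, rng):
        X = make_features(rng.random((8, 3)))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])  # 1 case < 5 folds
        S = braycurtis_similarity(X)
        with pytest.raises(ValidationError):
            tune_alpha(X, y, S, grid=(0.1,), seed=0)
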