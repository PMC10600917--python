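"""Preprocessing chain: aggregation, filtering, clr transform, split, scaling."""

import numpy as np
import pandas as pd
import pytest

from maprfe.preprocess import (
    EmptyResultError,
    aggregate_taxa,
    apply_minmax,
    clr_log_transform,
    fit_minmax,
    intersect_features,
    prevalence_filter,
    stratified_split,
)
from maprfe.types import ValidationError
from tests.conftest import make_counts, make_features


def _lineage(genus, species=""):
    return ["Bacteria", "ph", "cl", "or", "fa", genus, species]


class TestAggregateTaxa:
    def test_same_species_counts_are_summed(self):
        cm = make_counts(
            [[3, 2], [5, 0]],
            taxon_ids=["otu1", "otu2"],
            taxonomy=[_lineage("Bacteroides", "fragilis")] * 2,
        )
        out = aggregate_taxa(cm, "species")
        assert out.shape == (2, 1)
        assert out.counts.iloc[:, 0].tolist() == [5, 5]

    def test_genus_level_conserves_sample_totals(self):
        cm = make_counts(
            [[1, 2, 3, 4], [0, 5, 0, 7]],
            taxonomy=[
                _lineage("A", "x"), _lineage("A", "y"),
                _lineage("B", "x"), _lineage("B", "z"),
            ],
        )
        out = aggregate_taxa(cm, "genus")
        assert out.shape[1] == 2
        assert out.counts.sum(axis=1).tolist() == cm.counts.sum(axis=1).tolist()

    def test_matches_brute_force_group_by(self, rng):
        genera = ["G1", "G2", "G3"]
        species = ["s1", "s2"]
        taxonomy = [
            _lineage(genera[j % 3], species[j % 2]) for j in range(10)
        ]
        counts = rng.integers(0, 20, size=(6, 10))
        cm = make_counts(counts, taxonomy=taxonomy)
        out = aggregate_taxa(cm, "species")
        # independent oracle: dict-based group-by over full truncated lineages
        groups = {}
        for j in range(10):
            key = tuple(taxonomy[j][:7])
            groups.setdefault(key, np.zeros(6, dtype=int))
            groups[key] += counts[:, j]
        assert out.shape[1] == len(groups)
        for key, expected in groups.items():
            col = [
                c for c in out.counts.columns
                if f"g:{key[5]};s:{key[6]}" in c
            ]
            assert len(col) == 1
            assert out.counts[col[0]].tolist() == expected.tolist()

    def test_unknown_rank_rejected(self):
        cm = make_counts([[1]], taxonomy=[_lineage("A")])
        with pytest.raises(ValidationError):
            aggregate_taxa(cm, "strain")


class TestPrevalenceFilter:
    def test_boundary_semantics(self):
        # 100 samples; taxon A all zeros (frac 1.0) removed, taxon B with
        # exactly 99 zeros (frac 0.99) kept under the <= comparison
        col_a = np.zeros(100, dtype=int)
        col_b = np.zeros(100, dtype=int)
        col_b[0] = 5
        cm = make_counts(np.column_stack([col_a, col_b]), taxon_ids=["A", "B"])
        out = prevalence_filter(cm, 0.99)
        assert out.taxon_ids == ["B"]

    def test_matches_zero_counting_oracle(self, rng):
        counts = (rng.random((50, 30)) < 0.2) * rng.integers(1, 9, size=(50, 30))
        cm = make_counts(counts)
        threshold = 0.85
        out = prevalence_filter(cm, threshold)
        expected = [
            f"t{j}" for j in range(30)
            if sum(1 for v in counts[:, j] if v == 0) / 50 <= threshold
        ]
        assert out.taxon_ids == expected

    def test_identity_and_strict_limits(self, rng):
        counts = rng.integers(0, 3, size=(20, 10))
        counts[:, 0] = 1  # one taxon with no zeros
        cm = make_counts(counts)
        assert prevalence_filter(cm, 1.0).taxon_ids == cm.taxon_ids
        strict = prevalence_filter(cm, 0.0)
        assert all((cm.counts[t] > 0).all() for t in strict.taxon_ids)

    def test_all_removed_is_an_error(self):
        cm = make_counts(np.zeros((10, 3), dtype=int))
        with pytest.raises(EmptyResultError):
            prevalence_filter(cm, 0.5)


class TestClrTransform:
    def test_constant_sample_maps_to_zero(self):
        out = clr_log_transform(make_counts([[1, 1, 1, 1]]))
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_hand_computed_two_entry_sample(self):
        # counts [0, 3], pseudocount c = 3 -> shifted [3, 6], geometric
        # mean sqrt(18); values log2(3/sqrt(18)), log2(6/sqrt(18))
        out = clr_log_transform(make_counts([[0, 3]]))
        g = np.sqrt(3 * 6)
        expected = [np.log2(3 / g), np.log2(6 / g)]
        assert np.allclose(out.values.to_numpy()[0], expected)
        assert abs(out.values.to_numpy()[0].sum()) < 1e-9

    def test_rows_sum_to_zero_on_random_tables(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 50, size=(8, 12))
            if counts.max() == 0:
                continue
            out = clr_log_transform(make_counts(counts))
            assert np.allclose(out.values.sum(axis=1), 0.0, atol=1e-9)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            clr_log_transform(make_counts(np.zeros((3, 3), dtype=int)))


class TestIntersectFeatures:
    def test_pairwise_intersection(self):
        a = make_counts([[1, 2, 3]], taxon_ids=["A", "B", "C"])
        b = make_counts([[4, 5, 6]], taxon_ids=["B", "C", "D"])
        out = intersect_features([a, b])
        assert out[0].taxon_ids == out[1].taxon_ids == ["B", "C"]

    def test_triple_intersection_matches_set_oracle(self, rng):
        universe = [f"x{j}" for j in range(12)]
        tables, kept = [], []
        for _ in range(3):
            ids = sorted(rng.choice(universe, size=8, replace=False))
            kept.append(set(ids))
            tables.append(make_counts(rng.integers(0, 5, size=(4, 8)), taxon_ids=ids))
        out = intersect_features(tables)
        expected = sorted(kept[0] & kept[1] & kept[2])
        assert all(t.taxon_ids == expected for t in out)

    def test_empty_intersection_is_an_error(self):
        a = make_counts([[1]], taxon_ids=["A"])
        b = make_counts([[1]], taxon_ids=["B"])
        with pytest.raises(EmptyResultError):
            intersect_features([a, b])


class TestStratifiedSplit:
    def test_proportions_and_determinism(self):
        y = np.zeros(100, dtype=int)
        y[:45] = 1
        X = make_features(np.random.default_rng(0).random((100, 3)))
        tr, te = stratified_split(X, y, 0.2, seed=7)
        assert len(te) == 20 and y[te].sum() == 9
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == 100
        tr2, te2 = stratified_split(X, y, 0.2, seed=7)
        assert np.array_equal(tr, tr2) and np.array_equal(te, te2)

    def test_exact_stratification_on_four_samples(self):
        y = np.array([0, 1, 0, 1])
        X = make_features(np.eye(4))
        tr, te = stratified_split(X, y, 0.5, seed=0)
        assert len(tr) == len(te) == 2
        assert y[tr].sum() == y[te].sum() == 1

    def test_tiny_class_rejected(self):
        X = make_features(np.ones((3, 2)))
        with pytest.raises(ValidationError):
            stratified_split(X, np.array([1, 0, 0]), 0.3, seed=0)


class TestMinMax:
    def test_affine_map_and_constant_feature(self):
        X = make_features(np.array([[2.0, 5.0], [4.0, 5.0], [6.0, 5.0]]), stage="log_transformed")
        scaled = apply_minmax(X, fit_minmax(X))
        assert scaled.values.iloc[:, 0].tolist() == [0.0, 0.5, 1.0]
        assert scaled.values.iloc[:, 1].tolist() == [0.0, 0.0, 0.0]
        assert scaled.stage == "scaled"

    def test_new_data_is_clipped(self):
        X = make_features(np.array([[2.0], [6.0]]), stage="log_transformed")
        state = fit_minmax(X)
        new = make_features(np.array([[8.0], [0.0]]), stage="log_transformed")
        out = apply_minmax(new, state)
        assert out.values.iloc[:, 0].tolist() == [1.0, 0.0]

    def test_idempotent_on_scaled_training_data(self, rng):
        X = make_features(rng.random((10, 4)) * 5 - 2, stage="log_transformed")
        scaled = apply_minmax(X, fit_minmax(X))
        again = apply_minmax(scaled, fit_minmax(scaled))
        assert np.allclose(scaled.values.to_numpy(), again.values.to_numpy())
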