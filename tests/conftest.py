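import numpy as np
import pandas as pd
import pytest

from maprfe.types import TAXONOMIC_RANKS, CountMatrix, FeatureMatrix


def make_counts(values, sample_ids=None, taxon_ids=None, taxonomy=None):
    values = np.asarray(values)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    taxon_ids = taxon_ids or [f"t{j}" for j in range(p)]
    df = pd.DataFrame(values, index=sample_ids, columns=taxon_ids)
    tax = None
    if taxonomy is not None:
        tax = pd.DataFrame(taxonomy, index=taxon_ids, columns=list(TAXONOMIC_RANKS))
    return CountMatrix(df, tax)


def make_features(values, stage="scaled", feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feature_ids = feature_ids or [f"f{j}" for j in range(p)]
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(n)], columns=feature_ids)
    return FeatureMatrix(df, stage=stage)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_task():
    """Two well-separated Gaussian classes in 5 dimensions."""
    def _make(seed, n=160):
        r = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = r.normal(0, 1, size=(n, 5))
        X[y == 1, :2] += 4.0
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        perm = r.permutation(n)
        return make_features(X[perm]), y[perm]
    return _make
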