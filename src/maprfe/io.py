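"""Readers and writers for abundance tables, taxonomy, metadata and ranks.

TSV dialect: samples as rows, features as columns, header row, tab-separated.
BIOM 1.0 (JSON) abundance tables are accepted for counts; the BIOM
orientation (observations x samples) is transposed on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from maprfe.types import TAXONOMIC_RANKS, CountMatrix, FeatureMatrix

LABEL_MAP = {
    "ibd": 1, "case": 1, "1": 1, "disease": 1, "true": 1,
    "nonibd": 0, "non-ibd": 0, "control": 0, "healthy": 0, "0": 0, "false": 0,
}


class ParseError(ValueError):
    """Raised on malformed input files; the message names the offending record."""


def _check_unique(index: pd.Index, what: str, path) -> None:
    if not index.is_unique:
        dups = index[index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate {what}: {dups}")


def read_abundance(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a sample x taxon count table from TSV or BIOM-JSON."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique(df.index, "sample ids", path)
        _check_unique(df.columns, "taxon ids", path)
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise ParseError(f"{path}: non-numeric counts in columns {list(bad)[:5]}")
        if np.any(arr != np.floor(arr)):
            i, j = np.argwhere(arr != np.floor(arr))[0]
            raise ParseError(
                f"{path}: non-integer count at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        return CountMatrix(df.astype(np.int64))
    if format == "biom":
        return _read_biom_json(path)
    raise ParseError(f"unknown abundance format {format!r}; expected 'tsv' or 'biom'")


def _read_biom_json(path: Path) -> CountMatrix:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        n_obs, n_samp = doc["shape"]
        obs_ids = [r["id"] for r in doc["rows"]]
        samp_ids = [c["id"] for c in doc["columns"]]
        dense = np.zeros((n_obs, n_samp))
        if doc["matrix_type"] == "dense":
            dense[:] = np.asarray(doc["data"], dtype=float)
        elif doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                dense[int(i), int(j)] = v
        else:
            raise ParseError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: malformed BIOM JSON ({exc})") from exc
    df = pd.DataFrame(dense.T, index=pd.Index(samp_ids), columns=pd.Index(obs_ids))
    _check_unique(df.index, "sample ids", path)
    _check_unique(df.columns, "taxon ids", path)
    if np.any(dense != np.floor(dense)):
        raise ParseError(f"{path}: non-integer counts in BIOM data")
    taxonomy = None
    if doc["rows"] and doc["rows"][0].get("metadata") and "taxonomy" in doc["rows"][0]["metadata"]:
        rows = []
        for r in doc["rows"]:
            lineage = list(r["metadata"].get("taxonomy") or [])
            lineage = (lineage + [""] * 7)[:7]
            rows.append(lineage)
        taxonomy = pd.DataFrame(rows, index=df.columns, columns=list(TAXONOMIC_RANKS))
    return CountMatrix(df.astype(np.int64), taxonomy)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a TSV taxonomy table: taxon_id column + the 7 rank columns."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    missing = [c for c in TAXONOMIC_RANKS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: taxonomy missing rank columns {missing}")
    _check_unique(df.index, "taxon ids", path)
    return df[list(TAXONOMIC_RANKS)]


def read_metadata(path: str | Path, label_column: str = "label") -> pd.Series:
    """Read per-sample binary labels (1 = case, 0 = control) from TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "sample ids", path)
    if label_column not in df.columns:
        raise ParseError(f"{path}: no column {label_column!r} (found {list(df.columns)})")
    raw = df[label_column]
    mapped = []
    for sid, val in raw.items():
        key = str(val).strip().lower()
        if key not in LABEL_MAP:
            raise ParseError(f"{path}: unrecognized label {val!r} for sample {sid!r}")
        mapped.append(LABEL_MAP[key])
    return pd.Series(mapped, index=df.index, name="label", dtype=int)


def write_abundance(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="sample_id")


def write_taxonomy(cm: CountMatrix, path: str | Path) -> None:
    if cm.taxonomy is None:
        raise ParseError("count matrix has no taxonomy to write")
    cm.taxonomy.to_csv(path, sep="\t", index_label="taxon_id")


def write_feature_matrix(X: FeatureMatrix, path: str | Path) -> None:
    X.values.to_csv(path, sep="\t", index_label="sample_id")


def read_feature_matrix(path: str | Path, stage: str = "log_transformed") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "sample ids", path)
    _check_unique(df.columns, "feature ids", path)
    return FeatureMatrix(df, stage=stage)


def write_labels(y: pd.Series, path: str | Path) -> None:
    y.rename("label").to_csv(path, sep="\t", index_label="sample_id")


def write_ranks(ranks: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x replicate rank matrix as TSV."""
    ranks.to_csv(path, sep="\t", index_label="feature_id")


def read_ranks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "feature ids", path)
    return df.astype(int)
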