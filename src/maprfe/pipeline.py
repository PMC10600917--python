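"""End-to-end orchestration: simulate -> preprocess -> similarity -> RFE ->
stability -> classify -> explain, with a single config and run manifests.

Every stochastic stage carries an explicit seed in the config; rerunning the
same config reproduces all deterministic outputs bit-for-bit.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import maprfe
from maprfe import io as mio
from maprfe.classifiers import default_model_specs, evaluate_suite, build_and_tune, predict_scores, ModelSpec
from maprfe.mapping import (
    DEFAULT_ALPHA_GRID,
    SimilarityMatrix,
    braycurtis_similarity,
    pearson_similarity,
)
from maprfe.preprocess import (
    apply_minmax,
    clr_log_transform,
    fit_minmax,
    prevalence_filter,
    stratified_split,
)
from maprfe.rfe import DEFAULT_C_GRID, make_bootstraps, run_bootstrap_rfe, top_k_by_delta_mcc
from maprfe.shapley import explain_samples, shap_summary
from maprfe.simulate import SyntheticConfig, config_from_dict, config_to_dict, generate_cohort, generate_external
from maprfe.stability import noise_filter_experiment, pairwise_stability
from maprfe.types import CountMatrix, FeatureMatrix, ValidationError

_REQUIRED_SEEDS = ("simulate", "split", "bootstrap", "noise", "classify", "explain")


@dataclass
class RunConfig:
    """Reproducible description of one full pipeline run."""

    simulation: dict = field(default_factory=dict)
    abundance_path: str | None = None
    metadata_path: str | None = None
    external_path: str | None = None
    mapping_kind: str = "bray_curtis"  # none | pearson | bray_curtis
    alpha_grid: list[float] = field(default_factory=lambda: list(DEFAULT_ALPHA_GRID))
    C_grid: list[float] = field(default_factory=lambda: list(DEFAULT_C_GRID))
    bootstraps: int = 100
    test_fraction: float = 0.2
    max_zero_fraction: float = 0.99
    models: list[str] = field(default_factory=lambda: [s.algorithm for s in default_model_specs()])
    delta_mcc_epsilon: float = 0.005
    delta_mcc_window: int = 5
    n_noise: int = 100
    run_noise_eval: bool = False
    shap_model: str = "random_forest"
    seeds: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [k for k in _REQUIRED_SEEDS if k not in self.seeds]
        if missing:
            raise ValidationError(f"config is missing seeds for stages: {missing}")
        if self.mapping_kind not in ("none", "pearson", "bray_curtis"):
            raise ValidationError(f"unknown mapping kind {self.mapping_kind!r}")
        if not self.simulation and not (self.abundance_path and self.metadata_path):
            raise ValidationError("config needs either a simulation block or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _load_inputs(cfg: RunConfig) -> tuple[CountMatrix, pd.Series, CountMatrix | None]:
    if cfg.simulation:
        sim = config_from_dict({**cfg.simulation, "seed": cfg.seeds["simulate"]})
        counts, y, _truth = generate_cohort(sim)
        external = generate_external(sim, seed2=cfg.seeds["simulate"] + 1)
        return counts, y, external
    counts = mio.read_abundance(cfg.abundance_path)
    y = mio.read_metadata(cfg.metadata_path).reindex(counts.counts.index)
    external = mio.read_abundance(cfg.external_path) if cfg.external_path else None
    return counts, y, external


def preprocess_cohort(
    counts: CountMatrix, max_zero_fraction: float = 0.99
) -> FeatureMatrix:
    """Prevalence filter + clr-style log transform for one cohort."""
    filtered = prevalence_filter(counts, max_zero_fraction)
    return clr_log_transform(filtered)


def external_similarity(
    external: CountMatrix, feature_ids: list[str], kind: str,
    max_zero_fraction: float = 0.99,
) -> SimilarityMatrix:
    """Similarity matrix from an external cohort restricted to the working features.

    The external cohort passes the same preprocess chain (filter on its own
    sparsity, clr, min-max on itself), then is restricted and ordered to the
    working feature set before the similarity is computed.
    """
    logged = preprocess_cohort(external, max_zero_fraction)
    missing = [f for f in feature_ids if f not in logged.values.columns]
    if missing:
        # features absent after the external filter: fall back to unfiltered clr
        logged = clr_log_transform(external)
        missing = [f for f in feature_ids if f not in logged.values.columns]
        if missing:
            raise ValidationError(f"external cohort lacks working features: {missing[:5]}")
    sub = FeatureMatrix(logged.values[feature_ids], stage="log_transformed")
    scaled = apply_minmax(sub, fit_minmax(sub))
    if kind == "pearson":
        return pearson_similarity(scaled)
    if kind == "bray_curtis":
        return braycurtis_similarity(scaled)
    raise ValidationError(f"unknown similarity kind {kind!r}")


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage, writing intermediate artifacts and a manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "config": asdict(cfg),
        "package_version": maprfe.__version__,
        "python": platform.python_version(),
        "stages": [],
    }

    def _stage(name):
        manifest["stages"].append({"name": name, "t": round(time.time() - t0, 2)})

    counts, y, external = _load_inputs(cfg)
    mio.write_abundance(counts, outdir / "counts.tsv")
    mio.write_labels(y, outdir / "labels.tsv")
    _stage("load")

    logged = preprocess_cohort(counts, cfg.max_zero_fraction)
    train_idx, test_idx = stratified_split(
        logged, y, cfg.test_fraction, seed=cfg.seeds["split"]
    )
    X_train_raw = FeatureMatrix(logged.values.iloc[train_idx], stage="log_transformed")
    X_test_raw = FeatureMatrix(logged.values.iloc[test_idx], stage="log_transformed")
    scaler = fit_minmax(X_train_raw)
    X_train = apply_minmax(X_train_raw, scaler)
    X_test = apply_minmax(X_test_raw, scaler)
    y_train = y.iloc[train_idx]
    y_test = y.iloc[test_idx]
    mio.write_feature_matrix(X_train, outdir / "train_scaled.tsv")
    mio.write_feature_matrix(X_test, outdir / "test_scaled.tsv")
    _stage("preprocess")

    S = None
    if cfg.mapping_kind != "none":
        if external is None:
            raise ValidationError("mapping requires an external cohort")
        S = external_similarity(
            external, X_train.feature_ids, cfg.mapping_kind, cfg.max_zero_fraction
        )
        S.values.to_csv(outdir / "similarity.tsv", sep="\t", index_label="feature_id")
    _stage("similarity")

    result = run_bootstrap_rfe(
        X_train, y_train, B=cfg.bootstraps, mapping_kind=cfg.mapping_kind, S=S,
        alpha_grid=tuple(cfg.alpha_grid), C_grid=tuple(cfg.C_grid),
        seed=cfg.seeds["bootstrap"],
    )
    result.to_dir(outdir / "rfe")
    _stage("rfe")

    stability = pairwise_stability(result.rank_matrix)
    (outdir / "stability.json").write_text(json.dumps(stability.as_dict(), indent=2))
    _stage("stability")

    top_k = top_k_by_delta_mcc(
        result.mcc_mean, epsilon=cfg.delta_mcc_epsilon, window=cfg.delta_mcc_window
    )
    selected = result.ordering[:top_k]
    (outdir / "selected_features.json").write_text(
        json.dumps({"top_k": top_k, "optimal_k": result.optimal_k, "features": selected}, indent=2)
    )
    _stage("top_k")

    if cfg.run_noise_eval:
        noise = noise_filter_experiment(
            X_train, y_train, n_noise=cfg.n_noise, mapping_kind=cfg.mapping_kind,
            S=S, B=cfg.bootstraps, alpha_grid=tuple(cfg.alpha_grid),
            C_grid=tuple(cfg.C_grid), seed=cfg.seeds["noise"],
        )
        (outdir / "noise_eval.json").write_text(
            json.dumps(
                {"noise_filter_score": noise.noise_filter_score, "n_noise": noise.n_noise},
                indent=2,
            )
        )
        _stage("noise_eval")

    specs = [s for s in default_model_specs() if s.algorithm in cfg.models]
    table = evaluate_suite(
        X_train, y_train, {"test": (X_test, y_test)},
        feature_subset=selected, seed=cfg.seeds["classify"], specs=specs,
    )
    table.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    _stage("classify")

    shap_spec = next(
        (s for s in specs if s.algorithm == cfg.shap_model),
        ModelSpec(cfg.shap_model),
    )
    Xtr_sel = FeatureMatrix(X_train.values[selected], stage="scaled")
    Xte_sel = FeatureMatrix(X_test.values[selected], stage="scaled")
    model = build_and_tune(shap_spec, Xtr_sel, y_train, seed=cfg.seeds["classify"])
    attr = explain_samples(
        lambda A: predict_scores(model, A), Xtr_sel, Xte_sel,
        seed=cfg.seeds["explain"],
    )
    attr.values.to_csv(outdir / "shap_values.tsv", sep="\t", index_label="sample_id")
    summary = shap_summary(attr, Xte_sel)
    pd.DataFrame(
        {
            "mean_abs_attribution": summary.mean_abs,
            "direction": summary.direction,
            "total_rank": summary.total_rank,
        }
    ).to_csv(outdir / "shap_summary.tsv", sep="\t", index_label="feature_id")
    _stage("explain")

    manifest["wall_clock_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def compare_mappings(
    cfg: RunConfig,
    include_noise: bool = False,
) -> pd.DataFrame:
    """Run the three mapping variants under shared bootstrap splits.

    Returns one row per variant with the five stability indexes, the peak of
    the MCC curve and (optionally) the noise-filter score, so that stability
    differences are attributable to the mapping alone.
    """
    cfg.validate()
    counts, y, external = _load_inputs(cfg)
    logged = preprocess_cohort(counts, cfg.max_zero_fraction)
    train_idx, _ = stratified_split(logged, y, cfg.test_fraction, seed=cfg.seeds["split"])
    X_raw = FeatureMatrix(logged.values.iloc[train_idx], stage="log_transformed")
    scaler = fit_minmax(X_raw)
    X = apply_minmax(X_raw, scaler)
    y_train = y.iloc[train_idx]
    splits = make_bootstraps(y_train, cfg.bootstraps, seed=cfg.seeds["bootstrap"])
    rows = []
    for kind in ("none", "pearson", "bray_curtis"):
        S = None
        if kind != "none":
            if external is None:
                raise ValidationError("mapping requires an external cohort")
            S = external_similarity(external, X.feature_ids, kind, cfg.max_zero_fraction)
        result = run_bootstrap_rfe(
            X, y_train, mapping_kind=kind, S=S, alpha_grid=tuple(cfg.alpha_grid),
            C_grid=tuple(cfg.C_grid), seed=cfg.seeds["bootstrap"], splits=splits,
        )
        rep = pairwise_stability(result.rank_matrix)
        row = {
            "mapping": kind,
            "srcc": rep.srcc,
            "pearson": rep.pearson,
            "hamming": rep.hamming,
            "bray_curtis_dissimilarity": rep.bray_curtis_dissimilarity,
            "euclidean": rep.euclidean,
            "peak_mcc": float(np.max(result.mcc_mean)),
            "optimal_k": result.optimal_k,
        }
        if include_noise:
            noise = noise_filter_experiment(
                X, y_train, n_noise=cfg.n_noise, mapping_kind=kind, S=S,
                B=cfg.bootstraps, alpha_grid=tuple(cfg.alpha_grid),
                C_grid=tuple(cfg.C_grid), seed=cfg.seeds["noise"],
            )
            row["noise_filter_score"] = noise.noise_filter_score
        rows.append(row)
    return pd.DataFrame(rows)
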