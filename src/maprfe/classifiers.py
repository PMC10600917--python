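"""Eight-model classification suite with MCC-first evaluation.

The suite trains logistic regression, a linear SVM, a random forest, an
XGBoost regressor, a perceptron and MLP regressors with 1-3 hidden layers on
a selected feature subset, tuning each model's grid by 5-fold stratified
cross-validated MCC and reporting MCC, AUC, accuracy, specificity,
sensitivity, PPV and NPV at a 0.5 decision threshold. Regressors (XGBoost,
the MLPs) emit continuous scores thresholded at 0.5; the linear SVM and the
perceptron output the class directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC, LinearSVC
from xgboost import XGBRegressor

from maprfe.types import FeatureMatrix, ValidationError, validate_labels

ALGORITHMS = (
    "logistic", "linear_svm", "random_forest", "xgboost",
    "perceptron", "mlp1", "mlp2", "mlp3",
)

_LR_GRID = [0.005, 0.01, 0.05, 0.1, 0.5]
_L1_GRID = [1e-3, 1e-2, 0.1, 1.0, 10.0]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient from confusion counts.

    (TN*TP - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero factor in
    the denominator yields 0 by convention.
    """
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TN * c.TP - c.FN * c.FP) / math.sqrt(denom)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def mcc_from_predictions(y_true, y_pred) -> float:
    return mcc(confusion(y_true, y_pred))


@dataclass
class MetricsReport:
    mcc: float
    auc: float  # nan when the truth is single-class
    accuracy: float
    specificity: float
    sensitivity: float
    ppv: float
    npv: float
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "mcc": self.mcc, "auc": self.auc, "accuracy": self.accuracy,
            "specificity": self.specificity, "sensitivity": self.sensitivity,
            "ppv": self.ppv, "npv": self.npv, "threshold": self.threshold,
        }


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics_report(scores, y, threshold: float = 0.5) -> MetricsReport:
    """All seven performance metrics from continuous scores and binary truth."""
    scores = np.asarray(scores, dtype=float)
    y_true = validate_labels(y, require_both_classes=False)
    if scores.shape != y_true.shape:
        raise ValidationError("scores and labels must be aligned")
    pred = (scores >= threshold).astype(int)
    c = confusion(y_true, pred)
    if len(np.unique(y_true)) < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_true, scores))
    return MetricsReport(
        mcc=mcc(c),
        auc=auc,
        accuracy=(c.TP + c.TN) / c.total,
        specificity=_safe_ratio(c.TN, c.TN + c.FP),
        sensitivity=_safe_ratio(c.TP, c.TP + c.FN),
        ppv=_safe_ratio(c.TP, c.TP + c.FP),
        npv=_safe_ratio(c.TN, c.TN + c.FN),
        threshold=threshold,
    )


@dataclass
class ModelSpec:
    """One algorithm plus its hyperparameter grid and fixed settings."""

    algorithm: str
    grid: dict = field(default_factory=dict)
    kernel: str = "linear"  # linear_svm only; "rbf" available behind this flag

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")


def default_model_specs(svm_kernel: str = "linear") -> list[ModelSpec]:
    """The eight models with their standard tuning grids."""
    mlp_grid = {"learning_rate_init": _LR_GRID, "alpha": _L1_GRID}
    return [
        ModelSpec("logistic", {"C": [2.0**k for k in (-5, -3, -1, 1, 3, 5)]}),
        ModelSpec("linear_svm", {"C": [2.0**k for k in range(-5, 16, 2)]}, kernel=svm_kernel),
        ModelSpec("random_forest", {}),
        ModelSpec("xgboost", {"learning_rate": _LR_GRID, "reg_alpha": _L1_GRID}),
        ModelSpec("perceptron", {}),
        ModelSpec("mlp1", dict(mlp_grid)),
        ModelSpec("mlp2", dict(mlp_grid)),
        ModelSpec("mlp3", dict(mlp_grid)),
    ]


def _instantiate(spec: ModelSpec, params: dict, n_features: int, seed: int):
    a = spec.algorithm
    if a == "logistic":
        # L2 (ridge) penalty is sklearn's default; tolerance 1e-4, lbfgs
        return LogisticRegression(
            tol=1e-4, solver="lbfgs", max_iter=1000, random_state=seed, **params
        )
    if a == "linear_svm":
        if spec.kernel == "rbf":
            return SVC(kernel="rbf", gamma="scale", random_state=seed, **params)
        return LinearSVC(penalty="l2", random_state=seed, max_iter=5000, **params)
    if a == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, criterion="gini", max_depth=None,
            min_samples_split=2, min_samples_leaf=2, max_features="sqrt",
            random_state=seed, n_jobs=1, **params,
        )
    if a == "xgboost":
        return XGBRegressor(
            n_estimators=200, max_depth=20, subsample=0.2, colsample_bytree=0.5,
            gamma=1.0, random_state=seed, n_jobs=1, verbosity=0, **params,
        )
    if a == "perceptron":
        return Perceptron(random_state=seed, **params)
    if a in ("mlp1", "mlp2", "mlp3"):
        n_layers = int(a[-1])
        return MLPRegressor(
            hidden_layer_sizes=(n_features,) * n_layers, activation="relu",
            solver="lbfgs", tol=1e-4, max_iter=2000, random_state=seed, **params,
        )
    raise ValidationError(f"unknown algorithm {a!r}")


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores in a 0.5-thresholdable convention.

    Probability for classifiers with predict_proba; the raw regression output
    for regressors; the predicted class itself for margin classifiers
    (linear SVM, perceptron), which "output the class".
    """
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    scores = np.asarray(model.predict(X), dtype=float)
    return scores


def _fit_model(spec: ModelSpec, params: dict, X: np.ndarray, y: np.ndarray, seed: int):
    """Fit one configuration; reseed-and-retry degenerate MLP fits.

    An LBFGS-optimized ReLU network can start with all hidden units dead and
    converge immediately to a constant predictor; such fits are detected by
    a flat training output and retried with a different initialization.
    """
    retries = 5 if spec.algorithm.startswith("mlp") else 0
    for attempt in range(retries + 1):
        model = _instantiate(spec, params, X.shape[1], seed + attempt)
        try:
            model.fit(X, y)
        except Exception as exc:  # surface with the algorithm name
            raise RuntimeError(f"{spec.algorithm} failed to fit: {exc}") from exc
        if retries == 0 or np.ptp(model.predict(X)) > 1e-8:
            return model
    return model


def build_and_tune(spec: ModelSpec, X, y, cv_folds: int = 5, seed: int = 0):
    """Grid-search the spec's grid by mean stratified-CV MCC; refit on all data.

    Ties keep the first parameter combination in grid order. Returns the
    fitted model.
    """
    arr = X.values.to_numpy() if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    labels = validate_labels(y)
    n_features = arr.shape[1]
    combos = list(ParameterGrid(spec.grid)) if spec.grid else [{}]
    if len(combos) > 1:
        n_folds = min(cv_folds, int(np.bincount(labels).min()))
        if n_folds < 2:
            raise ValidationError(f"{spec.algorithm}: too few samples per class for CV")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(arr, labels))
        best, best_score = combos[0], -np.inf
        for params in combos:
            scores = []
            for tr, te in folds:
                model = _fit_model(spec, params, arr[tr], labels[tr], seed)
                pred = (predict_scores(model, arr[te]) >= 0.5).astype(int)
                scores.append(mcc_from_predictions(labels[te], pred))
            mean = float(np.mean(scores))
            if mean > best_score:
                best, best_score = params, mean
    else:
        best = combos[0]
    return _fit_model(spec, best, arr, labels, seed)


def evaluate_suite(
    X_train: FeatureMatrix,
    y_train,
    X_tests: dict[str, tuple[FeatureMatrix, object]],
    feature_subset: list[str] | None = None,
    seed: int = 0,
    specs: list[ModelSpec] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Train every model on the subset and evaluate on each named test set.

    ``X_tests`` maps a test-set name to (FeatureMatrix, labels). Returns a
    tidy DataFrame with one row per (model, test set) and the seven metrics.
    """
    specs = specs if specs is not None else default_model_specs()
    cols = feature_subset if feature_subset is not None else X_train.feature_ids
    Xtr = X_train.values[cols]
    rows = []
    for spec in specs:
        model = build_and_tune(spec, Xtr, y_train, seed=seed)
        for name, (Xte, yte) in X_tests.items():
            scores = predict_scores(model, Xte.values[cols].to_numpy())
            rep = metrics_report(scores, yte, threshold=threshold)
            rows.append(
                {"model": spec.algorithm, "test_set": name, "n_features": len(cols),
                 **rep.as_dict()}
            )
    return pd.DataFrame(rows)
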