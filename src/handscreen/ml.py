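"""Machine-learning baselines: logistic regression, SVM, random forest.

Each family trains on *all* predetermined features of a gesture (no
manual selection), standardized within the training folds, with grid-
searched hyperparameters under stratified 5-fold cross-validation.
Feature importance is read back as absolute coefficients for the linear
families and impurity importances for the forest, allowing a direct
comparison with the rule-based selection.

The default grids are deliberately small, conventional ones (an L2
regularization sweep for logistic regression, linear/RBF kernels with a C
sweep for the SVM, tree-count x depth for the forest); any grid can be
overridden per call and the resolved grid is recorded on the fitted
handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import FitError

__all__ = ["MLModelSpec", "MLFit", "FeatureImportanceReport", "fit_ml",
           "importance_report", "DEFAULT_GRIDS"]

FAMILIES = ("logistic-regression", "svm", "random-forest")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic-regression": {"model__C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "svm": {"model__kernel": ["linear", "rbf"], "model__C": [0.1, 1.0, 10.0]},
    "random-forest": {"model__n_estimators": [100, 300],
                      "model__max_depth": [None, 5, 10]},
}


@dataclass(frozen=True)
class MLModelSpec:
    family: str
    hyperparameter_grid: dict[str, list] | None = None
    cv_folds: int = 5
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FitError(f"unknown model family {self.family!r}; choose from {FAMILIES}")

    @property
    def grid(self) -> dict[str, list]:
        return self.hyperparameter_grid or DEFAULT_GRIDS[self.family]


@dataclass
class MLFit:
    """A fitted grid-searched model plus its CV bookkeeping."""

    spec: MLModelSpec
    feature_names: list[str]
    estimator: Pipeline
    best_params: dict[str, Any]
    cv_results: pd.DataFrame

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict(x).astype(bool)


@dataclass(frozen=True)
class FeatureImportanceReport:
    family: str
    importances: tuple[tuple[str, float], ...]  # sorted descending

    def ranking(self) -> list[str]:
        return [name for name, _ in self.importances]


def _base_estimator(spec: MLModelSpec):
    if spec.family == "logistic-regression":
        return LogisticRegression(max_iter=5000, random_state=spec.seed)
    if spec.family == "svm":
        return SVC(random_state=spec.seed)
    return RandomForestClassifier(random_state=spec.seed)


def fit_ml(features: pd.DataFrame, labels, spec: MLModelSpec,
           feature_names: list[str] | None = None) -> MLFit:
    """Grid-search, cross-validate and refit one baseline family.

    ``labels`` is boolean (True = target class).  Both classes must be
    present with at least ``cv_folds`` members each, otherwise fitting
    fails with a suggestion to reduce the fold count (a logged
    configuration choice, not an automatic fallback).
    """
    y = np.asarray(labels).astype(bool)
    names = feature_names or [c for c in features.columns
                              if features[c].dtype.kind == "f"]
    x = features[names].to_numpy(dtype=float)
    if x.shape[0] != y.size:
        raise FitError("features and labels disagree in length")
    n_min = min(int(y.sum()), int((~y).sum()))
    if n_min == 0:
        raise FitError("training data must contain both classes")
    if n_min < spec.cv_folds:
        raise FitError(
            f"smallest class has {n_min} member(s) < cv_folds={spec.cv_folds}; "
            "pass MLModelSpec(cv_folds=...) with a smaller fold count")

    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", _base_estimator(spec)))
    pipeline = Pipeline(steps)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(pipeline, spec.grid, cv=cv, scoring="accuracy", refit=True)
    search.fit(x, y)
    cv_table = pd.DataFrame(search.cv_results_)[
        ["params", "mean_test_score", "std_test_score", "rank_test_score"]]
    return MLFit(spec=spec, feature_names=names, estimator=search.best_estimator_,
                 best_params=dict(search.best_params_), cv_results=cv_table)


def importance_report(fit: MLFit) -> FeatureImportanceReport:
    """Feature importances of a fitted model, sorted descending.

    Absolute coefficients for the linear families (an RBF-kernel SVM has
    no per-feature coefficients and raises); impurity importances,
    nonnegative and summing to one, for the random forest.
    """
    model = fit.estimator.named_steps.get("model")
    if model is None or not hasattr(fit, "estimator"):
        raise FitError("importance requested from a non-fitted handle")
    if fit.spec.family == "random-forest":
        weights = model.feature_importances_
    else:
        if not hasattr(model, "coef_"):
            raise FitError(
                f"{fit.spec.family} with kernel "
                f"{getattr(model, 'kernel', '?')!r} exposes no coefficients")
        weights = np.abs(np.ravel(model.coef_))
    pairs = sorted(zip(fit.feature_names, map(float, weights)),
                   key=lambda kv: -kv[1])
    return FeatureImportanceReport(family=fit.spec.family, importances=tuple(pairs))
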