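"""End-to-end screening study: calibrate, predict and evaluate per gesture.

Glue over the module surfaces: for each gesture task, fit the rule-based
OR-ensemble (and optionally the three ML baselines) on the training
split of a cohort feature table, predict the held-out test split, and
report confusion matrices with accuracy/sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry
from .errors import EvaluationError
from .evaluation import MetricsReport, confusion, metrics
from .ml import MLFit, MLModelSpec, fit_ml
from .rules import RuleModel, fit_rule_model, predict_batch

__all__ = ["GestureResult", "StudyReport", "run_screening_study"]

ML_FAMILIES = ("logistic-regression", "svm", "random-forest")


@dataclass
class GestureResult:
    gesture: str
    rule_model: RuleModel
    reports: dict[str, MetricsReport]
    ml_fits: dict[str, MLFit] = field(default_factory=dict)


@dataclass
class StudyReport:
    gestures: dict[str, GestureResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, result in sorted(self.gestures.items()):
            for model, rep in result.reports.items():
                rows.append(rep.to_dict())
        return pd.DataFrame(rows)


def _require_columns(frame: pd.DataFrame, cols: list[str], stage: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise EvaluationError(f"{stage}: missing column(s) {missing}")


def run_screening_study(
    features: pd.DataFrame,
    criterion: str = "youden",
    fpr_floor: float = 0.02,
    with_ml: bool = False,
    seed: int = 0,
    cv_folds: int = 5,
) -> StudyReport:
    """Run the full per-gesture screening evaluation on a cohort table.

    ``features`` must carry ``gesture``, ``group`` ('target'/'non-target')
    and ``split`` ('train'/'test') columns plus the per-gesture feature
    columns (as produced by the synthetic cohort builder, or by joining a
    computed feature table with a truth/split sidecar).
    """
    _require_columns(features, ["gesture", "group", "split"], "evaluate")
    results: dict[str, GestureResult] = {}
    for gesture in sorted(features["gesture"].unique()):
        sub = features.loc[features["gesture"] == gesture]
        names = registry.feature_names(gesture)
        _require_columns(sub, names, f"evaluate[{gesture}]")
        train = sub.loc[sub["split"] == "train"]
        test = sub.loc[sub["split"] == "test"]
        y_train = (train["group"] == "target").to_numpy()
        y_test = (test["group"] == "target").to_numpy()

        rule = fit_rule_model(train, y_train, gesture,
                              criterion=criterion, fpr_floor=fpr_floor)
        pred = predict_batch(rule, test[names].assign(gesture=gesture))
        reports = {"rule-based": metrics(
            confusion((pred == "abnormal").to_numpy(), y_test),
            model="rule-based", gesture=gesture)}

        ml_fits: dict[str, MLFit] = {}
        if with_ml:
            for family in ML_FAMILIES:
                spec = MLModelSpec(family=family, seed=seed, cv_folds=cv_folds)
                fit = fit_ml(train, y_train, spec, feature_names=names)
                ml_fits[family] = fit
                ml_pred = fit.predict(test)
                reports[family] = metrics(confusion(ml_pred, y_test),
                                          model=family, gesture=gesture)
        results[gesture] = GestureResult(gesture=gesture, rule_model=rule,
                                         reports=reports, ml_fits=ml_fits)
    return StudyReport(gestures=results)
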