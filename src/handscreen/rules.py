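"""The rule-based OR-ensemble screening classifier.

Per gesture, the model is a set of (feature, threshold) classifiers
calibrated on training data and combined by OR: a record is predicted
*normal* only if every member feature lies at or below its threshold;
if any feature strictly exceeds its threshold the record is *abnormal*
and the hand screens positive for the gesture's target nerve.  Values
exactly at a threshold predict normal (the calibrated cutoffs sit at
midpoints between observed scores, so ties are not expected in practice).

Fitting composes the calibration module: per-feature ROC -> AUC filter at
0.8 with the minimum-two back-fill -> per-selected-feature threshold
choice (Youden or FPR-floor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry
from .calibration import (
    FeatureAUC,
    SelectionResult,
    ThresholdSpec,
    auc,
    choose_threshold,
    roc_curve,
    select_features,
)
from .errors import FitError, PredictionError

__all__ = ["RuleModel", "fit_rule_model", "predict", "predict_batch"]


@dataclass(frozen=True)
class RuleModel:
    """An OR-ensemble of thresholded feature classifiers for one gesture."""

    gesture: str
    classifiers: tuple[ThresholdSpec, ...]
    target_injury: str
    auc_table: tuple[FeatureAUC, ...] = ()
    selection: SelectionResult | None = None

    def __post_init__(self) -> None:
        if len(self.classifiers) < 2:
            raise FitError("a rule model needs at least two classifiers")
        names = set(registry.feature_names(self.gesture))
        for clf in self.classifiers:
            if clf.feature not in names:
                raise FitError(
                    f"feature {clf.feature!r} is not registered for {self.gesture}")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(clf.feature for clf in self.classifiers)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "gesture": self.gesture,
            "target_injury": self.target_injury,
            "classifiers": [
                {
                    "feature": c.feature,
                    "threshold": c.threshold,
                    "criterion": c.criterion,
                    "achieved_tpr": c.achieved_tpr,
                    "achieved_fpr": c.achieved_fpr,
                }
                for c in self.classifiers
            ],
            "auc_table": [
                {"feature": a.feature, "auc": a.auc,
                 "n_target": a.n_target, "n_nontarget": a.n_nontarget}
                for a in self.auc_table
            ],
            "selection_rule": self.selection.rule_applied if self.selection else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RuleModel":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        payload = json.loads(text)
        classifiers = tuple(
            ThresholdSpec(
                feature=c["feature"],
                threshold=float(c["threshold"]),
                criterion=c["criterion"],
                achieved_tpr=float(c["achieved_tpr"]),
                achieved_fpr=float(c["achieved_fpr"]),
            )
            for c in payload["classifiers"]
        )
        auc_table = tuple(
            FeatureAUC(feature=a["feature"], auc=float(a["auc"]),
                       n_target=int(a["n_target"]), n_nontarget=int(a["n_nontarget"]))
            for a in payload.get("auc_table", [])
        )
        return cls(
            gesture=payload["gesture"],
            classifiers=classifiers,
            target_injury=payload["target_injury"],
            auc_table=auc_table,
        )


def fit_rule_model(
    features: pd.DataFrame,
    labels,
    gesture: str,
    criterion: str = "youden",
    fpr_floor: float = 0.02,
    min_auc: float = 0.8,
    min_count: int = 2,
) -> RuleModel:
    """Calibrate the OR-ensemble for one gesture on training data.

    Parameters
    ----------
    features : DataFrame
        One row per training record with the gesture's feature columns.
    labels : array-like of bool
        True for target-group (injured for this gesture's nerve) records.
    criterion : {"youden", "fpr-floor"}
        Per-feature threshold rule.
    """
    y = np.asarray(labels).astype(bool)
    if len(features) != y.size:
        raise FitError("features and labels disagree in length")
    if y.all() or not y.any():
        raise FitError("training data must contain both classes")
    names = registry.feature_names(gesture)
    missing = [n for n in names if n not in features.columns]
    if missing:
        raise FitError(f"missing feature columns for {gesture}: {missing}")

    auc_table = []
    curves = {}
    for name in names:
        curve = roc_curve(features[name].to_numpy(dtype=float), y)
        curves[name] = curve
        auc_table.append(FeatureAUC(
            feature=name, auc=auc(curve),
            n_target=int(y.sum()), n_nontarget=int((~y).sum())))
    selection = select_features(auc_table, gesture, min_auc=min_auc, min_count=min_count)
    classifiers = tuple(
        choose_threshold(curves[name], criterion=criterion,
                         fpr_floor=fpr_floor, feature=name)
        for name in selection.selected
    )
    return RuleModel(
        gesture=gesture,
        classifiers=classifiers,
        target_injury=registry.GESTURE_NERVE[gesture],
        auc_table=tuple(auc_table),
        selection=selection,
    )


def predict(model: RuleModel, feature_values) -> str:
    """Classify one record: 'abnormal' iff any feature exceeds its threshold.

    ``feature_values`` is a mapping (or FeatureVector) of feature name to
    value; it must contain every model feature.
    """
    from collections.abc import Mapping

    values = (feature_values if isinstance(feature_values, Mapping)
              else feature_values.values)
    for clf in model.classifiers:
        if clf.feature not in values:
            raise PredictionError(f"missing feature {clf.feature!r} for prediction")
    fired = any(float(values[c.feature]) > c.threshold for c in model.classifiers)
    return "abnormal" if fired else "normal"


def predict_batch(model: RuleModel, features: pd.DataFrame) -> pd.Series:
    """Vectorized per-record predictions, order preserved.

    All rows must carry the model's gesture if a ``gesture`` column is
    present.
    """
    if "gesture" in features.columns:
        wrong = features.loc[features["gesture"] != model.gesture]
        if len(wrong):
            raise PredictionError(
                f"{len(wrong)} record(s) carry a gesture other than {model.gesture}")
    missing = [c.feature for c in model.classifiers if c.feature not in features.columns]
    if missing:
        raise PredictionError(f"missing feature column(s): {missing}")
    if len(features) == 0:
        return pd.Series([], dtype=object, name="prediction")
    fired = np.zeros(len(features), dtype=bool)
    for clf in model.classifiers:
        fired |= features[clf.feature].to_numpy(dtype=float) > clf.threshold
    return pd.Series(np.where(fired, "abnormal", "normal"),
                     index=features.index, name="prediction")
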