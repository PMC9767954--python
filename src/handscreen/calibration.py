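"""ROC construction, AUC, AUC-filtered feature selection and thresholds.

Every feature in the battery is oriented so that greater values are more
abnormal, so ROC curves are built with the fixed convention
"score > cutoff => positive (abnormal)".  Candidate cutoffs are placed
midway between adjacent distinct scores (with half-step extensions beyond
the extremes), which avoids boundary ambiguity on ties; the resulting
step curve's trapezoidal area is exactly the Mann-Whitney concordance
fraction with half credit for tied pairs.

Feature selection follows the screening battery's rule: keep all features
with AUC >= 0.8; if fewer than two survive, back-fill with the
highest-AUC remaining features (ties broken by battery number) until two
are selected.

Threshold choice supports two criteria.  ``youden`` maximizes
J = TPR - FPR (ties resolved toward higher specificity, then the higher
cutoff).  ``fpr-floor`` picks the highest-sensitivity cutoff whose
training FPR does not exceed a floor (default 0.02 per feature) -- a
conservative per-feature mode suited to OR-ensembles, whose false-positive
rates accumulate across member classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import registry
from .errors import CalibrationError

__all__ = [
    "ROCCurve",
    "FeatureAUC",
    "SelectionResult",
    "ThresholdSpec",
    "roc_curve",
    "auc",
    "mann_whitney_auc",
    "binormal_auc",
    "select_features",
    "choose_threshold",
]


@dataclass(frozen=True)
class ROCCurve:
    """An empirical ROC curve under the greater-is-positive convention.

    ``thresholds[i]`` is the cutoff realizing the operating point
    ``(fpr[i], tpr[i])`` via "score > threshold".  Points run from (0, 0)
    (cutoff above the maximum score) to (1, 1) (cutoff below the minimum),
    one point per distinct score plus the two endpoints.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    positive_direction: str = "greater-is-positive"

    def __post_init__(self) -> None:
        for arr in (self.fpr, self.tpr):
            if np.any(np.diff(arr) < 0):
                raise CalibrationError("ROC rates must be nondecreasing")


@dataclass(frozen=True)
class FeatureAUC:
    """Discriminative performance of one feature on a training split."""

    feature: str
    auc: float
    n_target: int
    n_nontarget: int


@dataclass(frozen=True)
class SelectionResult:
    gesture: str
    selected: tuple[str, ...]
    rule_applied: str  # "auc-filter" or "minimum-two-fallback"


@dataclass(frozen=True)
class ThresholdSpec:
    """A calibrated per-feature cutoff: abnormal iff value > threshold."""

    feature: str
    threshold: float
    criterion: str
    achieved_tpr: float
    achieved_fpr: float
    degenerate: bool = False


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y.astype(bool)
    return y


def roc_curve(scores, labels) -> ROCCurve:
    """Build the empirical ROC curve of a score against binary labels.

    ``labels`` is truthy for the target (positive) class.  Both classes
    must be present.  One operating point is produced per distinct score,
    plus the (0, 0) and (1, 1) endpoints; cutoffs are midpoints between
    adjacent distinct scores, extended by half the mean gap beyond the
    extremes.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if scores.shape != y.shape or scores.ndim != 1:
        raise CalibrationError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("both classes must be present to build a ROC curve")
    if not np.all(np.isfinite(scores)):
        raise CalibrationError("non-finite scores")

    # distinct scores descending, with per-score class counts
    distinct, inverse = np.unique(scores, return_inverse=True)
    pos_at = np.bincount(inverse, weights=y.astype(float), minlength=distinct.size)
    neg_at = np.bincount(inverse, weights=(~y).astype(float), minlength=distinct.size)
    distinct = distinct[::-1]
    pos_at = pos_at[::-1]
    neg_at = neg_at[::-1]

    tps = np.concatenate([[0.0], np.cumsum(pos_at)])
    fps = np.concatenate([[0.0], np.cumsum(neg_at)])
    half_gap = float(np.mean(np.diff(distinct[::-1])) / 2.0) if distinct.size > 1 else 0.5
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] + half_gap], mids, [distinct[-1] - half_gap]])
    return ROCCurve(thresholds=thresholds, fpr=fps / n_neg, tpr=tps / n_pos)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under an ROC curve, in [0, 1].

    With midpoint cutoffs this equals the Mann-Whitney concordance
    fraction (half credit for ties) to machine precision.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def mann_whitney_auc(target_scores, nontarget_scores) -> float:
    """Rank-statistic AUC: concordant-pair fraction with tie half-credit.

    Computed via the rank-sum identity, O(n log n); used both as the
    production path for large simulations and cross-checked against the
    trapezoidal formulation in the test suite.
    """
    from scipy.stats import rankdata

    t = np.asarray(target_scores, dtype=float)
    nt = np.asarray(nontarget_scores, dtype=float)
    if t.size == 0 or nt.size == 0:
        raise CalibrationError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([t, nt]))
    r_t = ranks[: t.size].sum()
    u = r_t - t.size * (t.size + 1) / 2.0
    return float(u / (t.size * nt.size))


def binormal_auc(mean0: float, sd0: float, mean1: float, sd1: float) -> float:
    """Closed-form AUC between two Gaussian score distributions.

    ``Phi((mean1 - mean0) / sqrt(sd0^2 + sd1^2))`` with group 1 as the
    positive class; the analytic oracle for moment-based simulations.
    """
    from scipy.stats import norm

    return float(norm.cdf((mean1 - mean0) / np.hypot(sd0, sd1)))


def select_features(
    aucs: list[FeatureAUC],
    gesture: str,
    min_auc: float = 0.8,
    min_count: int = 2,
) -> SelectionResult:
    """Apply the AUC filter with the minimum-two back-fill rule.

    Keeps every feature with AUC >= ``min_auc``; if fewer than
    ``min_count`` survive, back-fills with the best remaining features in
    descending AUC order, breaking ties by ascending battery number.
    Output order is battery order.
    """
    if not aucs:
        raise CalibrationError("empty AUC list")
    number = {fa.feature: registry.get_feature(gesture, fa.feature).number for fa in aucs}
    kept = [fa.feature for fa in aucs if fa.auc >= min_auc]
    rule = "auc-filter"
    if len(kept) < min_count:
        rule = "minimum-two-fallback"
        remaining = sorted(
            (fa for fa in aucs if fa.feature not in kept),
            key=lambda fa: (-fa.auc, number[fa.feature]),
        )
        for fa in remaining:
            kept.append(fa.feature)
            if len(kept) >= min_count:
                break
    kept.sort(key=lambda name: number[name])
    return SelectionResult(gesture=gesture, selected=tuple(kept), rule_applied=rule)


def choose_threshold(
    curve: ROCCurve,
    criterion: str = "youden",
    fpr_floor: float = 0.02,
    feature: str = "",
) -> ThresholdSpec:
    """Pick an operating point on a ROC curve.

    ``youden`` maximizes TPR - FPR; among ties the lower-FPR (more
    specific) point wins, then the higher cutoff.  ``fpr-floor`` takes the
    highest-TPR point with FPR <= ``fpr_floor`` (same tie-breaks).  If the
    floor admits only the degenerate TPR = 0 point, a warning is issued
    and the degenerate spec is returned explicitly.
    """
    tpr, fpr, thr = curve.tpr, curve.fpr, curve.thresholds
    if criterion == "youden":
        j = tpr - fpr
        order = np.lexsort((-thr, fpr, -j))  # best J, then low fpr, then high cutoff
        best = order[0]
        degenerate = False
    elif criterion == "fpr-floor":
        feasible = np.flatnonzero(fpr <= fpr_floor)
        sub_order = np.lexsort((-thr[feasible], fpr[feasible], -tpr[feasible]))
        best = feasible[sub_order[0]]
        degenerate = tpr[best] == 0.0
        if degenerate:
            warnings.warn(
                f"fpr-floor {fpr_floor} admits no sensitivity for feature "
                f"{feature or '<unnamed>'}; returning the degenerate cutoff",
                stacklevel=2,
            )
    else:
        raise CalibrationError(f"unknown threshold criterion {criterion!r}")
    return ThresholdSpec(
        feature=feature,
        threshold=float(thr[best]),
        criterion=criterion,
        achieved_tpr=float(tpr[best]),
        achieved_fpr=float(fpr[best]),
        degenerate=degenerate,
    )
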