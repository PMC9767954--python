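"""Performance metrics, stratified splitting and statistical summaries.

Metrics follow the screening convention: *abnormal* is the positive class,
so TP counts abnormal gestures predicted abnormal and TN normal gestures
predicted normal.  Accuracy, sensitivity and specificity are percentages:

    accuracy    = (TP + TN) / (TP + FP + TN + FN) * 100
    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (FP + TN) * 100

Group summaries report mean, SD (n-1 denominator) and a 95% CI using the
normal approximation (mean +/- 1.96 SD/sqrt(n); a t-quantile mode is
available).  Group differences use the independent t-test -- Welch's
unequal-variance form by default, since group SDs of the screening
features differ several-fold; the pooled-variance form is selectable.  No
multiple-testing correction is applied (marginal tests at alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "GroupSummary",
    "TTestResult",
    "confusion",
    "metrics",
    "stratified_split",
    "group_summary",
    "independent_t_test",
    "subgroup_analysis",
]

POSITIVE = "abnormal"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy/sensitivity/specificity in percent, with their matrix.

    A metric whose denominator is zero is ``None`` and listed in
    ``undefined`` rather than silently reported as zero.
    """

    matrix: ConfusionMatrix
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    model: str = ""
    gesture: str = ""
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "gesture": self.gesture,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.matrix.tp, "fp": self.matrix.fp,
            "fn": self.matrix.fn, "tn": self.matrix.tn,
            "undefined": list(self.undefined),
        }


def _as_positive(seq) -> np.ndarray:
    arr = np.asarray(seq)
    if arr.dtype == bool:
        return arr
    return np.asarray([str(v) == POSITIVE or v is True for v in arr])


def confusion(predictions, truth) -> ConfusionMatrix:
    """Count TP/FP/FN/TN from aligned predictions and true labels.

    Inputs may be booleans (True = abnormal) or the strings
    'abnormal'/'normal'.
    """
    pred = _as_positive(predictions)
    true = _as_positive(truth)
    if pred.shape != true.shape:
        raise EvaluationError(
            f"length mismatch: {pred.shape} predictions vs {true.shape} truths")
    return ConfusionMatrix(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
        tn=int(np.sum(~pred & ~true)),
    )


def metrics(matrix: ConfusionMatrix, model: str = "", gesture: str = "") -> MetricsReport:
    """Accuracy, sensitivity and specificity (percent) of a confusion matrix."""
    undefined = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return 100.0 * num / den

    acc = ratio(matrix.tp + matrix.tn, matrix.total, "accuracy")
    sens = ratio(matrix.tp, matrix.tp + matrix.fn, "sensitivity")
    spec = ratio(matrix.tn, matrix.fp + matrix.tn, "specificity")
    return MetricsReport(matrix=matrix, accuracy=acc, sensitivity=sens,
                         specificity=spec, model=model, gesture=gesture,
                         undefined=tuple(undefined))


def stratified_split(
    labels,
    test_fraction: float = 0.25,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test index split.

    Within each stratum of ``labels`` a ``test_fraction`` share (rounded
    to the nearest integer) is assigned to the test set.  Returns
    (train_indices, test_indices); together they partition
    ``range(len(labels))``.  Strata of fewer than two records stay in the
    training set with a warning.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise EvaluationError("cannot split an empty sequence")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        if idx.size < 2:
            import warnings

            warnings.warn(f"stratum {value!r} has {idx.size} record(s); "
                          "kept entirely in the training set", stacklevel=2)
            continue
        perm = rng.permutation(idx)
        n_test = int(round(idx.size * test_fraction))
        test_idx.extend(perm[:n_test].tolist())
    test = np.sort(np.asarray(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(labels.size), test)
    return train, test


@dataclass(frozen=True)
class GroupSummary:
    feature: str
    group: str
    mean: float
    sd: float
    ci95: tuple[float, float]
    n: int


def group_summary(
    values,
    groups,
    feature: str = "",
    ci_method: str = "normal",
) -> list[GroupSummary]:
    """Per-group mean, SD and 95% CI of one feature.

    ``ci_method='normal'`` uses mean +/- 1.96 SD/sqrt(n);
    ``'t'`` uses the t-distribution quantile instead.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = []
    for g in pd.unique(groups):
        x = values[groups == g]
        if x.size < 2:
            raise EvaluationError(f"group {g!r} has n={x.size} < 2")
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        if ci_method == "normal":
            half = 1.96 * sd / np.sqrt(x.size)
        elif ci_method == "t":
            half = float(stats.t.ppf(0.975, x.size - 1)) * sd / np.sqrt(x.size)
        else:
            raise EvaluationError(f"unknown CI method {ci_method!r}")
        out.append(GroupSummary(feature=feature, group=str(g), mean=mean, sd=sd,
                                ci95=(mean - half, mean + half), n=int(x.size)))
    return out


@dataclass(frozen=True)
class TTestResult:
    feature: str
    t: float
    p: float
    significant: bool
    flag: str = ""


def independent_t_test(
    group_a,
    group_b,
    feature: str = "",
    alpha: float = 0.05,
    equal_var: bool = False,
) -> TTestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EvaluationError("each group needs at least two observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(feature=feature, t=0.0, p=1.0, significant=False,
                               flag="zero-variance-equal-means")
        return TTestResult(feature=feature, t=np.inf, p=0.0, significant=True,
                           flag="zero-variance-distinct-means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return TTestResult(feature=feature, t=float(res.statistic), p=p,
                       significant=p < alpha)


def subgroup_analysis(
    features: pd.DataFrame,
    subgroup_labels,
    feature_names: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise t-tests among non-injury / untargeted-injury / targeted-injury.

    Returns one row per (feature, subgroup pair) with the Welch statistic,
    p-value and significance flag.  All three subgroups must be present.
    """
    labels = np.asarray(subgroup_labels)
    present = set(np.unique(labels))
    expected = {"non-injury", "untargeted-injury", "targeted-injury"}
    if not expected <= present:
        raise EvaluationError(f"missing subgroup(s): {sorted(expected - present)}")
    rows = []
    for feat in feature_names:
        x = features[feat].to_numpy(dtype=float)
        for g1, g2 in combinations(sorted(expected), 2):
            res = independent_t_test(x[labels == g1], x[labels == g2],
                                     feature=feat, alpha=alpha)
            rows.append({"feature": feat, "group_a": g1, "group_b": g2,
                         "t": res.t, "p": res.p, "significant": res.significant})
    return pd.DataFrame(rows, columns=["feature", "group_a", "group_b",
                                       "t", "p", "significant"])
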