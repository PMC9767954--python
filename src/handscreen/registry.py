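"""Registry of the 23 predetermined screening features.

Each of the three screening gestures targets one nerve and carries its own
block of features computed from the 21-point hand skeleton:

* Gesture 1 (radial nerve, digit extension/abduction): the five MCP joint
  angles.  Radial palsy impairs MCP extension, so these angles grow.
* Gesture 2 (ulnar nerve, digit adduction in extension): PIP/DIP flexion of
  the ring and little fingers (claw-hand component), their sums, and the
  third/fourth webspace angles (Wartenberg component).
* Gesture 3 (median nerve, thumb-index tip pinch): thumb CMC/MCP/IP and
  index MCP/PIP/DIP flexion angles and their sums -- all *negated* so that
  "greater value = more abnormal" holds uniformly (an injured hand flexes
  these joints *less* when pinching) -- plus the negated thumb palmar
  abduction angle and the standardized thumb-tip-to-index-tip distance.

The module also embeds the published per-group reference statistics for the
features (mean, SD per target/non-target group, and the reported training
AUC).  These are data inputs: the moment-based synthetic sampler uses the
means/SDs as its default generating distributions, and the reported AUC
column is the worked input for the feature-selection rule.

Angles are in degrees; ``dis_tip`` is a dimensionless ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FeatureDefinition",
    "GroupMoments",
    "FEATURES",
    "GESTURES",
    "GESTURE_NERVE",
    "feature_names",
    "get_feature",
    "primitive_feature_names",
    "REFERENCE_MOMENTS",
    "REFERENCE_AUC",
]

GESTURES = ("G1", "G2", "G3")

#: Nerve targeted by each gesture's binary screening task.
GESTURE_NERVE = {"G1": "radial", "G2": "ulnar", "G3": "median"}


@dataclass(frozen=True)
class FeatureDefinition:
    """One named feature of the screening battery.

    Parameters
    ----------
    number : int
        Position (1-23) in the battery; used as the deterministic
        tie-break order during feature selection.
    name : str
        Feature name; unique within a gesture (``ag_thumb_MCP`` and
        ``ag_index_MCP`` recur between G1 and G3 with different signs).
    gesture : str
        Owning gesture task, ``G1``/``G2``/``G3``.
    kind : str
        One of ``joint-angle``, ``webspace-angle``,
        ``palmar-abduction-angle``, ``angle-sum``, ``standardized-distance``.
    signed : bool
        True for the negated Gesture-3 angle features.
    components : tuple of str
        For ``angle-sum`` features, the names of the summed features.
    """

    number: int
    name: str
    gesture: str
    kind: str
    description: str
    signed: bool = False
    components: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupMoments:
    """Mean and SD of a feature within one group (target or non-target)."""

    mean: float
    sd: float


FEATURES: tuple[FeatureDefinition, ...] = (
    # -- Gesture 1: digit extension, radial nerve -------------------------
    FeatureDefinition(1, "ag_thumb_MCP", "G1", "joint-angle", "Angle of thumb MCP joint"),
    FeatureDefinition(2, "ag_index_MCP", "G1", "joint-angle", "Angle of index MCP joint"),
    FeatureDefinition(3, "ag_middle_MCP", "G1", "joint-angle", "Angle of middle MCP joint"),
    FeatureDefinition(4, "ag_ring_MCP", "G1", "joint-angle", "Angle of ring MCP joint"),
    FeatureDefinition(5, "ag_little_MCP", "G1", "joint-angle", "Angle of little MCP joint"),
    # -- Gesture 2: digit adduction, ulnar nerve --------------------------
    FeatureDefinition(6, "ag_ring_PIP", "G2", "joint-angle", "Angle of ring PIP joint"),
    FeatureDefinition(7, "ag_ring_DIP", "G2", "joint-angle", "Angle of ring DIP joint"),
    FeatureDefinition(8, "ag_ring", "G2", "angle-sum", "Sum of ring PIP and DIP angles",
                      components=("ag_ring_PIP", "ag_ring_DIP")),
    FeatureDefinition(9, "ag_little_PIP", "G2", "joint-angle", "Angle of little PIP joint"),
    FeatureDefinition(10, "ag_little_DIP", "G2", "joint-angle", "Angle of little DIP joint"),
    FeatureDefinition(11, "ag_little", "G2", "angle-sum", "Sum of little PIP and DIP angles",
                      components=("ag_little_PIP", "ag_little_DIP")),
    FeatureDefinition(12, "web3", "G2", "webspace-angle", "Angle of the third webspace"),
    FeatureDefinition(13, "web4", "G2", "webspace-angle", "Angle of the fourth webspace"),
    # -- Gesture 3: tip pinch, median nerve (starred angles negated) ------
    FeatureDefinition(14, "ag_thumb_CMC", "G3", "joint-angle", "Negated angle of thumb CMC joint", signed=True),
    FeatureDefinition(15, "ag_thumb_MCP", "G3", "joint-angle", "Negated angle of thumb MCP joint", signed=True),
    FeatureDefinition(16, "ag_thumb_IP", "G3", "joint-angle", "Negated angle of thumb IP joint", signed=True),
    FeatureDefinition(17, "ag_thumb", "G3", "angle-sum", "Sum of negated thumb CMC, MCP and IP angles",
                      signed=True, components=("ag_thumb_CMC", "ag_thumb_MCP", "ag_thumb_IP")),
    FeatureDefinition(18, "ag_index_MCP", "G3", "joint-angle", "Negated angle of index MCP joint", signed=True),
    FeatureDefinition(19, "ag_index_PIP", "G3", "joint-angle", "Negated angle of index PIP joint", signed=True),
    FeatureDefinition(20, "ag_index_DIP", "G3", "joint-angle", "Negated angle of index DIP joint", signed=True),
    FeatureDefinition(21, "ag_index", "G3", "angle-sum", "Sum of negated index MCP, PIP and DIP angles",
                      signed=True, components=("ag_index_MCP", "ag_index_PIP", "ag_index_DIP")),
    FeatureDefinition(22, "ag_palmab", "G3", "palmar-abduction-angle",
                      "Negated thumb palmar abduction angle", signed=True),
    FeatureDefinition(23, "dis_tip", "G3", "standardized-distance",
                      "Thumb tip to index tip distance / thumb tip to IP distance"),
)

_BY_KEY = {(f.gesture, f.name): f for f in FEATURES}
assert len(_BY_KEY) == 23


def feature_names(gesture: str) -> list[str]:
    """Names of the features registered for one gesture, in battery order."""
    return [f.name for f in FEATURES if f.gesture == gesture]


def get_feature(gesture: str, name: str) -> FeatureDefinition:
    return _BY_KEY[(gesture, name)]


def primitive_feature_names(gesture: str) -> list[str]:
    """Feature names excluding the derived angle-sums."""
    return [f.name for f in FEATURES
            if f.gesture == gesture and f.kind != "angle-sum"]


# Published per-group statistics of the 23 features (training cohort).
# Keys are (gesture, feature name); values per group are (mean, SD).
REFERENCE_MOMENTS: dict[tuple[str, str], dict[str, GroupMoments]] = {
    ("G1", "ag_thumb_MCP"): {"non_target": GroupMoments(5.49, 3.59), "target": GroupMoments(21.36, 7.27)},
    ("G1", "ag_index_MCP"): {"non_target": GroupMoments(8.46, 3.30), "target": GroupMoments(19.02, 9.95)},
    ("G1", "ag_middle_MCP"): {"non_target": GroupMoments(4.87, 2.39), "target": GroupMoments(17.44, 11.74)},
    ("G1", "ag_ring_MCP"): {"non_target": GroupMoments(6.99, 3.14), "target": GroupMoments(19.80, 11.87)},
    ("G1", "ag_little_MCP"): {"non_target": GroupMoments(13.75, 6.37), "target": GroupMoments(24.73, 16.13)},
    ("G2", "ag_ring_PIP"): {"non_target": GroupMoments(6.75, 7.08), "target": GroupMoments(13.81, 12.95)},
    ("G2", "ag_ring_DIP"): {"non_target": GroupMoments(4.74, 6.28), "target": GroupMoments(13.05, 15.13)},
    ("G2", "ag_ring"): {"non_target": GroupMoments(11.49, 12.51), "target": GroupMoments(26.87, 27.13)},
    ("G2", "ag_little_PIP"): {"non_target": GroupMoments(7.02, 4.48), "target": GroupMoments(12.46, 9.35)},
    ("G2", "ag_little_DIP"): {"non_target": GroupMoments(5.85, 5.72), "target": GroupMoments(13.70, 12.43)},
    ("G2", "ag_little"): {"non_target": GroupMoments(12.87, 9.57), "target": GroupMoments(26.16, 21.39)},
    ("G2", "web3"): {"non_target": GroupMoments(1.58, 1.00), "target": GroupMoments(6.50, 1.83)},
    ("G2", "web4"): {"non_target": GroupMoments(1.75, 1.51), "target": GroupMoments(8.33, 5.27)},
    ("G3", "ag_thumb_CMC"): {"non_target": GroupMoments(-28.16, 6.62), "target": GroupMoments(-30.16, 5.61)},
    ("G3", "ag_thumb_MCP"): {"non_target": GroupMoments(-24.10, 9.88), "target": GroupMoments(-30.61, 12.01)},
    ("G3", "ag_thumb_IP"): {"non_target": GroupMoments(-42.20, 19.62), "target": GroupMoments(-39.89, 28.04)},
    ("G3", "ag_thumb"): {"non_target": GroupMoments(-94.47, 19.51), "target": GroupMoments(-100.66, 30.51)},
    ("G3", "ag_index_MCP"): {"non_target": GroupMoments(-32.72, 5.41), "target": GroupMoments(-29.91, 6.87)},
    ("G3", "ag_index_PIP"): {"non_target": GroupMoments(-70.28, 18.33), "target": GroupMoments(-55.08, 25.78)},
    ("G3", "ag_index_DIP"): {"non_target": GroupMoments(-36.99, 13.85), "target": GroupMoments(-40.21, 28.77)},
    ("G3", "ag_index"): {"non_target": GroupMoments(-139.99, 19.53), "target": GroupMoments(-125.21, 49.30)},
    ("G3", "ag_palmab"): {"non_target": GroupMoments(-19.95, 8.34), "target": GroupMoments(-9.30, 4.43)},
    ("G3", "dis_tip"): {"non_target": GroupMoments(0.72, 0.28), "target": GroupMoments(1.19, 0.81)},
}

# Reported training-set AUC of each feature (the worked input for the
# selection rule: keep AUC >= 0.8, back-fill to a minimum of two).
REFERENCE_AUC: dict[tuple[str, str], float] = {
    ("G1", "ag_thumb_MCP"): 0.95,
    ("G1", "ag_index_MCP"): 0.85,
    ("G1", "ag_middle_MCP"): 0.89,
    ("G1", "ag_ring_MCP"): 0.85,
    ("G1", "ag_little_MCP"): 0.68,
    ("G2", "ag_ring_PIP"): 0.68,
    ("G2", "ag_ring_DIP"): 0.68,
    ("G2", "ag_ring"): 0.67,
    ("G2", "ag_little_PIP"): 0.66,
    ("G2", "ag_little_DIP"): 0.71,
    ("G2", "ag_little"): 0.66,
    ("G2", "web3"): 0.99,
    ("G2", "web4"): 0.89,
    ("G3", "ag_thumb_CMC"): 0.59,
    ("G3", "ag_thumb_MCP"): 0.65,
    ("G3", "ag_thumb_IP"): 0.49,
    ("G3", "ag_thumb"): 0.61,
    ("G3", "ag_index_MCP"): 0.39,
    ("G3", "ag_index_PIP"): 0.33,
    ("G3", "ag_index_DIP"): 0.54,
    ("G3", "ag_index"): 0.60,
    ("G3", "ag_palmab"): 0.87,
    ("G3", "dis_tip"): 0.66,
}
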