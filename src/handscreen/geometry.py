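"""Geometric primitives and the 23 screening features.

Three primitives underlie every feature:

* the angle between two 3-vectors,
  ``theta = arccos(v1 . v2 / (|v1| |v2|))`` in degrees,
* the Euclidean distance between two landmarks, and
* distance standardization, dividing any distance by the thumb TIP-IP
  segment length so the result is camera- and hand-size-invariant.

Joint angles are measured between the proximal segment direction
(previous landmark -> joint) and the distal segment direction
(joint -> next landmark), so a perfectly straight chain reads 0 degrees.
Because the skeleton has a single wrist landmark and no metacarpal bases,
the proximal segment of every finger MCP is wrist -> MCP; this is also why
fully extended real hands read small but nonzero MCP angles.

Webspace angles are taken between the whole-finger rays (MCP -> fingertip)
flanking the webspace, which captures whole-finger adduction.  The thumb
palmar-abduction angle is the elevation of the thumb ray (thumb MCP ->
thumb tip) out of the palm plane spanned by the wrist and the index/little
MCPs, negated so that larger values mean *less* abduction.  The Gesture-3
starred angle features are likewise negated, making "greater value = more
abnormal" uniform across the whole battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import registry
from .errors import DegenerateGeometryError
from .landmarks import CohortTable, HandLandmarkSet, canonicalize_hand

__all__ = [
    "angle_between",
    "euclid_distance",
    "standardize_distance",
    "joint_angle",
    "webspace_angle",
    "palmar_abduction_angle",
    "tip_distance",
    "FeatureVector",
    "compute_features",
    "compute_feature_table",
    "JOINT_LANDMARKS",
]

# joint name -> (proximal landmark, joint landmark, distal landmark)
JOINT_LANDMARKS: dict[str, tuple[int, int, int]] = {
    "thumb_CMC": (0, 1, 2),
    "thumb_MCP": (1, 2, 3),
    "thumb_IP": (2, 3, 4),
    "index_MCP": (0, 5, 6),
    "index_PIP": (5, 6, 7),
    "index_DIP": (6, 7, 8),
    "middle_MCP": (0, 9, 10),
    "middle_PIP": (9, 10, 11),
    "middle_DIP": (10, 11, 12),
    "ring_MCP": (0, 13, 14),
    "ring_PIP": (13, 14, 15),
    "ring_DIP": (14, 15, 16),
    "little_MCP": (0, 17, 18),
    "little_PIP": (17, 18, 19),
    "little_DIP": (18, 19, 20),
}

# webspace -> ((MCP, TIP) of the radial finger, (MCP, TIP) of the ulnar one)
_WEBSPACES = {"third": ((9, 12), (13, 16)), "fourth": ((13, 16), (17, 20))}


def angle_between(v1: np.ndarray, v2: np.ndarray, context: str = "") -> float:
    """Angle between two 3-vectors in degrees, in [0, 180].

    The normalized dot product is clamped to [-1, 1] to guard rounding.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError(
            f"zero-length vector while computing angle{' for ' + context if context else ''}")
    # atan2(|v1 x v2|, v1 . v2) == arccos of the clamped normalized dot
    # product, but stays well-conditioned near 0 and 180 degrees
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(v1, v2)),
                                       np.dot(v1, v2))))


def euclid_distance(p1, p2) -> float:
    """Euclidean distance between two landmarks (model units)."""
    a = p1.as_array() if hasattr(p1, "as_array") else np.asarray(p1, dtype=float)
    b = p2.as_array() if hasattr(p2, "as_array") else np.asarray(p2, dtype=float)
    return float(np.linalg.norm(a - b))


def standardize_distance(d_original: float, d_standard: float) -> float:
    """Dimensionless ratio d_original / d_standard; d_standard must be > 0."""
    if d_standard <= 0.0:
        raise DegenerateGeometryError("standard distance is zero or negative")
    return float(d_original) / float(d_standard)


def joint_angle(lms: HandLandmarkSet, joint: str) -> float:
    """Flexion angle of a named joint in degrees; straight chain reads 0."""
    try:
        ia, ib, ic = JOINT_LANDMARKS[joint]
    except KeyError:
        raise DegenerateGeometryError(f"unknown joint {joint!r}") from None
    coords = lms.as_array()
    return angle_between(coords[ib] - coords[ia], coords[ic] - coords[ib],
                         context=f"joint {joint} (landmarks {ia},{ib},{ic})")


def webspace_angle(lms: HandLandmarkSet, web: str) -> float:
    """Angle between the finger rays flanking the third or fourth webspace."""
    try:
        (m1, t1), (m2, t2) = _WEBSPACES[web]
    except KeyError:
        raise DegenerateGeometryError(f"unknown webspace {web!r}") from None
    coords = lms.as_array()
    return angle_between(coords[t1] - coords[m1], coords[t2] - coords[m2],
                         context=f"webspace {web}")


def palmar_abduction_angle(lms: HandLandmarkSet) -> float:
    """Negated elevation of the thumb ray out of the palm plane, degrees.

    The palm plane is spanned by wrist (0), index MCP (5) and little
    MCP (17); for a hand in right-hand convention the cross product
    ``(index MCP - wrist) x (little MCP - wrist)`` points dorsally.  The
    thumb ray runs from the thumb MCP (2) to the thumb tip (4).  A thumb
    abducted toward the palmar side has negative output (matching the
    published sign convention), a thumb in the palm plane reads 0, and
    reduced abduction raises the value toward (and past) zero.

    The caller must supply a canonicalized (right-convention) hand;
    :func:`compute_features` does this automatically.
    """
    coords = lms.as_array()
    u = coords[5] - coords[0]
    v = coords[17] - coords[0]
    normal = np.cross(u, v)
    norm = np.linalg.norm(normal)
    if norm == 0.0:
        raise DegenerateGeometryError(
            "palm-plane landmarks (wrist, index MCP, little MCP) are collinear")
    ray = coords[4] - coords[2]
    ray_norm = np.linalg.norm(ray)
    if ray_norm == 0.0:
        raise DegenerateGeometryError("thumb MCP and thumb tip coincide")
    sin_elev = np.clip(np.dot(ray, normal) / (ray_norm * norm), -1.0, 1.0)
    # dorsal normal: ray . normal > 0 means dorsal elevation, i.e. the
    # negated palmar elevation is positive -- exactly the feature's sign.
    return float(np.degrees(np.arcsin(sin_elev)))


def tip_distance(lms: HandLandmarkSet) -> float:
    """Thumb-tip to index-tip distance standardized by the thumb TIP-IP length."""
    coords = lms.as_array()
    d_standard = float(np.linalg.norm(coords[4] - coords[3]))
    if d_standard == 0.0:
        raise DegenerateGeometryError("thumb tip and thumb IP coincide")
    d_original = float(np.linalg.norm(coords[4] - coords[8]))
    return standardize_distance(d_original, d_standard)


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values for one record (degrees; dis_tip unitless)."""

    record_key: tuple[str, str, str, int]
    gesture: str
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _gesture_features(lms: HandLandmarkSet) -> dict[str, float]:
    g = lms.gesture
    try:
        if g == "G1":
            return {
                "ag_thumb_MCP": joint_angle(lms, "thumb_MCP"),
                "ag_index_MCP": joint_angle(lms, "index_MCP"),
                "ag_middle_MCP": joint_angle(lms, "middle_MCP"),
                "ag_ring_MCP": joint_angle(lms, "ring_MCP"),
                "ag_little_MCP": joint_angle(lms, "little_MCP"),
            }
        if g == "G2":
            vals = {
                "ag_ring_PIP": joint_angle(lms, "ring_PIP"),
                "ag_ring_DIP": joint_angle(lms, "ring_DIP"),
                "ag_little_PIP": joint_angle(lms, "little_PIP"),
                "ag_little_DIP": joint_angle(lms, "little_DIP"),
                "web3": webspace_angle(lms, "third"),
                "web4": webspace_angle(lms, "fourth"),
            }
            vals["ag_ring"] = vals["ag_ring_PIP"] + vals["ag_ring_DIP"]
            vals["ag_little"] = vals["ag_little_PIP"] + vals["ag_little_DIP"]
            return vals
        # G3: starred angles negated so greater = more abnormal
        vals = {
            "ag_thumb_CMC": -joint_angle(lms, "thumb_CMC"),
            "ag_thumb_MCP": -joint_angle(lms, "thumb_MCP"),
            "ag_thumb_IP": -joint_angle(lms, "thumb_IP"),
            "ag_index_MCP": -joint_angle(lms, "index_MCP"),
            "ag_index_PIP": -joint_angle(lms, "index_PIP"),
            "ag_index_DIP": -joint_angle(lms, "index_DIP"),
            "ag_palmab": palmar_abduction_angle(lms),
            "dis_tip": tip_distance(lms),
        }
        vals["ag_thumb"] = vals["ag_thumb_CMC"] + vals["ag_thumb_MCP"] + vals["ag_thumb_IP"]
        vals["ag_index"] = vals["ag_index_MCP"] + vals["ag_index_PIP"] + vals["ag_index_DIP"]
        return vals
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"record {lms.key}: {exc}") from exc


def compute_features(lms: HandLandmarkSet) -> FeatureVector:
    """Compute the gesture's registered features for one record.

    The hand is canonicalized to right-hand convention first, so every
    feature -- including the signed palmar abduction -- is invariant under
    reflection of the input.  Returns exactly 5 features for G1, 8 for G2
    and 10 for G3, ordered as in the battery.
    """
    canon = canonicalize_hand(lms)
    raw = _gesture_features(canon)
    ordered = {name: raw[name] for name in registry.feature_names(lms.gesture)}
    return FeatureVector(record_key=lms.key, gesture=lms.gesture, values=ordered)


def compute_feature_table(cohort: CohortTable) -> pd.DataFrame:
    """Feature table for a cohort: metadata columns plus one column per feature.

    Records of different gestures may be mixed; each row carries only its
    own gesture's feature columns (others are NaN).
    """
    rows = []
    for rec in cohort:
        fv = compute_features(rec)
        row = {
            "subject_id": rec.subject_id,
            "hand_side": rec.hand_side,
            "gesture": rec.gesture,
            "repetition": int(rec.repetition),
            "label": rec.label,
        }
        row.update(fv.values)
        rows.append(row)
    meta = ["subject_id", "hand_side", "gesture", "repetition", "label"]
    gestures = sorted({r["gesture"] for r in rows})
    feat_cols: list[str] = []
    for g in gestures:
        for name in registry.feature_names(g):
            if name not in feat_cols:
                feat_cols.append(name)
    return pd.DataFrame(rows, columns=meta + feat_cols)
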