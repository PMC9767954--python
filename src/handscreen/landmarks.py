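"""Reading, writing and canonicalizing 21-point hand-landmark records.

The landmark convention is the standard 21-point hand skeleton emitted by
single-camera hand trackers: index 0 is the wrist, 1-4 the thumb
(CMC, MCP, IP, TIP), then four fingers of four landmarks each
(MCP, PIP, DIP, TIP) for index (5-8), middle (9-12), ring (13-16) and
little (17-20).  Coordinates are dimensionless model units; every feature
downstream is either an angle or a ratio, so the absolute scale never
matters.

File formats
------------
CSV: one row per record with metadata columns
``subject_id, hand_side, handedness, gesture, repetition, label`` followed
by 63 coordinate columns ``x0, y0, z0, ..., x20, y20, z20``.
JSON: ``{"provenance": ..., "records": [{<metadata>, "points":
[[x, y, z] * 21]}]}``.

An external image-to-landmark tracker is *not* bundled; the pluggable
adapter contract is a callable taking an opaque image handle and returning
either a :class:`HandLandmarkSet` or :data:`NOT_DETECTED`.  Non-detected
images are excluded and counted, and the recognition rate is reported.
"""

from __future__ import annotations

import json
import math
from collections.abc import Callable, Iterable, Iterator, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import CapabilityError, SchemaError, ValidationError

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkPoint",
    "HandLandmarkSet",
    "CohortTable",
    "read_landmarks",
    "write_landmarks",
    "canonicalize_hand",
    "mirror_hand",
    "NOT_DETECTED",
    "RecognitionReport",
    "track_images",
]

LANDMARK_NAMES = (
    "wrist",
    "thumb_cmc", "thumb_mcp", "thumb_ip", "thumb_tip",
    "index_mcp", "index_pip", "index_dip", "index_tip",
    "middle_mcp", "middle_pip", "middle_dip", "middle_tip",
    "ring_mcp", "ring_pip", "ring_dip", "ring_tip",
    "little_mcp", "little_pip", "little_dip", "little_tip",
)

VALID_GESTURES = ("G1", "G2", "G3")
VALID_LABELS = ("none", "radial", "ulnar", "median", "ulnar+median")
VALID_SIDES = ("left", "right")

META_COLUMNS = ["subject_id", "hand_side", "handedness", "gesture", "repetition", "label"]
COORD_COLUMNS = [f"{axis}{i}" for i in range(21) for axis in ("x", "y", "z")]


@dataclass(frozen=True)
class LandmarkPoint:
    """One 3-D landmark; all coordinates must be finite."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for axis in (self.x, self.y, self.z):
            if not math.isfinite(axis):
                raise ValidationError(f"non-finite landmark coordinate: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class HandLandmarkSet:
    """One gesture capture: 21 ordered landmarks plus record metadata."""

    points: tuple[LandmarkPoint, ...]
    subject_id: str
    hand_side: str
    gesture: str
    repetition: int
    label: str = "none"
    handedness: str | None = None  # geometric chirality; defaults to hand_side

    def __post_init__(self) -> None:
        if self.handedness is None:
            object.__setattr__(self, "handedness", self.hand_side)
        if len(self.points) != 21:
            raise ValidationError(
                f"record {self.key} has {len(self.points)} landmarks, expected 21")
        if self.gesture not in VALID_GESTURES:
            raise ValidationError(f"record {self.key}: unknown gesture {self.gesture!r}")
        if not 1 <= int(self.repetition) <= 4:
            raise ValidationError(
                f"record {self.key}: repetition {self.repetition} outside 1..4")
        if self.hand_side not in VALID_SIDES or self.handedness not in VALID_SIDES:
            raise ValidationError(f"record {self.key}: invalid hand side/handedness")
        if self.label not in VALID_LABELS:
            raise ValidationError(f"record {self.key}: unknown label {self.label!r}")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.subject_id, self.hand_side, self.gesture, int(self.repetition))

    def as_array(self) -> np.ndarray:
        """Landmarks as a (21, 3) float array."""
        return np.array([[p.x, p.y, p.z] for p in self.points], dtype=float)

    @classmethod
    def from_array(cls, coords: np.ndarray, **meta: Any) -> "HandLandmarkSet":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (21, 3):
            raise ValidationError(f"landmark array has shape {coords.shape}, expected (21, 3)")
        pts = tuple(LandmarkPoint(*row) for row in coords)
        return cls(points=pts, **meta)


@dataclass
class CohortTable:
    """A validated collection of landmark records with unique record keys."""

    records: list[HandLandmarkSet] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple, int] = {}
        dupes = []
        for rec in self.records:
            if rec.key in seen:
                dupes.append(rec.key)
            seen[rec.key] = 1
        if dupes:
            raise ValidationError(f"duplicate record keys: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HandLandmarkSet]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict[str, Any] = {
                "subject_id": rec.subject_id,
                "hand_side": rec.hand_side,
                "handedness": rec.handedness,
                "gesture": rec.gesture,
                "repetition": int(rec.repetition),
                "label": rec.label,
            }
            coords = rec.as_array()
            for i in range(21):
                row[f"x{i}"], row[f"y{i}"], row[f"z{i}"] = coords[i]
            rows.append(row)
        return pd.DataFrame(rows, columns=META_COLUMNS + COORD_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "CohortTable":
        missing = [c for c in META_COLUMNS + COORD_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing[:6]}"
                              + (" ..." if len(missing) > 6 else ""))
        records, problems = [], []
        for _, row in df.iterrows():
            key = (row["subject_id"], row["hand_side"], row["gesture"], row["repetition"])
            try:
                coords = row[COORD_COLUMNS].to_numpy(dtype=float).reshape(21, 3)
                records.append(HandLandmarkSet.from_array(
                    coords,
                    subject_id=str(row["subject_id"]),
                    hand_side=str(row["hand_side"]),
                    handedness=str(row["handedness"]),
                    gesture=str(row["gesture"]),
                    repetition=int(row["repetition"]),
                    label=str(row["label"]),
                ))
            except (ValidationError, ValueError) as exc:
                problems.append(f"{key}: {exc}")
        if problems:
            raise ValidationError(
                f"{len(problems)} invalid record(s): " + "; ".join(problems[:5]))
        return cls(records=records, provenance=provenance)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_landmarks(path: str | Path, fmt: str | None = None) -> CohortTable:
    """Read a landmark file (CSV or JSON) into a validated cohort.

    Records that fail validation are reported collectively in the raised
    :class:`ValidationError`; nothing is silently dropped.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.empty and not set(META_COLUMNS) <= set(df.columns):
            raise SchemaError(f"{path}: missing columns {META_COLUMNS}")
        return CohortTable.from_dataframe(df, provenance=str(path))
    if fmt == "json":
        payload = json.loads(Path(path).read_text())
        if "records" not in payload:
            raise SchemaError(f"{path}: JSON landmark file must contain 'records'")
        records, problems = [], []
        for entry in payload["records"]:
            try:
                pts = np.asarray(entry["points"], dtype=float)
                records.append(HandLandmarkSet.from_array(
                    pts,
                    subject_id=str(entry["subject_id"]),
                    hand_side=str(entry["hand_side"]),
                    handedness=str(entry.get("handedness", entry["hand_side"])),
                    gesture=str(entry["gesture"]),
                    repetition=int(entry["repetition"]),
                    label=str(entry.get("label", "none")),
                ))
            except KeyError as exc:
                raise SchemaError(f"{path}: record missing field {exc}") from exc
            except (ValidationError, ValueError) as exc:
                problems.append(str(exc))
        if problems:
            raise ValidationError(
                f"{len(problems)} invalid record(s): " + "; ".join(problems[:5]))
        return CohortTable(records=records, provenance=payload.get("provenance", str(path)))
    raise SchemaError(f"unknown landmark format {fmt!r}")


def write_landmarks(cohort: CohortTable, path: str | Path, fmt: str | None = None) -> None:
    """Write a cohort so that :func:`read_landmarks` round-trips it exactly.

    CSV floats are serialized with ``repr`` (shortest round-trip
    representation), so read-after-write preserves coordinates bit-for-bit.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        cohort.to_dataframe().to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "provenance": cohort.provenance,
            "records": [
                {
                    "subject_id": r.subject_id,
                    "hand_side": r.hand_side,
                    "handedness": r.handedness,
                    "gesture": r.gesture,
                    "repetition": int(r.repetition),
                    "label": r.label,
                    "points": r.as_array().tolist(),
                }
                for r in cohort.records
            ],
        }
        Path(path).write_text(json.dumps(payload))
    else:
        raise SchemaError(f"unknown landmark format {fmt!r}")


def mirror_hand(lms: HandLandmarkSet) -> HandLandmarkSet:
    """Reflect a hand about the x = 0 plane and flip its handedness.

    An involution: mirroring twice restores the original record.  All
    inter-landmark distances and unsigned angles are preserved.
    """
    coords = lms.as_array()
    coords[:, 0] = -coords[:, 0]
    flipped = "left" if lms.handedness == "right" else "right"
    pts = tuple(LandmarkPoint(*row) for row in coords)
    return replace(lms, points=pts, handedness=flipped)


def canonicalize_hand(lms: HandLandmarkSet) -> HandLandmarkSet:
    """Map any hand into right-hand convention.

    Left hands (by geometric ``handedness``) are mirrored about the x-axis;
    right hands are returned unchanged.  The ``hand_side`` metadata is kept
    verbatim -- it records which anatomical hand was imaged.  Downstream
    sign conventions (the palm-plane orientation used by the palmar
    abduction feature) assume this canonical chirality.
    """
    if lms.handedness == "right":
        return lms
    return mirror_hand(lms)


# ---------------------------------------------------------------------------
# Tracker adapter contract

#: Sentinel returned by a tracker adapter when no hand was found in an image.
NOT_DETECTED = object()

TrackerAdapter = Callable[[Any], "HandLandmarkSet | object"]


@dataclass(frozen=True)
class RecognitionReport:
    """Bookkeeping of tracker exclusions."""

    n_total: int
    n_detected: int

    @property
    def n_excluded(self) -> int:
        return self.n_total - self.n_detected

    @property
    def recognition_rate(self) -> float:
        """Detected fraction as a percentage, one decimal place."""
        if self.n_total == 0:
            return 100.0
        return round(100.0 * self.n_detected / self.n_total, 1)

    def to_dict(self) -> dict[str, float | int]:
        return {
            "n_total": self.n_total,
            "n_detected": self.n_detected,
            "n_excluded": self.n_excluded,
            "recognition_rate_percent": self.recognition_rate,
        }


def track_images(
    adapter: TrackerAdapter | None,
    image_handles: Iterable[Any],
) -> tuple[list[HandLandmarkSet], RecognitionReport]:
    """Run a registered tracker adapter over image handles.

    Images for which the adapter reports :data:`NOT_DETECTED` are excluded
    from the returned records and counted in the recognition report.
    """
    if adapter is None:
        raise CapabilityError(
            "no tracker adapter registered; supply a landmark CSV/JSON file instead")
    detected: list[HandLandmarkSet] = []
    n_total = 0
    for handle in image_handles:
        n_total += 1
        result = adapter(handle)
        if result is NOT_DETECTED:
            continue
        if not isinstance(result, HandLandmarkSet):
            raise ValidationError(
                "tracker adapter must return a HandLandmarkSet or NOT_DETECTED")
        detected.append(result)
    return detected, RecognitionReport(n_total=n_total, n_detected=len(detected))
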