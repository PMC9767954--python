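"""Synthetic hand data: kinematic landmark generation and moment sampling.

Three layers, from most to least mechanistic:

1. **Forward kinematics** -- a 21-point articulated right-hand model.
   Each finger is a planar three-segment chain hanging off a fixed MCP
   position; flexion rotates successive segments within the finger's
   plane, so PIP/DIP joint angles are realized *exactly*, and the MCP
   joint angle (measured against the wrist->MCP direction, as the feature
   definition dictates on a skeleton without metacarpal bases) is realized
   exactly by compensating the in-plane rotation for the finger's azimuth
   offset.  Webspace targets are met by solving the ring/little azimuth
   offsets numerically (Brent's method on a smooth scalar objective);
   thumb palmar abduction has a closed-form solution in the roll of the
   thumb's flexion plane, and the standardized thumb-index tip distance is
   met by solving the thumb azimuth.  With zero landmark jitter the
   generated pose therefore reproduces every requested feature to solver
   precision (well below 1e-6 degrees).

2. **Moment-based feature sampling** -- per-group independent Gaussians
   parameterized by the published feature means/SDs (optionally equi-
   correlated), bypassing kinematics entirely.  Used for large-sample AUC
   simulations and fast end-to-end studies.

3. **The study-shaped cohort builder** -- mirrors the source study's
   default composition: 22 unilateral patients (10 radial, 5 ulnar,
   1 median, 6 combined ulnar+median) and 34 healthy volunteers, 2 hands
   each, 3 gestures, 4 repetitions = 1,344 records (448 per gesture task),
   with image-level stratified 3:1 train:test splits per gesture.  The
   four repetitions of a hand share a latent severity draw plus
   repetition noise (default 25% of the group SD), so repeated captures
   are realistically correlated while group marginals keep the configured
   mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from . import registry
from .errors import GenerationError
from .geometry import compute_features
from .landmarks import CohortTable, HandLandmarkSet, mirror_hand
from .registry import GESTURE_NERVE, GroupMoments, REFERENCE_MOMENTS

__all__ = [
    "HandSkeleton",
    "PoseParameters",
    "InjuryProfile",
    "SyntheticCohort",
    "CohortConfig",
    "forward_kinematics",
    "sample_gesture",
    "sample_features",
    "build_study_cohort",
]

FINGERS = ("index", "middle", "ring", "little")
_DEG = np.pi / 180.0


@dataclass(frozen=True)
class HandSkeleton:
    """Segment lengths and palm geometry of the articulated model.

    Units are arbitrary model units (roughly decimeters for an adult
    hand); every downstream feature is scale-free.
    """

    finger_mcp_x: dict[str, float] = field(default_factory=lambda: {
        "index": 0.20, "middle": 0.065, "ring": -0.065, "little": -0.19})
    finger_mcp_y: dict[str, float] = field(default_factory=lambda: {
        "index": 0.95, "middle": 1.00, "ring": 0.97, "little": 0.88})
    finger_lengths: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "index": (0.35, 0.22, 0.15),
        "middle": (0.40, 0.25, 0.17),
        "ring": (0.37, 0.23, 0.16),
        "little": (0.28, 0.18, 0.14)})
    thumb_cmc_radius: float = 0.50
    thumb_lengths: tuple[float, float, float] = (0.38, 0.30, 0.26)

    def __post_init__(self) -> None:
        lengths = [self.thumb_cmc_radius, *self.thumb_lengths]
        for f in FINGERS:
            lengths.extend(self.finger_lengths[f])
        if any(l <= 0 for l in lengths):
            raise GenerationError("all skeleton segment lengths must be positive")

    def mcp_position(self, finger: str) -> np.ndarray:
        return np.array([self.finger_mcp_x[finger], self.finger_mcp_y[finger], 0.0])

    def mcp_azimuth(self, finger: str) -> float:
        """Azimuth (degrees, from +y toward +x) of the wrist->MCP ray."""
        return float(np.degrees(np.arctan2(
            self.finger_mcp_x[finger], self.finger_mcp_y[finger])))


def _default_flexion() -> dict[str, float]:
    vals = {"thumb_CMC": 15.0, "thumb_MCP": 8.0, "thumb_IP": 10.0}
    for f in FINGERS:
        vals[f"{f}_MCP"] = 8.0
        vals[f"{f}_PIP"] = 6.0
        vals[f"{f}_DIP"] = 5.0
    return vals


@dataclass
class PoseParameters:
    """Joint-space description of one hand pose.

    ``flexion`` maps joint names (``index_MCP`` ... ``thumb_IP``) to joint
    angles in degrees, each in [0, 120].  ``abduction`` gives per-finger
    azimuth offsets (degrees, positive toward the thumb side) of the
    finger's flexion plane.  Optional targets override the corresponding
    free parameters: ``web3``/``web4`` solve the ring/little abduction,
    ``palmar_abduction`` (palmar elevation of the thumb ray, degrees,
    positive toward the palm) solves the thumb plane roll, and
    ``tip_distance`` (standardized units) solves the thumb azimuth.
    ``jitter_sd`` adds isotropic Gaussian landmark noise after posing.
    """

    flexion: dict[str, float] = field(default_factory=_default_flexion)
    abduction: dict[str, float] = field(default_factory=lambda: dict.fromkeys(FINGERS, 0.0))
    thumb_azimuth: float = 55.0
    thumb_roll: float = 0.0
    thumb_pitch: float = 0.0
    thumb_twist: float = 0.0
    web3: float | None = None
    web4: float | None = None
    palmar_abduction: float | None = None
    tip_distance: float | None = None
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        base = _default_flexion()
        base.update(self.flexion)
        self.flexion = base
        ab = dict.fromkeys(FINGERS, 0.0)
        ab.update(self.abduction)
        self.abduction = ab
        for joint, angle in self.flexion.items():
            if not 0.0 <= angle <= 120.0:
                raise GenerationError(
                    f"flexion angle {joint}={angle} outside the supported [0, 120] range")
        if self.jitter_sd < 0:
            raise GenerationError("jitter SD must be nonnegative")


def _finger_chain(
    skeleton: HandSkeleton, finger: str, theta_mcp: float,
    theta_pip: float, theta_dip: float, delta: float,
) -> np.ndarray:
    """Landmarks (MCP, PIP, DIP, TIP) of one finger, right-hand convention.

    The chain lies in the vertical plane of azimuth ``base + delta``;
    flexion is toward -z (palmar).  The in-plane MCP rotation is
    compensated for the azimuth offset so that the *measured* MCP joint
    angle (against the wrist->MCP ray) equals ``theta_mcp`` exactly, which
    requires ``theta_mcp >= |delta|``.
    """
    mcp = skeleton.mcp_position(finger)
    psi = skeleton.mcp_azimuth(finger)
    cos_ratio = np.cos(theta_mcp * _DEG) / np.cos(delta * _DEG)
    if cos_ratio > 1.0 + 1e-12:
        raise GenerationError(
            f"{finger}: MCP angle {theta_mcp:.2f} deg is not realizable with "
            f"abduction offset {delta:.2f} deg (needs theta >= |delta|)")
    phi1 = float(np.degrees(np.arccos(np.clip(cos_ratio, -1.0, 1.0))))
    alpha = (psi + delta) * _DEG
    h = np.array([np.sin(alpha), np.cos(alpha), 0.0])
    down = np.array([0.0, 0.0, -1.0])
    cum = np.cumsum([phi1, theta_pip, theta_dip]) * _DEG
    lengths = skeleton.finger_lengths[finger]
    pts = [mcp]
    for c, L in zip(cum, lengths):
        pts.append(pts[-1] + L * (np.cos(c) * h + np.sin(c) * down))
    return np.array(pts)


def _thumb_chain(
    skeleton: HandSkeleton, theta_cmc: float, theta_mcp: float,
    theta_ip: float, azimuth: float, roll: float = 0.0,
    pitch: float = 0.0, twist: float = 0.0,
) -> np.ndarray:
    """Landmarks (CMC, MCP, IP, TIP) of the thumb.

    The thumb column points along ``azimuth`` (degrees from +y toward +x)
    and is pitched ``pitch`` degrees below the palm plane -- opposition in
    real hands carries the whole column palmarly.  Proximal flexion occurs
    in a plane rolled ``roll`` degrees about the column (0 = palmar
    flexion, 90 = in-plane adduction toward the fingers); ``twist``
    rotates the MCP flexion axis about the proximal segment, modeling the
    axial pronation of thumb opposition that lets the distal thumb point
    across the palm while the proximal segment plunges palmarly.  All
    three thumb joint angles are interior angles of the rigid chain, so
    they are realized exactly for any azimuth/roll/pitch/twist.
    """
    a = azimuth * _DEG
    b = pitch * _DEG
    u0 = np.array([np.sin(a), np.cos(a), 0.0])      # horizontal column dir
    w = np.array([np.cos(a), -np.sin(a), 0.0])      # horizontal, perp to u0
    z = np.array([0.0, 0.0, 1.0])
    u = np.cos(b) * u0 - np.sin(b) * z              # pitched column dir
    zp = np.cos(b) * z + np.sin(b) * u0             # pitched palm normal
    r = roll * _DEG
    down = -np.cos(r) * zp + np.sin(r) * w          # proximal flexion dir
    t1, t2, t3 = (np.asarray([theta_cmc, theta_mcp, theta_ip]) * _DEG)

    d1 = np.cos(t1) * u + np.sin(t1) * down
    n1 = -np.sin(t1) * u + np.cos(t1) * down        # flexion dir past the bend
    b1 = np.cross(d1, n1)
    tw = twist * _DEG
    f2 = np.cos(tw) * n1 + np.sin(tw) * b1          # twisted MCP flexion dir
    d2 = np.cos(t2) * d1 + np.sin(t2) * f2
    n2 = -np.sin(t2) * d1 + np.cos(t2) * f2
    d3 = np.cos(t3) * d2 + np.sin(t3) * n2          # IP follows the MCP plane

    L1, L2, L3 = skeleton.thumb_lengths
    cmc = skeleton.thumb_cmc_radius * u
    mcp = cmc + L1 * d1
    ip = mcp + L2 * d2
    tip = ip + L3 * d3
    return np.array([cmc, mcp, ip, tip])


def _ray_angle(chain_a: np.ndarray, chain_b: np.ndarray) -> float:
    """Angle (degrees) between MCP->TIP rays of two finger chains."""
    va = chain_a[3] - chain_a[0]
    vb = chain_b[3] - chain_b[0]
    cos = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _solve_bracketed(fn, lo: float, hi: float, n_grid: int = 121) -> float:
    """First sign-change root of ``fn`` on [lo, hi], scanning from lo."""
    xs = np.linspace(lo, hi, n_grid)
    prev_x, prev_v = xs[0], fn(xs[0])
    if prev_v == 0.0:
        return float(prev_x)
    for x in xs[1:]:
        v = fn(x)
        if v == 0.0:
            return float(x)
        if np.sign(v) != np.sign(prev_v):
            return float(brentq(fn, prev_x, x, xtol=1e-12, rtol=8.9e-16))
        prev_x, prev_v = x, v
    raise GenerationError("no root in bracket")


def _solve_web_delta(
    skeleton: HandSkeleton,
    finger: str,
    angles: tuple[float, float, float],
    target: float,
    reference: np.ndarray,
) -> float:
    """Abduction offset bringing the webspace angle against ``reference``
    (a flanking finger's chain) to ``target`` degrees."""
    cap = min(angles[0] - 1e-9, 25.0)
    if cap <= 0:
        raise GenerationError(
            f"webspace target for {finger} needs a positive MCP angle")

    def objective(delta: float) -> float:
        chain = _finger_chain(skeleton, finger, *angles, delta)
        return _ray_angle(reference, chain) - target

    try:
        return _solve_bracketed(objective, -cap, cap)
    except GenerationError:
        raise GenerationError(
            f"webspace target {target:.2f} deg unreachable for {finger} "
            f"(|abduction| <= {cap:.2f} deg)") from None


def forward_kinematics(
    skeleton: HandSkeleton,
    pose: PoseParameters,
    seed: int | None = None,
    handedness: str = "right",
    **meta,
) -> HandLandmarkSet:
    """Emit a 21-point landmark set realizing a pose, deterministically.

    Metadata keyword arguments (``subject_id``, ``hand_side``, ``gesture``,
    ``repetition``, ``label``) are forwarded to the record; sensible
    defaults are used for standalone calls.  With ``jitter_sd == 0`` the
    landmarks are an exact realization of the pose (see the module
    docstring); jitter is isotropic Gaussian per landmark, seeded.
    """
    meta.setdefault("subject_id", "synthetic")
    meta.setdefault("hand_side", handedness)
    meta.setdefault("gesture", "G1")
    meta.setdefault("repetition", 1)
    meta.setdefault("label", "none")

    flex = pose.flexion
    chains: dict[str, np.ndarray] = {}
    for finger in ("index", "middle"):
        chains[finger] = _finger_chain(
            skeleton, finger, flex[f"{finger}_MCP"], flex[f"{finger}_PIP"],
            flex[f"{finger}_DIP"], pose.abduction[finger])

    def _solved_finger(finger: str, target: float | None,
                       reference: np.ndarray) -> np.ndarray:
        angles = (flex[f"{finger}_MCP"], flex[f"{finger}_PIP"], flex[f"{finger}_DIP"])
        if target is None:
            return _finger_chain(skeleton, finger, *angles, pose.abduction[finger])
        delta = _solve_web_delta(skeleton, finger, angles, target, reference)
        return _finger_chain(skeleton, finger, *angles, delta)

    chains["ring"] = _solved_finger("ring", pose.web3, chains["middle"])
    chains["little"] = _solved_finger("little", pose.web4, chains["ring"])

    # Thumb: solve the MCP twist for a palmar-abduction target (the ray
    # elevation falls monotonically as the distal thumb twists across the
    # palm), then sweep the column pitch / solve the azimuth for a
    # tip-distance target.
    t_angles = (flex["thumb_CMC"], flex["thumb_MCP"], flex["thumb_IP"])

    def _elevation(chain: np.ndarray) -> float:
        ray = chain[3] - chain[1]  # thumb MCP -> TIP
        return float(np.degrees(np.arcsin(
            np.clip(-ray[2] / np.linalg.norm(ray), -1.0, 1.0))))

    def _solve_twist(pitch: float, e_target: float) -> float:
        def objective(tw: float) -> float:
            return _elevation(_thumb_chain(
                skeleton, *t_angles, pose.thumb_azimuth, pose.thumb_roll,
                pitch, tw)) - e_target

        try:
            return _solve_bracketed(objective, 0.0, 180.0, n_grid=73)
        except GenerationError:
            raise GenerationError(
                f"palmar abduction {e_target:.2f} deg unreachable at "
                f"thumb pitch {pitch:.1f} deg") from None

    twist = pose.thumb_twist
    pitch = pose.thumb_pitch
    azimuth = pose.thumb_azimuth
    if pose.tip_distance is None:
        if pose.palmar_abduction is not None:
            twist = _solve_twist(pitch, pose.palmar_abduction)
    else:
        index_tip = chains["index"][3]
        L3t = skeleton.thumb_lengths[2]
        solved = False
        for pitch_try in np.concatenate([[pitch], np.linspace(0.0, 60.0, 13)]):
            try:
                twist_try = (twist if pose.palmar_abduction is None
                             else _solve_twist(pitch_try, pose.palmar_abduction))
            except GenerationError:
                continue

            def tip_objective(psi: float) -> float:
                chain = _thumb_chain(skeleton, *t_angles, psi, pose.thumb_roll,
                                     pitch_try, twist_try)
                return (float(np.linalg.norm(chain[3] - index_tip)) / L3t
                        - pose.tip_distance)

            try:
                azimuth = _solve_bracketed(tip_objective, 5.0, 120.0)
            except GenerationError:
                continue
            twist, pitch, solved = twist_try, pitch_try, True
            break
        if not solved:
            raise GenerationError(
                f"tip-distance target {pose.tip_distance:.3f} unreachable for "
                "the drawn thumb/index flexions")
    thumb = _thumb_chain(skeleton, *t_angles, azimuth, pose.thumb_roll, pitch, twist)

    coords = np.zeros((21, 3))
    coords[1:5] = thumb
    coords[5:9] = chains["index"]
    coords[9:13] = chains["middle"]
    coords[13:17] = chains["ring"]
    coords[17:21] = chains["little"]

    rot = Rotation.from_euler("xyz", pose.rotation_deg, degrees=True)
    coords = coords @ rot.as_matrix().T + np.asarray(pose.translation, dtype=float)

    if pose.jitter_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, pose.jitter_sd, size=coords.shape)

    lms = HandLandmarkSet.from_array(coords, handedness="right", **meta)
    if handedness == "left":
        lms = mirror_hand(lms)
    return lms


# ---------------------------------------------------------------------------
# Moment-based machinery

#: Kinematic feasibility bounds per feature (degrees / ratio), applied as
#: truncation when drawing pose targets for the kinematic generator.
_FEASIBLE: dict[str, tuple[float, float]] = {
    "ag_thumb_MCP": (0.0, 60.0), "ag_index_MCP": (0.0, 60.0),
    "ag_middle_MCP": (0.0, 60.0), "ag_ring_MCP": (0.0, 60.0),
    "ag_little_MCP": (0.0, 60.0),
    "ag_ring_PIP": (0.0, 60.0), "ag_ring_DIP": (0.0, 60.0),
    "ag_little_PIP": (0.0, 60.0), "ag_little_DIP": (0.0, 60.0),
    "web3": (0.15, 16.0), "web4": (0.15, 16.0),
    "ag_thumb_CMC": (-95.0, -1.0), "ag_thumb_MCP*": (-95.0, -1.0),
    "ag_thumb_IP": (-110.0, -1.0),
    "ag_index_MCP*": (-60.0, -2.0), "ag_index_PIP": (-115.0, -2.0),
    "ag_index_DIP": (-110.0, -1.0),
    "ag_palmab": (-80.0, -0.5), "dis_tip": (0.02, 2.6),
}


def _feasible_bounds(gesture: str, name: str) -> tuple[float, float]:
    if gesture == "G3" and name in ("ag_thumb_MCP", "ag_index_MCP"):
        return _FEASIBLE[name + "*"]
    return _FEASIBLE[name]


@dataclass(frozen=True)
class InjuryProfile:
    """Injury annotation plus the per-group generating moments.

    ``injury`` is one of none/radial/ulnar/median/ulnar+median.  Per
    gesture task the hand belongs to the *target* group iff the injury
    involves that gesture's nerve; feature values are then drawn from the
    matching group row of ``moments``.
    """

    injury: str = "none"
    moments: dict[tuple[str, str], dict[str, GroupMoments]] = field(
        default_factory=lambda: REFERENCE_MOMENTS)

    def nerves(self) -> frozenset[str]:
        return frozenset() if self.injury == "none" else frozenset(self.injury.split("+"))

    def group_for(self, gesture: str) -> str:
        return "target" if GESTURE_NERVE[gesture] in self.nerves() else "non_target"

    def feature_moments(self, gesture: str, group: str | None = None) -> dict[str, GroupMoments]:
        group = group or self.group_for(gesture)
        out = {}
        for name in registry.feature_names(gesture):
            key = (gesture, name)
            if key not in self.moments or group not in self.moments[key]:
                raise GenerationError(f"profile lacks moments for {key} / {group}")
            out[name] = self.moments[key][group]
        return out


def sample_features(
    profile: InjuryProfile,
    gesture: str,
    n: int,
    seed: int | None = None,
    rho: float = 0.0,
) -> pd.DataFrame:
    """Draw n feature vectors from the profile's group Gaussians.

    Features are independent given the group by default; ``rho`` installs
    a uniform equi-correlation through a shared latent factor.  The sums
    (features 08, 11, 17, 21) are drawn from their own published moments
    in this mode, so they track their printed marginals rather than the
    additive identity; the kinematic path computes them exactly instead.
    """
    if not 0.0 <= rho <= 1.0:
        raise GenerationError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    moments = profile.feature_moments(gesture)
    names = list(moments)
    if n == 0:
        return pd.DataFrame(columns=names)
    common = rng.standard_normal(n)
    data = {}
    for name in names:
        z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        data[name] = moments[name].mean + moments[name].sd * z
    return pd.DataFrame(data)


def _truncated_normal(rng: np.random.Generator, m: GroupMoments,
                      lo: float, hi: float, max_tries: int = 200) -> float:
    for _ in range(max_tries):
        x = rng.normal(m.mean, m.sd)
        if lo <= x <= hi:
            return float(x)
    raise GenerationError(
        f"could not draw a value in [{lo}, {hi}] from N({m.mean}, {m.sd}^2) "
        f"after {max_tries} tries")


def _planar_inclination(lengths: tuple[float, float, float],
                        mcp: float, pip: float, dip: float) -> float:
    """In-plane inclination (degrees) of the MCP->TIP ray of a flexed chain."""
    cum = np.cumsum([mcp, pip, dip]) * _DEG
    s = sum(L * np.sin(c) for L, c in zip(lengths, cum))
    c = sum(L * np.cos(c_) for L, c_ in zip(lengths, cum))
    return float(np.degrees(np.arctan2(s, c)))


def _match_inclination(lengths: tuple[float, float, float], pip: float,
                       dip: float, target_incl: float) -> float:
    """MCP flexion bringing a chain's ray inclination to ``target_incl``."""
    def objective(mcp: float) -> float:
        return _planar_inclination(lengths, mcp, pip, dip) - target_incl

    lo, hi = 1.0, 60.0
    if objective(lo) > 0 or objective(hi) < 0:
        raise GenerationError(
            f"ray inclination {target_incl:.1f} deg unreachable for curl "
            f"({pip:.1f}, {dip:.1f})")
    return float(brentq(objective, lo, hi, xtol=1e-10))


def _g2_matched_mcp(
    skeleton: HandSkeleton,
    finger: str,
    pip: float,
    dip: float,
    target_incl: float,
    web_target: float,
    ref_chain: np.ndarray,
) -> tuple[float, float]:
    """(MCP joint angle, abduction offset) realizing a webspace target.

    Finds the in-plane MCP rotation matching the reference ray
    inclination, then solves the abduction offset with the measured MCP
    angle coupled to the offset (``theta = arccos(cos phi cos delta)``)
    inside the objective -- this keeps the ray inclinations matched
    exactly at every candidate offset, so arbitrarily small webspace
    targets stay reachable.
    """
    phi = _match_inclination(skeleton.finger_lengths[finger], pip, dip, target_incl)

    def theta_at(delta: float) -> float:
        return float(np.degrees(np.arccos(
            np.cos(phi * _DEG) * np.cos(delta * _DEG))))

    def objective(delta: float) -> float:
        chain = _finger_chain(skeleton, finger, theta_at(delta), pip, dip, delta)
        return _ray_angle(ref_chain, chain) - web_target

    try:
        delta = _solve_bracketed(objective, -25.0, 25.0, n_grid=201)
    except GenerationError:
        raise GenerationError(
            f"webspace target {web_target:.2f} deg unreachable for {finger} "
            "at matched ray inclination") from None
    return theta_at(delta), delta


def _pose_from_features(gesture: str, values: dict[str, float],
                        rng: np.random.Generator) -> PoseParameters:
    """Invert drawn feature values into pose parameters for one record.

    Unmeasured joints get mildly varied defaults.  For Gesture 2 the
    middle finger mirrors the drawn ring curl and the ring/little MCP
    flexions are chosen so all finger rays share a similar palmar
    inclination -- keeping small webspace targets geometrically reachable
    (the 3-D webspace angle is floored by any elevation mismatch between
    the flanking finger rays).
    """
    jitter = 0.0  # caller applies jitter via PoseParameters
    if gesture == "G1":
        flex = {
            "thumb_MCP": values["ag_thumb_MCP"],
            "index_MCP": values["ag_index_MCP"],
            "middle_MCP": values["ag_middle_MCP"],
            "ring_MCP": values["ag_ring_MCP"],
            "little_MCP": values["ag_little_MCP"],
            "thumb_CMC": rng.uniform(10, 20), "thumb_IP": rng.uniform(5, 15),
        }
        for f in FINGERS:
            flex[f"{f}_PIP"] = rng.uniform(3, 9)
            flex[f"{f}_DIP"] = rng.uniform(2, 8)
        return PoseParameters(flexion=flex, jitter_sd=jitter)
    if gesture == "G2":
        skeleton = HandSkeleton()
        mid_mcp = 20.0 + rng.uniform(-2, 2)
        rp, rd = values["ag_ring_PIP"], values["ag_ring_DIP"]
        lp, ld = values["ag_little_PIP"], values["ag_little_DIP"]
        # middle mirrors the ring curl; ring/little MCP angles are chosen so
        # their rays match the middle ray's palmar inclination at the solved
        # abduction offsets, making even near-zero webspace targets reachable
        target_incl = _planar_inclination(skeleton.finger_lengths["middle"], mid_mcp, rp, rd)
        mid_chain = _finger_chain(skeleton, "middle", mid_mcp, rp, rd, 0.0)
        ring_mcp, ring_delta = _g2_matched_mcp(
            skeleton, "ring", rp, rd, target_incl, values["web3"], mid_chain)
        ring_chain = _finger_chain(skeleton, "ring", ring_mcp, rp, rd, ring_delta)
        little_mcp, _ = _g2_matched_mcp(
            skeleton, "little", lp, ld, target_incl, values["web4"], ring_chain)
        flex = {
            "ring_PIP": rp, "ring_DIP": rd,
            "little_PIP": lp, "little_DIP": ld,
            "middle_PIP": rp, "middle_DIP": rd,
            "index_PIP": rng.uniform(4, 10), "index_DIP": rng.uniform(3, 8),
            "index_MCP": mid_mcp, "middle_MCP": mid_mcp,
            "ring_MCP": ring_mcp, "little_MCP": little_mcp,
            "thumb_CMC": rng.uniform(10, 20), "thumb_MCP": rng.uniform(5, 12),
            "thumb_IP": rng.uniform(5, 15),
        }
        return PoseParameters(flexion=flex, web3=values["web3"], web4=values["web4"],
                              jitter_sd=jitter)
    flex = {
        "thumb_CMC": -values["ag_thumb_CMC"],
        "thumb_MCP": -values["ag_thumb_MCP"],
        "thumb_IP": -values["ag_thumb_IP"],
        "index_MCP": -values["ag_index_MCP"],
        "index_PIP": -values["ag_index_PIP"],
        "index_DIP": -values["ag_index_DIP"],
        "middle_MCP": rng.uniform(5, 12), "middle_PIP": rng.uniform(4, 10),
        "middle_DIP": rng.uniform(3, 8),
        "ring_MCP": rng.uniform(5, 12), "ring_PIP": rng.uniform(4, 10),
        "ring_DIP": rng.uniform(3, 8),
        "little_MCP": rng.uniform(5, 12), "little_PIP": rng.uniform(4, 10),
        "little_DIP": rng.uniform(3, 8),
    }
    return PoseParameters(
        flexion=flex,
        palmar_abduction=-values["ag_palmab"],
        tip_distance=values["dis_tip"],
        jitter_sd=jitter,
    )


def _draw_primitive_values(gesture: str, moments: dict[str, GroupMoments],
                           rng: np.random.Generator) -> dict[str, float]:
    values = {}
    for name in registry.primitive_feature_names(gesture):
        lo, hi = _feasible_bounds(gesture, name)
        values[name] = _truncated_normal(rng, moments[name], lo, hi)
    return values


def sample_gesture(
    profile: InjuryProfile,
    gesture: str,
    n: int,
    seed: int | None = None,
    jitter_sd: float = 0.0,
    handedness: str = "right",
    subject_prefix: str = "S",
    max_retries: int = 100,
) -> CohortTable:
    """Generate n landmark records whose features follow the profile.

    Per record, primitive feature values are drawn from the group's
    Gaussians truncated at geometric feasibility, inverted to pose
    parameters and rendered through :func:`forward_kinematics`.  Records
    whose draw is kinematically unreachable are redrawn; a record failing
    ``max_retries`` consecutive draws raises :class:`GenerationError`
    reporting the retry count.  Records are labeled rep 1-4 cyclically
    under distinct synthetic subject ids.
    """
    rng = np.random.default_rng(seed)
    moments = profile.feature_moments(gesture)
    records = []
    for i in range(n):
        last_error: Exception | None = None
        for attempt in range(max_retries):
            values = _draw_primitive_values(gesture, moments, rng)
            try:
                pose = _pose_from_features(gesture, values, rng)
                pose.jitter_sd = jitter_sd
                rec = forward_kinematics(
                    HandSkeleton(), pose,
                    seed=int(rng.integers(2**31)) if jitter_sd > 0 else None,
                    handedness=handedness,
                    subject_id=f"{subject_prefix}{i // 4:04d}",
                    hand_side=handedness,
                    gesture=gesture,
                    repetition=(i % 4) + 1,
                    label=profile.injury,
                )
                records.append(rec)
                break
            except GenerationError as exc:
                last_error = exc
        else:
            raise GenerationError(
                f"record {i}: no feasible pose after {max_retries} retries "
                f"(last error: {last_error})")
    return CohortTable(records=records,
                       provenance=f"synthetic:{gesture}:{profile.injury}")


# ---------------------------------------------------------------------------
# Study-shaped cohort

@dataclass
class CohortConfig:
    """Composition of the synthetic study cohort.

    Defaults mirror the source study: 34 healthy volunteers and 22
    unilateral patients (10 radial, 5 ulnar, 1 median, 6 ulnar+median),
    2 hands each, 3 gestures, 4 repetitions -- 1,344 records, 448 per
    gesture task.
    """

    n_volunteers: int = 34
    patients: dict[str, int] = field(default_factory=lambda: {
        "radial": 10, "ulnar": 5, "median": 1, "ulnar+median": 6})
    repetitions: int = 4
    gestures: tuple[str, ...] = ("G1", "G2", "G3")
    rep_noise_frac: float = 0.25
    rho: float = 0.0
    jitter_sd: float = 0.0
    test_fraction: float = 0.25
    split_unit: Literal["image", "hand"] = "image"
    moments: dict[tuple[str, str], dict[str, GroupMoments]] = field(
        default_factory=lambda: REFERENCE_MOMENTS)

    def validate(self) -> None:
        if self.n_volunteers < 0 or any(v < 0 for v in self.patients.values()):
            raise GenerationError("cohort counts must be nonnegative")
        if not 1 <= self.repetitions <= 4:
            raise GenerationError("repetitions must be in 1..4")
        if not 0.0 < self.test_fraction < 1.0:
            raise GenerationError("test fraction must be in (0, 1)")
        if not 0.0 <= self.rep_noise_frac < 1.0:
            raise GenerationError("repetition-noise fraction must be in [0, 1)")
        bad = [k for k in self.patients if k not in ("radial", "ulnar", "median", "ulnar+median")]
        if bad:
            raise GenerationError(f"unknown injury keys: {bad}")

    @property
    def n_patients(self) -> int:
        return sum(self.patients.values())

    @property
    def n_subjects(self) -> int:
        return self.n_volunteers + self.n_patients

    @property
    def expected_records(self) -> int:
        return self.n_subjects * 2 * len(self.gestures) * self.repetitions


@dataclass
class SyntheticCohort:
    """A generated study-shaped dataset.

    ``features`` always holds the per-record feature table with metadata
    columns (subject_id, hand_side, gesture, repetition, label, group,
    split); ``records`` additionally holds landmark sets when the cohort
    was built kinematically.
    """

    features: pd.DataFrame
    records: CohortTable | None = None
    config: CohortConfig | None = None

    def gesture_frame(self, gesture: str) -> pd.DataFrame:
        return self.features.loc[self.features["gesture"] == gesture].reset_index(drop=True)

    def counts(self) -> dict[str, int]:
        per_gesture = self.features["gesture"].value_counts().to_dict()
        return {"total": len(self.features), **{g: int(per_gesture.get(g, 0))
                                                for g in ("G1", "G2", "G3")}}


def _hand_roster(config: CohortConfig, rng: np.random.Generator) -> list[dict]:
    """One entry per hand: subject id, side, injury label of that hand."""
    hands = []
    pid = 0
    for injury, count in config.patients.items():
        for _ in range(count):
            pid += 1
            injured_side = "right" if rng.random() < 0.5 else "left"
            for side in ("left", "right"):
                hands.append({
                    "subject_id": f"P{pid:02d}",
                    "hand_side": side,
                    "label": injury if side == injured_side else "none",
                })
    for v in range(1, config.n_volunteers + 1):
        for side in ("left", "right"):
            hands.append({"subject_id": f"V{v:02d}", "hand_side": side, "label": "none"})
    return hands


def _stratified_assign(frame: pd.DataFrame, config: CohortConfig,
                       rng: np.random.Generator) -> pd.Series:
    """Train/test assignment, stratified by group within each gesture."""
    split = pd.Series("train", index=frame.index, dtype=object)
    unit_cols = (["subject_id", "hand_side"] if config.split_unit == "hand" else None)
    for (_, _), idx in frame.groupby(["gesture", "group"]).groups.items():
        idx = np.asarray(list(idx))
        if unit_cols is None:
            if idx.size < 2:
                continue  # degenerate stratum stays in train
            perm = rng.permutation(idx)
            n_test = int(round(idx.size * config.test_fraction))
            split.loc[perm[:n_test]] = "test"
        else:
            units = frame.loc[idx, unit_cols].apply(tuple, axis=1).unique()
            perm = rng.permutation(len(units))
            n_test = int(round(len(units) * config.test_fraction))
            test_units = {tuple(units[i]) for i in perm[:n_test]}
            mask = frame.loc[idx, unit_cols].apply(tuple, axis=1).isin(test_units)
            split.loc[idx[mask.to_numpy()]] = "test"
    return split


def build_study_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    method: Literal["moments", "kinematic"] = "moments",
) -> SyntheticCohort:
    """Build a full study-shaped synthetic cohort.

    ``moments`` draws feature vectors directly from the group Gaussians;
    ``kinematic`` additionally renders every record through the forward
    model (features are then recomputed from landmarks downstream, and
    drawn values are clipped to kinematic feasibility first).  Repetitions
    of one hand share a latent severity draw; repetition noise has SD
    ``rep_noise_frac`` x group SD, with the two components scaled so the
    marginal matches the configured moments.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    hands = _hand_roster(config, rng)

    q = config.rep_noise_frac
    latent_scale = np.sqrt(1.0 - q * q)
    rows = []
    lm_records = []
    for hand in hands:
        profile = InjuryProfile(injury=hand["label"], moments=config.moments)
        for gesture in config.gestures:
            group = profile.group_for(gesture)
            moments = profile.feature_moments(gesture)
            names = list(moments)
            common = rng.standard_normal()
            latent = {
                name: np.sqrt(config.rho) * common
                + np.sqrt(1.0 - config.rho) * rng.standard_normal()
                for name in names
            }
            for rep in range(1, config.repetitions + 1):
                values = {}
                for name in names:
                    m = moments[name]
                    z = latent_scale * latent[name] + q * rng.standard_normal()
                    values[name] = m.mean + m.sd * z
                if method == "kinematic":
                    # redraw the repetition noise (latent kept) if the drawn
                    # combination is kinematically unreachable; if the hand's
                    # latent severity itself is unrealizable, redraw it too
                    rec = None
                    last_error: Exception | None = None
                    for attempt in range(100):
                        if attempt and attempt % 5 == 0:
                            latent = {
                                name: np.sqrt(config.rho) * common
                                + np.sqrt(1.0 - config.rho) * rng.standard_normal()
                                for name in names
                            }
                        prim = {}
                        for name in registry.primitive_feature_names(gesture):
                            lo, hi = _feasible_bounds(gesture, name)
                            prim[name] = float(np.clip(values[name], lo, hi))
                        try:
                            pose = _pose_from_features(gesture, prim, rng)
                            pose.jitter_sd = config.jitter_sd
                            rec = forward_kinematics(
                                HandSkeleton(), pose,
                                seed=int(rng.integers(2**31)) if config.jitter_sd > 0 else None,
                                handedness=hand["hand_side"],
                                subject_id=hand["subject_id"],
                                hand_side=hand["hand_side"],
                                gesture=gesture,
                                repetition=rep,
                                label=hand["label"],
                            )
                            break
                        except GenerationError as exc:
                            last_error = exc
                            values = {
                                name: moments[name].mean + moments[name].sd
                                * (latent_scale * latent[name] + q * rng.standard_normal())
                                for name in names
                            }
                    if rec is None:
                        raise GenerationError(
                            f"{hand['subject_id']}/{hand['hand_side']}/{gesture} rep {rep}: "
                            f"no feasible pose after 100 retries ({last_error})")
                    lm_records.append(rec)
                    values = dict(compute_features(rec).values)
                row = {
                    "subject_id": hand["subject_id"],
                    "hand_side": hand["hand_side"],
                    "gesture": gesture,
                    "repetition": rep,
                    "label": hand["label"],
                    "group": "target" if group == "target" else "non-target",
                }
                row.update(values)
                rows.append(row)

    frame = pd.DataFrame(rows)
    frame["split"] = _stratified_assign(frame, config, rng)
    meta = ["subject_id", "hand_side", "gesture", "repetition", "label", "group", "split"]
    feat_cols = [c for c in frame.columns if c not in meta]
    frame = frame[meta + feat_cols]
    records = None
    if method == "kinematic":
        records = CohortTable(records=lm_records, provenance="synthetic:study-cohort")
    return SyntheticCohort(features=frame, records=records, config=config)
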