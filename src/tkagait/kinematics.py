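"""Tibiofemoral kinematics from implant poses.

Computes anatomical knee rotations (joint-coordinate-system / Grood–Suntay
style decomposition), condylar anterior–posterior (A-P) translations relative
to the tibial plateau, 101-point time-normalized gait cycles, per-phase
range-of-motion (RoM) summaries and force-plate heel-strike detection.

Coordinate convention (both implant frames)
-------------------------------------------
x: anterior, y: proximal (up), z: medio-lateral (lateral condyle at +z).
A pose is the 4x4 homogeneous transform mapping femoral-component
coordinates into the tibial-component frame, in millimetres.

Angle convention
----------------
Flexion about the femoral z axis (fixed axis), internal rotation about the
tibial y axis (fixed axis), ab/adduction about the mutually perpendicular
floating axis, i.e. the rotation block factorizes as

    R = Rz(flexion) @ Rx(adduction) @ Ry(internal)

Signs: flexion positive, adduction positive, internal rotation positive.
Translations in mm, angles in degrees, time as % of the gait cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GimbalLockError",
    "GaitEvents",
    "PoseSeries",
    "TibialPlane",
    "CondyleGeometry",
    "KinematicCycle",
    "RoMSummary",
    "compose_grood_suntay",
    "decompose_grood_suntay",
    "condylar_ap",
    "pose_tracks",
    "time_normalize_cycle",
    "rom_summary",
    "detect_heelstrike",
]

#: parameters carried through a kinematic cycle, in fixed order
CYCLE_PARAMETERS = ("flexion", "abduction", "internal", "medial_ap", "lateral_ap")

_ORTHO_TOL = 1e-6
_GIMBAL_LIMIT_DEG = 89.0


class GimbalLockError(ValueError):
    """Raised when ab/adduction approaches +/-90 deg and the decomposition degenerates."""


# ---------------------------------------------------------------------------
# rotation decomposition
# ---------------------------------------------------------------------------

def compose_grood_suntay(flexion: float, adduction: float, internal: float) -> np.ndarray:
    """Build the 3x3 rotation block from knee angles in degrees.

    Inverse of :func:`decompose_grood_suntay`; see module docstring for the
    axis convention.
    """
    a, b, c = np.deg2rad([flexion, adduction, internal])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    return np.array(
        [
            [ca * cc - sa * sb * sc, -sa * cb, ca * sc + sa * sb * cc],
            [sa * cc + ca * sb * sc, ca * cb, sa * sc - ca * sb * cc],
            [-cb * sc, sb, cb * cc],
        ]
    )


def _rotation_block(pose: np.ndarray) -> np.ndarray:
    pose = np.asarray(pose, dtype=float)
    if pose.shape == (4, 4):
        return pose[:3, :3]
    if pose.shape == (3, 3):
        return pose
    raise ValueError(f"expected a 3x3 or 4x4 pose, got shape {pose.shape}")


def decompose_grood_suntay(pose: np.ndarray) -> tuple[float, float, float]:
    """Decompose a pose into (flexion, adduction, internal) in degrees.

    Raises
    ------
    ValueError
        If the rotation block is not orthonormal to 1e-6.
    GimbalLockError
        If |ab/adduction| exceeds 89 deg, where flexion and internal
        rotation axes align and the split becomes ill-conditioned.
    """
    R = _rotation_block(pose)
    if np.linalg.norm(R.T @ R - np.eye(3)) > _ORTHO_TOL:
        raise ValueError("rotation block is not orthonormal (||R'R - I|| > 1e-6)")
    sb = np.clip(R[2, 1], -1.0, 1.0)
    adduction = np.rad2deg(np.arcsin(sb))
    if abs(adduction) > _GIMBAL_LIMIT_DEG:
        raise GimbalLockError(
            f"ab/adduction = {adduction:.2f} deg is within 1 deg of gimbal lock"
        )
    flexion = np.rad2deg(np.arctan2(-R[0, 1], R[1, 1]))
    internal = np.rad2deg(np.arctan2(-R[2, 0], R[2, 2]))
    return float(flexion), float(adduction), float(internal)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitEvents:
    """Frame indices of the two heel-strikes and the intervening toe-off."""

    heel_strike_1: int
    toe_off: int
    heel_strike_2: int

    def __post_init__(self) -> None:
        if not self.heel_strike_1 < self.toe_off < self.heel_strike_2:
            raise ValueError(
                "gait events must satisfy heel_strike_1 < toe_off < heel_strike_2, "
                f"got {self.heel_strike_1}, {self.toe_off}, {self.heel_strike_2}"
            )


@dataclass
class PoseSeries:
    """Per-frame femoral-in-tibial homogeneous transforms with gait events.

    frames: (n, 4, 4) array, mm; rate in Hz (fluoroscopy runs at 30 Hz).
    """

    frames: np.ndarray
    events: GaitEvents
    rate: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (4, 4):
            raise ValueError(f"frames must be (n, 4, 4), got {self.frames.shape}")
        if not np.isfinite(self.frames).all():
            raise ValueError("pose frames contain non-finite values")
        R = self.frames[:, :3, :3]
        err = np.linalg.norm(
            np.einsum("nij,nik->njk", R, R) - np.eye(3), axis=(1, 2)
        )
        if err.max(initial=0.0) > _ORTHO_TOL:
            raise ValueError("rotation blocks are not orthonormal to 1e-6")
        n = len(self.frames)
        if not (0 <= self.events.heel_strike_1 and self.events.heel_strike_2 < n):
            raise ValueError("gait events fall outside the pose series")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TibialPlane:
    """Tibial plateau reference plane: point on plane, unit normal, unit A-P axis."""

    point: np.ndarray
    normal: np.ndarray
    ap_axis: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.ap_axis = np.asarray(self.ap_axis, dtype=float)
        for name, v in (("normal", self.normal), ("ap_axis", self.ap_axis)):
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise ValueError(f"{name} must be unit length")
        if abs(self.normal @ self.ap_axis) > _ORTHO_TOL:
            raise ValueError("ap_axis must be perpendicular to the plane normal")


@dataclass
class CondyleGeometry:
    """Condyle point clouds in the femoral component frame plus tibial plane."""

    medial_points: np.ndarray
    lateral_points: np.ndarray
    tibial_plane: TibialPlane

    def __post_init__(self) -> None:
        self.medial_points = np.asarray(self.medial_points, dtype=float)
        self.lateral_points = np.asarray(self.lateral_points, dtype=float)
        for name, pts in (
            ("medial_points", self.medial_points),
            ("lateral_points", self.lateral_points),
        ):
            if pts.ndim != 2 or pts.shape[1] != 3:
                raise ValueError(f"{name} must be (n, 3)")
            if len(pts) < 10:
                raise ValueError(f"{name}: need at least 10 points, got {len(pts)}")


@dataclass
class KinematicCycle:
    """101-point normalized gait cycle of 3 angles and 2 condylar A-P tracks.

    A-P tracks are referenced to the medial condyle position at the initial
    heel-strike, so ``medial_ap[0] == 0`` by construction.
    """

    flexion: np.ndarray
    abduction: np.ndarray
    internal: np.ndarray
    medial_ap: np.ndarray
    lateral_ap: np.ndarray
    toe_off_pct: float

    def __post_init__(self) -> None:
        for name in CYCLE_PARAMETERS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (101,):
                raise ValueError(f"{name} must have exactly 101 points")
            setattr(self, name, arr)
        if not 0.0 < self.toe_off_pct < 100.0:
            raise ValueError("toe_off_pct must lie strictly inside the cycle")

    def track(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class RoMSummary:
    """Per-phase max-min RoM per parameter plus the intercondylar A-P difference.

    ``stance`` / ``swing`` map parameter name -> RoM; the extra key
    ``intercondylar_ap_diff`` is lateral A-P RoM minus medial A-P RoM (mm),
    the transverse-plane pivot indicator (negative = medial pivot).
    """

    stance: dict = field(default_factory=dict)
    swing: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# condylar A-P translation
# ---------------------------------------------------------------------------

def condylar_ap(
    pose: np.ndarray,
    geometry: CondyleGeometry,
    n_nearest: int = 10,
    eps_mm: float = 0.1,
) -> tuple[float, float]:
    """A-P coordinate (mm) of the weighted nearest-point centroid of each condyle.

    Condyle points are mapped into the tibial frame; per condyle the
    ``n_nearest`` points with smallest *signed* distance to the plateau plane
    are selected (penetration counts as nearest), and their A-P coordinates
    are averaged with weights proportional to 1/(|distance| + eps_mm),
    renormalized to sum to one. The inverse-distance kernel is a documented
    choice (closest points dominate; eps guards zero distance) and can be
    swapped by passing ``eps_mm``/``n_nearest``.

    Returns ``(medial_ap, lateral_ap)``.
    """
    pose = np.asarray(pose, dtype=float)
    if pose.shape != (4, 4):
        raise ValueError("pose must be a 4x4 homogeneous transform")
    R, t = pose[:3, :3], pose[:3, 3]
    plane = geometry.tibial_plane
    out = []
    for pts in (geometry.medial_points, geometry.lateral_points):
        if len(pts) < n_nearest:
            raise ValueError(
                f"condyle has {len(pts)} points; need at least {n_nearest}"
            )
        q = pts @ R.T + t
        rel = q - plane.point
        dist = rel @ plane.normal
        sel = np.argsort(dist, kind="stable")[:n_nearest]
        w = 1.0 / (np.abs(dist[sel]) + eps_mm)
        w /= w.sum()
        out.append(float(w @ (rel[sel] @ plane.ap_axis)))
    return out[0], out[1]


def pose_tracks(series: PoseSeries, geometry: CondyleGeometry) -> dict[str, np.ndarray]:
    """Per-frame angle and condylar A-P tracks for a pose series."""
    n = len(series)
    tracks = {name: np.empty(n) for name in CYCLE_PARAMETERS}
    for i, frame in enumerate(series.frames):
        fl, ad, ir = decompose_grood_suntay(frame)
        med, lat = condylar_ap(frame, geometry)
        tracks["flexion"][i] = fl
        tracks["abduction"][i] = ad
        tracks["internal"][i] = ir
        tracks["medial_ap"][i] = med
        tracks["lateral_ap"][i] = lat
    return tracks


# ---------------------------------------------------------------------------
# time normalization and RoM
# ---------------------------------------------------------------------------

def time_normalize_cycle(series: PoseSeries, tracks: dict[str, np.ndarray]) -> KinematicCycle:
    """Resample heel-strike-to-heel-strike tracks onto 101 points.

    Linear interpolation over frame index; condylar A-P tracks are then
    referenced to the medial condyle position at the initial heel-strike.
    """
    ev = series.events
    src = np.arange(ev.heel_strike_1, ev.heel_strike_2 + 1, dtype=float)
    if len(src) < 2:
        raise ValueError("cycle must span at least two frames")
    dst = np.linspace(src[0], src[-1], 101)
    resampled = {}
    for name in CYCLE_PARAMETERS:
        y = np.asarray(tracks[name], dtype=float)
        if len(y) != len(series):
            raise ValueError(f"track '{name}' length {len(y)} != series length {len(series)}")
        resampled[name] = np.interp(dst, src, y[ev.heel_strike_1 : ev.heel_strike_2 + 1])
    ref = resampled["medial_ap"][0]
    resampled["medial_ap"] = resampled["medial_ap"] - ref
    resampled["lateral_ap"] = resampled["lateral_ap"] - ref
    toe_off_pct = 100.0 * (ev.toe_off - ev.heel_strike_1) / (ev.heel_strike_2 - ev.heel_strike_1)
    return KinematicCycle(toe_off_pct=toe_off_pct, **resampled)


def rom_summary(cycle: KinematicCycle) -> RoMSummary:
    """Max-minus-min RoM per phase and parameter, with the intercondylar A-P diff.

    Stance runs from point 1 to the toe-off point, swing from the toe-off
    point to point 101; the toe-off sample belongs to both phases.
    """
    to_idx = int(round(cycle.toe_off_pct))
    to_idx = min(max(to_idx, 1), 99)
    phases = {"stance": slice(0, to_idx + 1), "swing": slice(to_idx, 101)}
    out = RoMSummary()
    for phase, sl in phases.items():
        d = getattr(out, phase)
        for name in CYCLE_PARAMETERS:
            seg = cycle.track(name)[sl]
            d[name] = float(seg.max() - seg.min())
        d["intercondylar_ap_diff"] = d["lateral_ap"] - d["medial_ap"]
    return out


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_heelstrike(force: np.ndarray, threshold: float = 25.0) -> int | None:
    """Index of the first upward crossing of the vertical-force threshold (25 N).

    Returns ``None`` when the trace never reaches the threshold. A trace that
    starts at or above the threshold reports index 0.
    """
    f = np.asarray(force, dtype=float)
    if f.ndim != 1 or len(f) == 0:
        raise ValueError("force must be a non-empty 1-D trace")
    if f[0] >= threshold:
        return 0
    above = f >= threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0]
    if len(crossings) == 0:
        return None
    return int(crossings[0] + 1)
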