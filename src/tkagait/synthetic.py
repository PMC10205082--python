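"""Synthetic gait-trial generator with known ground truth.

Emulates the study conditions of a fluoroscopy + EMG gait experiment in two
TKA cohorts (10 "stable", 8 "unstable" knees; 3-5 cycles per subject;
level walking, downhill walking, stair descent): per-frame femoral-in-tibial
implant poses at 30 Hz with condyle point clouds and a tibial plateau plane,
8-channel surface EMG at 2000 Hz built from planted synergy modules and
activation patterns, and vertical ground-reaction force at 2000 Hz whose
25 N threshold crossing reproduces the stored heel-strike.

Kinematic curves are smooth shape-preserving (PCHIP) bumps per gait phase
whose stance/swing ranges of motion are drawn per subject from normal
distributions centred on the published group statistics, so generated
cohorts match the reported RoM tables without claiming waveform fidelity.
Raw EMG is a band-limited (50-450 Hz) Gaussian carrier amplitude-modulated
by the planted envelope, a model chosen because the standard conditioning
chain (50 Hz high-pass, rectification, 20 Hz low-pass) then provably
recovers the envelope up to a constant gain that amplitude normalization
absorbs.

Seeding: one master seed; every subject/trial/purpose gets an independent
stream via ``SeedSequence(seed, spawn_key=...)`` so adding a subject or
requesting one generator (poses, EMG, force) in isolation never perturbs
the others. Identical (spec, seed) inputs give bit-identical outputs.

An optional acute-instability event superposes a posterior-then-anterior
condylar A-P excursion inside the 55-80 % cycle window (early/mid swing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy import signal

from .emg import MUSCLES, N_POINTS, RawEMG
from .kinematics import (
    CondyleGeometry,
    GaitEvents,
    PoseSeries,
    TibialPlane,
    compose_grood_suntay,
    condylar_ap,
)
from .synergies import SynergySet

__all__ = [
    "ACTIVITIES",
    "GROUP_LABELS",
    "CohortSpec",
    "InstabilityEventSpec",
    "GroundTruthSynergies",
    "TrialKinematics",
    "TrialEMG",
    "TrialForce",
    "default_truth",
    "template_curves",
    "generate_kinematics",
    "generate_emg",
    "generate_force",
    "planted_synergy_sets",
]

ACTIVITIES = ("level", "downhill", "stair")
GROUP_LABELS = ("stable", "unstable")

POSE_RATE = 30.0     # Hz, fluoroscopic frame rate
EMG_RATE = 2000.0    # Hz
FORCE_RATE = 2000.0  # Hz, force plates

#: default toe-off as % cycle; the source tables do not print toe-off, these
#: sit at the dotted-line positions typical for the three activities
TOE_OFF_PCT = {"level": 60.0, "downhill": 60.0, "stair": 65.0}
CYCLE_DURATION_S = {"level": 1.10, "downhill": 1.15, "stair": 1.40}

# Published rotation RoM statistics (degrees): per activity, group and
# parameter, (stance_mean, stance_sd, swing_mean, swing_sd).
ROTATION_ROM = {
    "level": {
        "stable": {
            "flexion": (47.2, 4.9, 61.8, 4.4),
            "internal": (7.7, 1.1, 6.9, 1.8),
            "abduction": (2.1, 0.2, 2.8, 0.5),
        },
        "unstable": {
            "flexion": (43.5, 6.8, 59.6, 8.0),
            "internal": (7.0, 1.8, 7.8, 2.5),
            "abduction": (2.1, 0.3, 2.7, 0.7),
        },
    },
    "downhill": {
        "stable": {
            "flexion": (57.9, 3.8, 68.6, 4.6),
            "internal": (5.5, 0.9, 7.0, 1.3),
            "abduction": (2.2, 0.3, 2.5, 0.4),
        },
        "unstable": {
            "flexion": (54.9, 4.3, 67.4, 6.7),
            "internal": (6.1, 1.2, 8.2, 1.8),
            "abduction": (2.8, 0.3, 2.8, 0.7),
        },
    },
    "stair": {
        "stable": {
            "flexion": (84.4, 3.4, 91.2, 4.5),
            "internal": (8.7, 1.2, 9.4, 1.9),
            "abduction": (3.5, 0.5, 2.8, 0.6),
        },
        "unstable": {
            "flexion": (84.5, 11.7, 92.8, 5.8),
            "internal": (8.4, 1.0, 10.3, 2.6),
            "abduction": (3.3, 0.4, 3.1, 0.9),
        },
    },
}

# Published medial condyle A-P RoM statistics (mm): (stance_mean, stance_sd,
# swing_mean, swing_sd) per activity and group.
MEDIAL_AP_ROM = {
    "level": {"stable": (5.4, 1.4, 7.0, 2.5), "unstable": (4.5, 0.9, 6.2, 1.6)},
    "downhill": {"stable": (4.2, 0.9, 5.7, 1.5), "unstable": (3.4, 1.0, 5.5, 1.5)},
    "stair": {"stable": (5.1, 1.6, 7.7, 1.7), "unstable": (4.6, 1.2, 6.9, 1.7)},
}

_ANGLE_BASELINES = {"flexion": 5.0, "abduction": 0.5, "internal": -2.0}
_CONDYLE_SEPARATION_MM = 42.0  # medial-to-lateral condyle centre distance
_CONDYLE_RADIUS_MM = 24.0
_CONDYLE_N_POINTS = 120
_PLANE_CLEARANCE_MM = 0.3

# spawn-key stream ids
_S_KIN_SUBJ, _S_TIMING, _S_KIN_CYC, _S_EMG_CYC, _S_FORCE_CYC, _S_EMG_SUBJ, _S_FORCE_SUBJ = range(7)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """One cohort x activity: group label, sizes and the master seed."""

    group_label: str
    n_subjects: int
    cycles_per_subject: int
    activity: str
    seed: int

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"group_label must be one of {GROUP_LABELS}")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"activity must be one of {ACTIVITIES}")
        for name in ("n_subjects", "cycles_per_subject", "seed"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite integer")
        if self.n_subjects < 1 or self.cycles_per_subject < 1:
            raise ValueError("n_subjects and cycles_per_subject must be >= 1")


@dataclass(frozen=True)
class InstabilityEventSpec:
    """Acute-instability A-P excursion: rapid posterior slide then anterior return.

    The excursion is confined to the 55-80 % cycle window (early/mid swing).
    ``affected_condyles`` is 'medial', 'lateral' or 'both'.
    """

    onset_pct: float
    posterior_amplitude_mm: float
    anterior_amplitude_mm: float
    affected_condyles: str = "both"

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_pct <= 100.0):
            raise ValueError("onset_pct must lie in [0, 100]")
        if self.posterior_amplitude_mm < 0 or self.anterior_amplitude_mm < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.affected_condyles not in ("medial", "lateral", "both"):
            raise ValueError("affected_condyles must be 'medial', 'lateral' or 'both'")
        for name in ("onset_pct", "posterior_amplitude_mm", "anterior_amplitude_mm"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruthSynergies:
    """Planted synergy modules (8 x k, unit-max columns) and patterns (k x 200)."""

    modules: np.ndarray
    patterns: np.ndarray
    k: int
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.modules = np.asarray(self.modules, dtype=float)
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.modules.shape != (len(MUSCLES), self.k):
            raise ValueError(f"modules must be ({len(MUSCLES)}, k)")
        if self.patterns.shape != (self.k, N_POINTS):
            raise ValueError(f"patterns must be (k, {N_POINTS})")
        if self.modules.min() < 0 or self.patterns.min() < 0:
            raise ValueError("ground-truth synergies must be non-negative")
        col_max = self.modules.max(axis=0)
        if not np.allclose(col_max, 1.0, atol=1e-9):
            raise ValueError("module columns must have unit maximum")


# ---------------------------------------------------------------------------
# planted synergy truths
# ---------------------------------------------------------------------------

def _circular_bump(center: float, sigma: float, amp: float = 1.0) -> np.ndarray:
    t = np.arange(N_POINTS, dtype=float)
    d = (t - center + N_POINTS / 2) % N_POINTS - N_POINTS / 2
    return amp * np.exp(-0.5 * (d / sigma) ** 2)


_MODULE_WEIGHTS = {
    "knee_extensors": [0.85, 1.0, 0.95, 0.05, 0.04, 0.04, 0.06, 0.05],
    "plantarflexors": [0.04, 0.05, 0.05, 0.06, 0.05, 0.05, 1.00, 0.92],
    "dorsiflexors": [0.05, 0.04, 0.04, 1.00, 0.06, 0.05, 0.03, 0.03],
    "knee_flexors": [0.05, 0.06, 0.05, 0.05, 1.00, 0.90, 0.08, 0.06],
    "dorsi_knee_flexors": [0.05, 0.05, 0.05, 0.85, 1.00, 0.90, 0.05, 0.05],
}


def default_truth(activity: str, flexor_width_scale: float = 1.0) -> GroundTruthSynergies:
    """Planted synergy set for an activity (k=4 level/downhill, k=3 stair).

    Activation-pattern timing follows the published description: knee
    extensors in early stance (level) or throughout stance, plantarflexors
    in late stance (level/downhill) or mid-late swing (stair), dorsiflexors
    at early stance + early swing (level) or sustained, knee flexors in
    late swing / early stance. ``flexor_width_scale`` multiplies the width
    (sigma) of the flexor-dominated pattern, the knob used to plant the
    prolonged flexor activation reported for unstable knees.
    """
    base = 0.01
    w = flexor_width_scale
    if activity in ("level", "downhill"):
        labels = ("knee_extensors", "plantarflexors", "dorsiflexors", "knee_flexors")
        if activity == "level":
            patterns = [
                _circular_bump(15, 11),
                _circular_bump(62, 10),
                _circular_bump(5, 6, 0.9) + _circular_bump(112, 9),
                _circular_bump(188, 8 * w),
            ]
        else:
            patterns = [
                _circular_bump(22, 12),
                _circular_bump(48, 9),
                _circular_bump(90, 18),
                _circular_bump(190, 8 * w) + _circular_bump(58, 6, 0.45),
            ]
    elif activity == "stair":
        labels = ("knee_extensors", "plantarflexors", "dorsi_knee_flexors")
        patterns = [
            _circular_bump(40, 13.5),
            _circular_bump(160, 11),
            _circular_bump(100, 8.5 * w),
        ]
    else:
        raise ValueError(f"unknown activity {activity!r}")
    H = np.clip(np.vstack(patterns), 0.0, None) + base
    W = np.array([_MODULE_WEIGHTS[lab] for lab in labels]).T
    return GroundTruthSynergies(modules=W, patterns=H, k=len(labels), labels=labels)


# ---------------------------------------------------------------------------
# parametric kinematic curves
# ---------------------------------------------------------------------------

def _phase_bump(pct: np.ndarray, x0: float, x1: float, amp: float, frac: float = 0.5) -> np.ndarray:
    """Shape-preserving bump: 0 at x0 and x1, extremum amp at x0 + frac*(x1-x0)."""
    out = np.zeros_like(pct)
    if amp == 0.0 or x1 <= x0:
        return out
    spline = PchipInterpolator([x0, x0 + frac * (x1 - x0), x1], [0.0, amp, 0.0])
    mask = (pct >= x0) & (pct <= x1)
    out[mask] = spline(pct[mask])
    return out


def _shaped_phase(pct: np.ndarray, x0: float, x1: float, rom: float, shape: tuple) -> np.ndarray:
    """One gait-phase excursion with exact RoM (max - min = rom).

    ``shape`` is ('uni', sign) for a single mid-phase bump, or
    ('bi', sign1, sign2, share) for two opposite-signed bumps occupying the
    phase halves with amplitude split share / (1 - share). PCHIP bumps never
    overshoot their control values, so the phase RoM equals ``rom`` exactly.
    """
    if shape[0] == "uni":
        return _phase_bump(pct, x0, x1, shape[1] * rom)
    _, s1, s2, share = shape
    xm = 0.5 * (x0 + x1)
    return _phase_bump(pct, x0, xm, s1 * share * rom) + _phase_bump(
        pct, xm, x1, s2 * (1.0 - share) * rom
    )


# Per-track phase shapes. The internal-rotation and medial-A-P shapes are
# deliberately de-phased (bimodal halves) so the *derived* lateral condylar
# track, which physically equals the medial track plus the vertical-axis
# rotation times the intercondylar separation, sweeps a realistic range
# instead of cancelling to near zero.
_TRACK_SHAPES = {
    "flexion": (("uni", 1), ("uni", 1)),
    "abduction": (("uni", 1), ("uni", 1)),
    "internal": (("bi", -1, 1, 0.45), ("uni", -1)),
    "medial_ap": (("uni", -1), ("bi", -1, 1, 0.45)),
}


def _rom_curve(
    pct: np.ndarray,
    toe_off_pct: float,
    base: float,
    stance_rom: float,
    swing_rom: float,
    track: str,
) -> np.ndarray:
    """Curve whose stance (0..toe-off) and swing (toe-off..100) RoMs are exact."""
    st_shape, sw_shape = _TRACK_SHAPES[track]
    return (
        base
        + _shaped_phase(pct, 0.0, toe_off_pct, stance_rom, st_shape)
        + _shaped_phase(pct, toe_off_pct, 100.0, swing_rom, sw_shape)
    )


def _event_excursion(pct: np.ndarray, event: InstabilityEventSpec) -> np.ndarray:
    """Posterior-then-anterior A-P excursion confined to the 55-80 % window."""
    t0 = float(np.clip(event.onset_pct, 55.0, 80.0))
    t1 = min(t0 + 20.0, 80.0)
    tm = 0.5 * (t0 + t1)
    out = np.zeros_like(pct)
    for lo, hi, amp in ((t0, tm, -event.posterior_amplitude_mm), (tm, t1, event.anterior_amplitude_mm)):
        if hi <= lo:
            continue
        mask = (pct >= lo) & (pct <= hi)
        out[mask] += amp * np.sin(np.pi * (pct[mask] - lo) / (hi - lo)) ** 2
    return out


@dataclass
class SubjectKinematicParams:
    toe_off_pct: float
    duration_factor: float
    angle_base: dict
    angle_rom: dict    # parameter -> (stance_rom, swing_rom)
    medial_ap_rom: tuple[float, float]


def _subject_kinematic_params(spec: CohortSpec, subject: int, subject_noise: float) -> SubjectKinematicParams:
    rng = _rng(spec.seed, _S_KIN_SUBJ, subject)
    rng_t = _rng(spec.seed, _S_TIMING, subject)
    duration_factor = 1.0 + 0.05 * rng_t.standard_normal()
    toe_off = float(np.clip(TOE_OFF_PCT[spec.activity] + 1.5 * rng_t.standard_normal(), 52.0, 72.0))
    rot = ROTATION_ROM[spec.activity][spec.group_label]
    angle_rom, angle_base = {}, {}
    for name in ("flexion", "abduction", "internal"):
        st_m, st_sd, sw_m, sw_sd = rot[name]
        st = st_m + subject_noise * st_sd * rng.standard_normal()
        sw = sw_m + subject_noise * sw_sd * rng.standard_normal()
        angle_rom[name] = (max(st, 0.2 * st_m), max(sw, 0.2 * sw_m))
        angle_base[name] = _ANGLE_BASELINES[name] + subject_noise * 1.0 * rng.standard_normal()
    st_m, st_sd, sw_m, sw_sd = MEDIAL_AP_ROM[spec.activity][spec.group_label]
    ap_st = max(st_m + subject_noise * st_sd * rng.standard_normal(), 0.2 * st_m)
    ap_sw = max(sw_m + subject_noise * sw_sd * rng.standard_normal(), 0.2 * sw_m)
    return SubjectKinematicParams(
        toe_off_pct=toe_off,
        duration_factor=duration_factor,
        angle_base=angle_base,
        angle_rom=angle_rom,
        medial_ap_rom=(ap_st, ap_sw),
    )


@dataclass
class TrialTiming:
    duration_s: float
    toe_off_s: float
    n_frames: int
    events: GaitEvents
    toe_off_pct: float   # toe-off as % cycle on the continuous axis


def _trial_timing(spec: CohortSpec, subject: int, cycle: int) -> TrialTiming:
    params = _subject_kinematic_params(spec, subject, subject_noise=0.0)
    rng = _rng(spec.seed, _S_TIMING, subject, cycle)
    duration = CYCLE_DURATION_S[spec.activity] * params.duration_factor * (1.0 + 0.02 * rng.standard_normal())
    n_frames = int(round(duration * POSE_RATE)) + 1
    toe_off_s = duration * params.toe_off_pct / 100.0
    to_frame = int(np.clip(round(toe_off_s * POSE_RATE), 1, n_frames - 2))
    return TrialTiming(
        duration_s=duration,
        toe_off_s=toe_off_s,
        n_frames=n_frames,
        events=GaitEvents(0, to_frame, n_frames - 1),
        toe_off_pct=params.toe_off_pct,
    )


def template_curves(
    activity: str,
    group_label: str,
    pct: np.ndarray,
    toe_off_pct: float | None = None,
) -> dict[str, np.ndarray]:
    """Noise-free activity/group template curves evaluated at ``pct`` (% cycle)."""
    if toe_off_pct is None:
        toe_off_pct = TOE_OFF_PCT[activity]
    rot = ROTATION_ROM[activity][group_label]
    ap = MEDIAL_AP_ROM[activity][group_label]
    out = {}
    for name in ("flexion", "abduction", "internal"):
        st_m, _, sw_m, _ = rot[name]
        out[name] = _rom_curve(pct, toe_off_pct, _ANGLE_BASELINES[name], st_m, sw_m, name)
    out["medial_ap"] = _rom_curve(pct, toe_off_pct, 0.0, ap[0], ap[2], "medial_ap")
    return out


# ---------------------------------------------------------------------------
# pose synthesis
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y**2)
    pts = np.column_stack([np.cos(phi) * r, y, np.sin(phi) * r]) * radius
    return pts + center


def _default_geometry() -> CondyleGeometry:
    half = _CONDYLE_SEPARATION_MM / 2.0
    medial = _fibonacci_sphere(
        _CONDYLE_N_POINTS, _CONDYLE_RADIUS_MM, np.array([0.0, _CONDYLE_RADIUS_MM, -half])
    )
    lateral = _fibonacci_sphere(
        _CONDYLE_N_POINTS, _CONDYLE_RADIUS_MM, np.array([0.0, _CONDYLE_RADIUS_MM, half])
    )
    plane = TibialPlane(
        point=np.zeros(3), normal=np.array([0.0, 1.0, 0.0]), ap_axis=np.array([1.0, 0.0, 0.0])
    )
    return CondyleGeometry(medial_points=medial, lateral_points=lateral, tibial_plane=plane)


@dataclass
class TrialKinematics:
    """One generated gait cycle: poses, geometry and the ground-truth curves.

    ``truth`` keys: pct, flexion, abduction, internal, medial_ap, lateral_ap
    (per pose frame), toe_off_pct.
    """

    poses: PoseSeries
    geometry: CondyleGeometry
    truth: dict
    subject: int
    cycle: int


def _build_pose(
    angles_deg: tuple[float, float, float],
    medial_ap_target: float,
    geometry: CondyleGeometry,
    n_nearest: int = 10,
    eps_mm: float = 0.1,
) -> np.ndarray:
    """4x4 pose realizing given angles with the medial condylar A-P on target.

    The A-P readout of the weighted nearest-point centroid is linear in the
    pose's A-P translation component, so the translation is solved exactly;
    the vertical translation seats the condyles just above the plateau plane.
    """
    R = compose_grood_suntay(*angles_deg)
    plane = geometry.tibial_plane
    med = geometry.medial_points @ R.T
    lat = geometry.lateral_points @ R.T
    min_n = min((med @ plane.normal).min(), (lat @ plane.normal).min())
    t_vert = _PLANE_CLEARANCE_MM - (min_n - plane.point @ plane.normal)
    dist = med @ plane.normal + t_vert - plane.point @ plane.normal
    sel = np.argsort(dist, kind="stable")[:n_nearest]
    w = 1.0 / (np.abs(dist[sel]) + eps_mm)
    w /= w.sum()
    ap_rot = float(w @ (med[sel] @ plane.ap_axis))
    t = (
        (medial_ap_target - ap_rot + plane.point @ plane.ap_axis) * plane.ap_axis
        + t_vert * plane.normal
    )
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = t
    return T


def generate_kinematics(
    spec: CohortSpec,
    event: InstabilityEventSpec | None = None,
    subject_noise: float = 1.0,
    cycle_noise: float = 1.0,
) -> list[list[TrialKinematics]]:
    """Generate pose series + condyle geometry for every subject and cycle.

    ``subject_noise`` / ``cycle_noise`` scale the between-subject and
    cycle-to-cycle perturbations (0 gives the exact group template). When
    ``event`` is given, its A-P excursion is superposed on every trial:
    directly on the prescribed medial track for 'both'/'medial', and as the
    equivalent internal-rotation increment (excursion divided by the
    intercondylar separation) when only one condyle is affected, since a
    rigid transform cannot move one condyle without the other except by
    rotating about the vertical axis.
    """
    geometry = _default_geometry()
    subjects = []
    for s in range(spec.n_subjects):
        params = _subject_kinematic_params(spec, s, subject_noise)
        cycles = []
        for c in range(spec.cycles_per_subject):
            timing = _trial_timing(spec, s, c)
            rng_c = _rng(spec.seed, _S_KIN_CYC, s, c)
            jitter = {
                name: 1.0 + cycle_noise * 0.05 * rng_c.standard_normal()
                for name in ("flexion", "abduction", "internal", "medial_ap")
            }
            pct = 100.0 * np.arange(timing.n_frames) / (timing.n_frames - 1)
            curves = {}
            for name in ("flexion", "abduction", "internal"):
                st, sw = params.angle_rom[name]
                curves[name] = _rom_curve(
                    pct, timing.toe_off_pct, params.angle_base[name],
                    st * jitter[name], sw * jitter[name], name,
                )
            ap_st, ap_sw = params.medial_ap_rom
            medial = _rom_curve(
                pct, timing.toe_off_pct, 0.0,
                ap_st * jitter["medial_ap"], ap_sw * jitter["medial_ap"],
                "medial_ap",
            )
            if event is not None:
                exc = _event_excursion(pct, event)
                if event.affected_condyles in ("medial", "both"):
                    medial = medial + exc
                if event.affected_condyles != "both":
                    # Single-condyle excursions are realized through the
                    # vertical-axis rotation; its A-P lever arm is the
                    # intercondylar separation shortened by the flexion and
                    # internal-rotation cosines (those rotations are applied
                    # after/before it in the decomposition order).
                    lever = (
                        _CONDYLE_SEPARATION_MM
                        * np.cos(np.deg2rad(curves["flexion"]))
                        * np.cos(np.deg2rad(curves["internal"]))
                    )
                    sign = -1.0 if event.affected_condyles == "medial" else 1.0
                    curves["internal"] = curves["internal"] + sign * np.rad2deg(exc / lever)
            frames = np.empty((timing.n_frames, 4, 4))
            lateral = np.empty(timing.n_frames)
            for i in range(timing.n_frames):
                frames[i] = _build_pose(
                    (curves["flexion"][i], curves["abduction"][i], curves["internal"][i]),
                    medial[i],
                    geometry,
                )
                lateral[i] = condylar_ap(frames[i], geometry)[1]
            poses = PoseSeries(frames=frames, events=timing.events, rate=POSE_RATE)
            truth = {
                "pct": pct,
                "flexion": curves["flexion"],
                "abduction": curves["abduction"],
                "internal": curves["internal"],
                "medial_ap": medial,
                "lateral_ap": lateral,
                "toe_off_pct": timing.toe_off_pct,
            }
            cycles.append(
                TrialKinematics(poses=poses, geometry=geometry, truth=truth, subject=s, cycle=c)
            )
        subjects.append(cycles)
    return subjects


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------

@dataclass
class TrialEMG:
    """One generated EMG cycle: raw signals plus the planted envelope truth."""

    raw: RawEMG
    time_s: np.ndarray
    envelope_200: np.ndarray       # planted (8, 200) envelope for this cycle
    modules_subject: np.ndarray    # planted subject-level modules (8, k)
    subject: int
    cycle: int


def _subject_modules(spec: CohortSpec, subject: int, truth: GroundTruthSynergies,
                     module_jitter_sd: float) -> np.ndarray:
    rng = _rng(spec.seed, _S_EMG_SUBJ, subject)
    jit = np.clip(1.0 + module_jitter_sd * rng.standard_normal(truth.modules.shape), 0.0, None)
    W = truth.modules * jit
    col_max = W.max(axis=0)
    return W / np.where(col_max > 0, col_max, 1.0)


def generate_emg(
    spec: CohortSpec,
    truth: GroundTruthSynergies,
    noise_pct: float = 0.05,
    module_jitter_sd: float = 0.10,
    amp_jitter_sd: float = 0.05,
    noise_floor: float = 1e-3,
    rate: float = EMG_RATE,
) -> list[list[TrialEMG]]:
    """Raw 8-channel EMG per trial from planted synergies.

    Envelope E = W_subject @ H mapped onto the trial's real time axis
    (stance columns -> stance interval, swing columns -> swing interval);
    raw signal = E x zero-mean band-limited (50-450 Hz) unit-RMS carrier
    plus additive white noise with SD ``noise_pct`` x the envelope maximum
    (plus a tiny absolute floor). The planted per-cycle envelope and
    subject-level modules are stored alongside.
    """
    if truth.modules.min() < 0 or truth.patterns.min() < 0:
        raise ValueError("ground-truth synergies must be non-negative")
    sos = signal.butter(4, [50.0, 450.0], btype="bandpass", fs=rate, output="sos")
    subjects = []
    for s in range(spec.n_subjects):
        W = _subject_modules(spec, s, truth, module_jitter_sd)
        cycles = []
        for c in range(spec.cycles_per_subject):
            timing = _trial_timing(spec, s, c)
            rng = _rng(spec.seed, _S_EMG_CYC, s, c)
            amp = np.clip(1.0 + amp_jitter_sd * rng.standard_normal(truth.k), 0.0, None)
            env200 = W @ (truth.patterns * amp[:, None])
            n = int(round(timing.duration_s * rate)) + 1
            t = np.arange(n) / rate
            col_times = np.concatenate(
                [
                    np.linspace(0.0, timing.toe_off_s, N_POINTS // 2),
                    np.linspace(timing.toe_off_s, timing.duration_s, N_POINTS // 2),
                ]
            )
            env_t = np.vstack([np.interp(t, col_times, row) for row in env200])
            carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
            rms = np.sqrt(np.mean(carrier**2))
            carrier = carrier / (rms if rms > 0 else 1.0)
            noise_sd = noise_pct * env200.max() + noise_floor
            raw = env_t * carrier + noise_sd * rng.standard_normal((len(MUSCLES), n))
            hs1 = 0
            to = int(np.clip(round(timing.toe_off_s * rate), 1, n - 2))
            raw_emg = RawEMG(signals=raw, rate=rate, events=(hs1, to, n - 1))
            cycles.append(
                TrialEMG(
                    raw=raw_emg,
                    time_s=t,
                    envelope_200=env200,
                    modules_subject=W,
                    subject=s,
                    cycle=c,
                )
            )
        subjects.append(cycles)
    return subjects


# ---------------------------------------------------------------------------
# ground-reaction force synthesis
# ---------------------------------------------------------------------------

@dataclass
class TrialForce:
    """Vertical GRF for one cycle with the noise-free heel-strike sample stored."""

    time_s: np.ndarray
    force_n: np.ndarray
    rate: float
    heelstrike_index: int
    subject: int
    cycle: int


def generate_force(
    spec: CohortSpec,
    noise_n: float = 0.0,
    lead_in_s: float = 0.15,
    rate: float = FORCE_RATE,
) -> list[list[TrialForce]]:
    """Double-hump stance vertical force, zero in swing, scaled by body weight.

    The trace starts ``lead_in_s`` before heel-strike (zeros) and the stored
    heel-strike index is the first sample of the noise-free profile at or
    above 25 N, so threshold detection reproduces it exactly without noise
    and within about a millisecond under sensor noise.
    """
    subjects = []
    for s in range(spec.n_subjects):
        rng_s = _rng(spec.seed, _S_FORCE_SUBJ, s)
        bw = max(rng_s.normal(750.0, 100.0), 400.0)
        cycles = []
        for c in range(spec.cycles_per_subject):
            timing = _trial_timing(spec, s, c)
            rng = _rng(spec.seed, _S_FORCE_CYC, s, c)
            n = int(round((lead_in_s + timing.duration_s) * rate)) + 1
            t = np.arange(n) / rate - lead_in_s
            u = t / timing.toe_off_s
            stance = (t >= 0) & (u <= 1.0)
            profile = np.zeros(n)
            us = u[stance]
            profile[stance] = bw * np.clip(
                np.sin(np.pi * us) + 0.3 * np.sin(3 * np.pi * us), 0.0, None
            )
            above = np.nonzero(profile >= 25.0)[0]
            if len(above) == 0:
                raise RuntimeError("generated force never reaches the 25 N threshold")
            hs_idx = int(above[0])
            force = profile
            if noise_n > 0:
                force = profile + noise_n * rng.standard_normal(n)
            cycles.append(
                TrialForce(
                    time_s=t, force_n=force, rate=rate,
                    heelstrike_index=hs_idx, subject=s, cycle=c,
                )
            )
        subjects.append(cycles)
    return subjects


# ---------------------------------------------------------------------------
# planted classification fixtures
# ---------------------------------------------------------------------------

def planted_synergy_sets(
    n_subjects: int,
    truth: GroundTruthSynergies,
    classifiable_fraction: float = 1.0,
    seed: int = 0,
    jitter_sd: float = 0.05,
) -> dict[str, SynergySet]:
    """Per-subject synergy sets with a planted classifiable fraction.

    Every subject receives jittered copies of the planted synergies. To
    plant unclassifiable synergies, slots are replaced round-robin by a
    near-duplicate of another synergy of the same subject, which forces a
    within-cluster collision during classification: the expected
    classifiable ratio is 1 - n_replaced / (n_subjects * k).
    """
    if not 0.0 < classifiable_fraction <= 1.0:
        raise ValueError("classifiable_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    k = truth.k
    total = n_subjects * k
    n_bad = int(round((1.0 - classifiable_fraction) * total))
    bad_slots = {(i % n_subjects, 1 + (i // n_subjects) % (k - 1)) for i in range(n_bad)}
    if len(bad_slots) < n_bad:
        raise ValueError("classifiable_fraction too low to plant distinct collisions")
    out: dict[str, SynergySet] = {}
    for s in range(n_subjects):
        W = np.clip(truth.modules * (1.0 + jitter_sd * rng.standard_normal(truth.modules.shape)), 0.0, None)
        H = np.clip(truth.patterns * (1.0 + jitter_sd * rng.standard_normal(truth.patterns.shape)), 0.0, None)
        for slot in range(k):
            if (s, slot) in bad_slots:
                src = (slot + 1) % k
                W[:, slot] = np.clip(W[:, src] * (1.0 + 0.02 * rng.standard_normal(len(MUSCLES))), 0.0, None)
                H[slot] = np.clip(H[src] * (1.0 + 0.02 * rng.standard_normal(N_POINTS)), 0.0, None)
        col_max = W.max(axis=0)
        W = W / np.where(col_max > 0, col_max, 1.0)
        out[f"S{s:02d}"] = SynergySet(modules=W, patterns=H, r_squared=1.0, k=k)
    return out
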