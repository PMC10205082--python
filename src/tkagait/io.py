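"""File formats, dataset manifests and run configuration.

All on-disk formats are plain text and diffable: TSV for pose series, CSV
for point clouds / EMG / force, JSON for events, planes, ground truth and
manifests (PLY point clouds are also read when trimesh is available).
Floats are written with 17 significant digits so write -> read round-trips
are lossless well below 1e-9.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emg import MUSCLES
from .kinematics import CondyleGeometry, GaitEvents, PoseSeries, TibialPlane

__all__ = [
    "DataError",
    "RunConfig",
    "write_pose_tsv",
    "read_pose_tsv",
    "write_events_json",
    "read_events_json",
    "write_condyle_csv",
    "read_condyle_points",
    "write_plane_json",
    "read_plane_json",
    "write_emg_csv",
    "read_emg_csv",
    "write_force_csv",
    "read_force_csv",
    "write_json",
    "read_json",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FMT = "%.17g"
GENERATOR_VERSION = "tkagait-0.1.0"


class DataError(ValueError):
    """Unreadable, inconsistent or malformed input data."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters; defaults equal the published processing values.

    Printed parameters: 50 Hz high-pass / 20 Hz low-pass 4th-order filters,
    101-point kinematic and 200-point EMG normalization, 25 N heel-strike
    threshold. Unprinted parameters (NMF restarts/tolerance, R^2 rank
    threshold, k-means restarts, permutation count, Bonferroni family sizes)
    are package choices, configurable here and recorded in every results
    directory.
    """

    # cohort simulation
    n_stable: int = 10
    n_unstable: int = 8
    cycles_per_subject: int = 4
    activities: tuple = ("level", "downhill", "stair")
    # EMG chain
    highpass_hz: float = 50.0
    lowpass_hz: float = 20.0
    filter_order: int = 4
    zero_phase: bool = True
    emg_noise_pct: float = 0.05
    # normalization lengths
    n_points_kinematics: int = 101
    n_points_emg: int = 200
    # planted group effect: width multiplier on the flexor-dominated
    # activation pattern of the unstable group (1.0 = no effect)
    unstable_flexor_width_scale: float = 1.0
    # events
    force_threshold_n: float = 25.0
    # NMF / rank selection
    nmf_restarts: int = 10
    nmf_max_iter: int = 1000
    nmf_tol: float = 1e-6
    r2_threshold: float = 0.90
    # classification
    kmeans_restarts: int = 50
    # statistics
    alpha: float = 0.05
    n_perm: int = 1000
    # Bonferroni family sizes: kinematic RoM comparisons form one family per
    # activity; FWHM and CoA are corrected within metric x activity (family =
    # number of classified synergies). None -> derived from the data.
    kinematic_family_size: int | None = None
    timing_family_size: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**d)
        if isinstance(cfg.activities, list):
            cfg.activities = tuple(cfg.activities)
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise DataError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["activities"] = list(self.activities)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# pose series
# ---------------------------------------------------------------------------

_POSE_COLUMNS = ["frame"] + [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)] + ["tx", "ty", "tz"]


def write_pose_tsv(path: str | Path, series: PoseSeries) -> None:
    rows = []
    for i, T in enumerate(series.frames):
        rows.append([i, *T[:3, :3].ravel(), *T[:3, 3]])
    df = pd.DataFrame(rows, columns=_POSE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_pose_tsv(path: str | Path, events: GaitEvents, rate: float = 30.0) -> PoseSeries:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surfacing as a data error
        raise DataError(f"cannot parse pose TSV {path}: {exc}") from exc
    missing = [c for c in _POSE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"pose TSV {path} missing column(s) {missing}")
    n = len(df)
    frames = np.tile(np.eye(4), (n, 1, 1))
    frames[:, :3, :3] = df[_POSE_COLUMNS[1:10]].to_numpy().reshape(n, 3, 3)
    frames[:, :3, 3] = df[["tx", "ty", "tz"]].to_numpy()
    return PoseSeries(frames=frames, events=events, rate=rate)


def write_events_json(path: str | Path, events: GaitEvents) -> None:
    write_json(
        path,
        {
            "heel_strike_1": events.heel_strike_1,
            "toe_off": events.toe_off,
            "heel_strike_2": events.heel_strike_2,
        },
    )


def read_events_json(path: str | Path) -> GaitEvents:
    d = read_json(path)
    try:
        return GaitEvents(int(d["heel_strike_1"]), int(d["toe_off"]), int(d["heel_strike_2"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise DataError(f"bad events file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def write_condyle_csv(path: str | Path, points: np.ndarray) -> None:
    pd.DataFrame(np.asarray(points, float), columns=["x", "y", "z"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_condyle_points(path: str | Path) -> np.ndarray:
    """Read a condyle point cloud from CSV (x,y,z header) or PLY."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        try:
            import trimesh
        except ImportError as exc:
            raise DataError("reading PLY point clouds requires the 'trimesh' extra") from exc
        loaded = trimesh.load(str(path))
        return np.asarray(loaded.vertices, dtype=float)
    try:
        df = pd.read_csv(path)
        return df[["x", "y", "z"]].to_numpy(dtype=float)
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"cannot parse condyle CSV {path}: {exc}") from exc


def write_plane_json(path: str | Path, plane: TibialPlane) -> None:
    write_json(
        path,
        {
            "point": plane.point.tolist(),
            "normal": plane.normal.tolist(),
            "ap_axis": plane.ap_axis.tolist(),
        },
    )


def read_plane_json(path: str | Path) -> TibialPlane:
    d = read_json(path)
    try:
        return TibialPlane(
            point=np.asarray(d["point"], float),
            normal=np.asarray(d["normal"], float),
            ap_axis=np.asarray(d["ap_axis"], float),
        )
    except (KeyError, ValueError) as exc:
        raise DataError(f"bad plane file {path}: {exc}") from exc


def read_geometry(medial_path: str | Path, lateral_path: str | Path,
                  plane_path: str | Path) -> CondyleGeometry:
    return CondyleGeometry(
        medial_points=read_condyle_points(medial_path),
        lateral_points=read_condyle_points(lateral_path),
        tibial_plane=read_plane_json(plane_path),
    )


# ---------------------------------------------------------------------------
# EMG / force traces
# ---------------------------------------------------------------------------

def write_emg_csv(path: str | Path, time_s: np.ndarray, signals: np.ndarray) -> None:
    df = pd.DataFrame({"time": np.asarray(time_s, float)})
    for i, name in enumerate(MUSCLES):
        df[name] = np.asarray(signals, float)[i]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_emg_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path)
        time = df["time"].to_numpy(dtype=float)
        signals = df[list(MUSCLES)].to_numpy(dtype=float).T
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"cannot parse EMG CSV {path}: {exc}") from exc
    return time, signals


def write_force_csv(path: str | Path, time_s: np.ndarray, force_n: np.ndarray) -> None:
    pd.DataFrame({"time": np.asarray(time_s, float), "fz": np.asarray(force_n, float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_force_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path)
        return df["time"].to_numpy(dtype=float), df["fz"].to_numpy(dtype=float)
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"cannot parse force CSV {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# JSON helpers, manifest
# ---------------------------------------------------------------------------

class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path):
    try:
        return json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read JSON {path}: {exc}") from exc


@dataclass
class TrialPaths:
    cycle: int
    poses: str
    events: str
    medial_condyle: str
    lateral_condyle: str
    plane: str
    emg: str
    force: str


@dataclass
class SubjectEntry:
    subject_id: str
    group: str
    activity: str
    trials: list[TrialPaths] = field(default_factory=list)


@dataclass
class DatasetManifest:
    """Ties every trial file to its subject, group, activity and seed."""

    root: str
    master_seed: int
    generator_version: str
    subjects: list[SubjectEntry] = field(default_factory=list)

    def resolve(self, rel: str) -> Path:
        return Path(self.root) / rel

    def validate(self) -> None:
        """Check that every referenced file exists."""
        missing = []
        for sub in self.subjects:
            for tr in sub.trials:
                for f in dataclasses.fields(TrialPaths):
                    if f.name == "cycle":
                        continue
                    p = self.resolve(getattr(tr, f.name))
                    if not p.exists():
                        missing.append(str(p))
        if missing:
            raise DataError(f"manifest references missing file(s): {missing[:5]} ...")


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    d = dataclasses.asdict(manifest)
    d.pop("root")
    write_json(path, d)


def read_manifest(path: str | Path) -> DatasetManifest:
    d = read_json(path)
    try:
        subjects = [
            SubjectEntry(
                subject_id=s["subject_id"],
                group=s["group"],
                activity=s["activity"],
                trials=[TrialPaths(**t) for t in s["trials"]],
            )
            for s in d["subjects"]
        ]
        m = DatasetManifest(
            root=str(Path(path).parent),
            master_seed=int(d["master_seed"]),
            generator_version=str(d["generator_version"]),
            subjects=subjects,
        )
    except (KeyError, TypeError) as exc:
        raise DataError(f"bad manifest {path}: {exc}") from exc
    if not m.subjects:
        raise DataError(f"manifest {path} lists no subjects")
    return m


def remove_partial(path: str | Path) -> None:
    """Best-effort cleanup of a partially written dataset directory."""
    shutil.rmtree(path, ignore_errors=True)
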