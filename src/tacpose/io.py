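"""Configuration, dataset readers/writers and timestamp pairing.

On-disk layout for a simulated recording (all plain text except the
optional HDF5 container):

* ``frames/frame_NNNNNN.csv`` — one pressure grid per file, comma-separated
* ``frames_index.csv`` — columns (t, file), frame timestamps in seconds
* ``keypoints.csv`` — columns (t, joint_id, x_mm, y_mm, z_mm)
* ``split.json`` — train/test/val frame indices
* or a single ``dataset.h5`` holding clean/noisy stacks, poses, labels

Frames and poses are joined on timestamp; the default policy is exact
match (the simulator guarantees it), with an optional nearest-neighbour
mode within a tolerance (default one 60 Hz frame period) for real
recordings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .cda import CDAConfig
from .denoiser import Stage1TrainConfig, UNetConfig
from .diffusion import NoiseSchedule, make_schedule
from .mask import MaskParams
from .posenet import PoseNetConfig, Stage2TrainConfig
from .synthetic import (
    DEFAULT_HOLDOUT,
    SUPPORTED_ACTIVITIES,
    BodyModel,
    SceneConfig,
    SyntheticScene,
)

FRAME_PERIOD_S = 1.0 / 60.0  # mat frame period

ABLATION_FLAGS = ("PSFD", "RMFD", "CA", "PP")


@dataclass
class ScheduleConfig:
    D: int = 50
    alpha_start: float = 0.999
    alpha_end: float = 0.95
    mode: str = "variance_preserving"

    def build(self) -> NoiseSchedule:
        return make_schedule(self.D, self.alpha_start, self.alpha_end, self.mode)


@dataclass
class DataConfig:
    n_frames: int = 200
    activities: tuple[str, ...] = SUPPORTED_ACTIVITIES
    holdout: tuple[str, ...] = DEFAULT_HOLDOUT
    body_scale: float = 1.0
    split: tuple[float, float] = (0.8, 0.2)

    def build_body(self) -> BodyModel:
        return BodyModel().scaled(self.body_scale)


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    mask: MaskParams = field(default_factory=MaskParams)
    unet: UNetConfig = field(default_factory=UNetConfig)
    posenet: PoseNetConfig = field(default_factory=PoseNetConfig)
    train1: Stage1TrainConfig = field(default_factory=Stage1TrainConfig)
    train2: Stage2TrainConfig = field(default_factory=Stage2TrainConfig)
    data: DataConfig = field(default_factory=DataConfig)
    ablation: tuple[str, ...] = ("PSFD", "RMFD", "CA", "PP")
    seed: int = 0

    def __post_init__(self):
        validate_ablation(self.ablation)

    @property
    def use_mask_stream(self) -> bool:
        return "RMFD" in self.ablation

    @property
    def use_pp(self) -> bool:
        return "PP" in self.ablation


def validate_ablation(flags: Sequence[str]) -> tuple[str, ...]:
    flags = tuple(flags)
    unknown = [f for f in flags if f not in ABLATION_FLAGS]
    if unknown:
        raise ValueError(f"ablation: unknown flags {unknown}; allowed {ABLATION_FLAGS}")
    if "PSFD" not in flags:
        raise ValueError("ablation: PSFD is the backbone and must always be present")
    if ("RMFD" in flags) != ("CA" in flags):
        raise ValueError("ablation: RMFD and CA come as a pair (the mask stream feeds CA)")
    if "PP" in flags and "CA" not in flags:
        raise ValueError("ablation: PP feeds CA, so PP requires CA")
    return flags


# -- dataclass (de)serialisation ----------------------------------------------
def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def _from_dict(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        target = _NESTED.get((cls, k))
        if target is not None and isinstance(v, dict):
            kwargs[k] = _from_dict(target, v, f"{path}.{k}")
        elif isinstance(v, list):
            kwargs[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"{path}: {e}") from e


_NESTED = {
    (RunConfig, "scene"): SceneConfig,
    (RunConfig, "schedule"): ScheduleConfig,
    (RunConfig, "mask"): MaskParams,
    (RunConfig, "unet"): UNetConfig,
    (RunConfig, "posenet"): PoseNetConfig,
    (RunConfig, "train1"): Stage1TrainConfig,
    (RunConfig, "train2"): Stage2TrainConfig,
    (RunConfig, "data"): DataConfig,
    (UNetConfig, "cda"): CDAConfig,
}


def config_from_dict(d: dict) -> RunConfig:
    return _from_dict(RunConfig, d, "config")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config; defaults fill missing keys,
    unknown keys are rejected with their field path."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the config contents (insensitive to key order)."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- frame / keypoint files ----------------------------------------------------
def write_frames(out_dir, frames: Sequence[np.ndarray], timestamps: Sequence[float]) -> None:
    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (f, t) in enumerate(zip(frames, timestamps)):
        name = f"frames/frame_{i:06d}.csv"
        np.savetxt(out_dir / name, np.asarray(f), delimiter=",", fmt="%.10g")
        rows.append({"t": t, "file": name})
    pd.DataFrame(rows).to_csv(out_dir / "frames_index.csv", index=False, float_format="%.17g")


def read_frames(in_dir) -> tuple[list[np.ndarray], np.ndarray]:
    """Read a frames directory -> (frames, timestamps)."""
    in_dir = Path(in_dir)
    idx_path = in_dir / "frames_index.csv"
    if not idx_path.exists():
        raise FileNotFoundError(f"missing frames_index.csv in {in_dir}")
    idx = pd.read_csv(idx_path, float_precision="round_trip")
    missing = {"t", "file"} - set(idx.columns)
    if missing:
        raise ValueError(f"frames_index.csv missing columns: {sorted(missing)}")
    if idx["t"].duplicated().any():
        raise ValueError("duplicate timestamps in frames_index.csv")
    frames = [
        np.atleast_2d(np.loadtxt(in_dir / row.file, delimiter=","))
        for row in idx.itertuples()
    ]
    return frames, idx["t"].to_numpy(dtype=float)


def write_keypoints(path, poses: np.ndarray, timestamps: Sequence[float]) -> None:
    poses = np.asarray(poses, dtype=float)
    n, J, _ = poses.shape
    rec = []
    for i in range(n):
        for j in range(J):
            rec.append({
                "t": timestamps[i], "joint_id": j,
                "x_mm": poses[i, j, 0], "y_mm": poses[i, j, 1], "z_mm": poses[i, j, 2],
            })
    pd.DataFrame(rec).to_csv(path, index=False, float_format="%.17g")


def read_keypoints(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a keypoint CSV -> (poses [N, J, 3] mm, timestamps [N])."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"t", "joint_id", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"keypoints file missing columns: {sorted(missing)}")
    ts = np.array(sorted(df["t"].unique()), dtype=float)
    J = df["joint_id"].nunique()
    poses = np.zeros((ts.size, J, 3))
    for i, t in enumerate(ts):
        sub = df[df["t"] == t].sort_values("joint_id")
        if len(sub) != J:
            raise ValueError(f"timestamp {t}: expected {J} joints, found {len(sub)}")
        poses[i] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
    return poses, ts


def pair_by_timestamp(
    frame_ts: np.ndarray,
    pose_ts: np.ndarray,
    tol: float | None = None,
) -> list[tuple[int, int]]:
    """Match frame and pose timestamps.

    Exact matching by default; with ``tol`` set, each frame takes the
    nearest pose within the tolerance (``FRAME_PERIOD_S`` suits the mat's
    60 Hz stream).  Unmatched frames are reported with a warning.
    """
    frame_ts = np.asarray(frame_ts, dtype=float)
    pose_ts = np.asarray(pose_ts, dtype=float)
    for name, ts in (("frame", frame_ts), ("pose", pose_ts)):
        if np.unique(ts).size != ts.size:
            raise ValueError(f"duplicate {name} timestamps")
    pairs: list[tuple[int, int]] = []
    unmatched = 0
    lookup = {t: i for i, t in enumerate(pose_ts)}
    for i, t in enumerate(frame_ts):
        if tol is None:
            j = lookup.get(t)
            if j is None:
                unmatched += 1
                continue
        else:
            k = int(np.argmin(np.abs(pose_ts - t)))
            if abs(pose_ts[k] - t) > tol:
                unmatched += 1
                continue
            j = k
        pairs.append((i, j))
    if unmatched:
        warnings.warn(f"{unmatched} frame(s) had no matching pose", stacklevel=2)
    return pairs


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/1 CSV grid or an 8-bit PNG (0/255)."""
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix == ".csv":
        np.savetxt(path, mask.astype(int), delimiter=",", fmt="%d")
    elif path.suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, (mask > 0).astype(np.uint8) * 255)
    else:
        raise ValueError("mask format must be .csv or .png")


# -- dataset container ---------------------------------------------------------
def write_dataset(out_dir, scenes: Sequence[SyntheticScene],
                  split: dict[str, list[int]]) -> None:
    """Write the full text layout: frame CSVs (noisy and clean), keypoints,
    split manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts = [s.t for s in scenes]
    write_frames(out_dir, [s.noisy for s in scenes], ts)
    clean_dir = out_dir / "clean"
    clean_dir.mkdir(exist_ok=True)
    write_frames(clean_dir, [s.clean for s in scenes], ts)
    write_keypoints(out_dir / "keypoints.csv", np.stack([s.pose for s in scenes]), ts)
    manifest = {"split": split, "activities": [s.activity for s in scenes]}
    (out_dir / "split.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(in_dir) -> tuple[list[SyntheticScene], dict[str, list[int]]]:
    in_dir = Path(in_dir)
    noisy, ts = read_frames(in_dir)
    clean, _ = read_frames(in_dir / "clean")
    poses, pts = read_keypoints(in_dir / "keypoints.csv")
    pairs = pair_by_timestamp(ts, pts)
    manifest = json.loads((in_dir / "split.json").read_text())
    acts = manifest["activities"]
    scenes = [
        SyntheticScene(clean[i], noisy[i], poses[j], acts[i], float(ts[i]))
        for i, j in pairs
    ]
    return scenes, manifest["split"]


def write_dataset_h5(path, scenes: Sequence[SyntheticScene],
                     split: dict[str, list[int]]) -> None:
    """Single-file HDF5 container (clean/noisy stacks, poses, labels, split)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("clean", data=np.stack([s.clean for s in scenes]))
        f.create_dataset("noisy", data=np.stack([s.noisy for s in scenes]))
        f.create_dataset("poses", data=np.stack([s.pose for s in scenes]))
        f.create_dataset("t", data=np.array([s.t for s in scenes]))
        f.create_dataset(
            "activity",
            data=np.array([s.activity for s in scenes], dtype=h5py.string_dtype()),
        )
        f.attrs["split"] = json.dumps(split)


def read_dataset_h5(path) -> tuple[list[SyntheticScene], dict[str, list[int]]]:
    with h5py.File(path, "r") as f:
        clean = f["clean"][:]
        noisy = f["noisy"][:]
        poses = f["poses"][:]
        ts = f["t"][:]
        acts = [a.decode() for a in f["activity"][:]]
        split = json.loads(f.attrs["split"])
    scenes = [
        SyntheticScene(clean[i], noisy[i], poses[i], acts[i], float(ts[i]))
        for i in range(len(acts))
    ]
    return scenes, split
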