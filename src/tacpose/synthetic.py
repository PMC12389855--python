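"""Synthetic tactile scenes: parameterised poses, rendered pressure maps,
sensor corruption and dataset assembly.

The generator emulates a capacitive pressure mat observing a person
exercising on it: a 12-point body model is posed for a named activity, the
joints in ground contact deposit Gaussian pressure blobs on the mat plane,
and the frame is then corrupted by additive sensor noise plus sporadic
small spurious blobs.  Every draw is keyed on explicit seeds, so scenes are
bitwise reproducible.

Units and coordinates: pressure in kPa (sensor ceiling ``max_pressure``),
pose in millimetres, mat plane at z = 0, x along mat rows with the origin
at the top-left mat corner, frames row-major with row 0 at the top.

Activity layouts are expressed in fractions of the body "span" (torso plus
leg length), so the same repertoire renders sensibly on a full-size mat or
on the desk-scale single-person patch used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._seeding import rng as _rng, spawn_seed

JOINT_NAMES = (
    "head", "pelvis",
    "l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_hand", "r_hand",
    "l_knee", "r_knee", "l_foot", "r_foot",
)
_J = {n: i for i, n in enumerate(JOINT_NAMES)}

#: activity -> joints on the mat (z = 0)
ACTIVITY_CONTACTS = {
    "standing": ("l_foot", "r_foot"),
    "squat": ("l_foot", "r_foot"),
    "plank": ("l_hand", "r_hand", "l_foot", "r_foot"),
    "pushup": ("l_hand", "r_hand", "l_foot", "r_foot"),
    "lunge": ("l_foot", "r_foot", "r_knee"),
    "sit": ("pelvis", "l_foot", "r_foot"),
    "wide_stand": ("l_foot", "r_foot"),
    "bend": ("l_foot", "r_foot"),
}

SUPPORTED_ACTIVITIES = tuple(ACTIVITY_CONTACTS)

TACTEL_PITCH_MM = 40.0  # capacitive tactel lattice pitch


@dataclass
class BodyModel:
    """A stick-figure body: joint count, segment lengths (mm) and the joints
    allowed to touch the mat."""

    n_joints: int = 12
    #: (neck, torso, upper arm, forearm, thigh, shank) in mm
    segment_lengths: np.ndarray = field(
        default_factory=lambda: np.array([250.0, 500.0, 300.0, 280.0, 450.0, 430.0])
    )
    contact_points: tuple[int, ...] = tuple(
        _J[n] for n in ("pelvis", "l_hand", "r_hand", "l_knee", "r_knee", "l_foot", "r_foot")
    )
    weight_kg: float = 70.0

    def __post_init__(self):
        self.segment_lengths = np.asarray(self.segment_lengths, dtype=float)
        if self.n_joints < 2:
            raise ValueError("n_joints must be >= 2")
        if np.any(self.segment_lengths <= 0):
            raise ValueError("segment_lengths must be positive")

    @property
    def span(self) -> float:
        """Torso + leg length: the characteristic body scale (mm)."""
        neck, torso, uarm, farm, thigh, shank = self.segment_lengths
        return torso + thigh + shank

    def scaled(self, factor: float) -> "BodyModel":
        return replace(self, segment_lengths=self.segment_lengths * factor)


@dataclass
class SceneConfig:
    """Sensor geometry and corruption parameters."""

    grid_h: int = 45
    grid_w: int = 16
    frame_h: int = 496
    frame_w: int = 298
    max_pressure: float = 15.0  # kPa ceiling
    noise_sigma: float = 1.0    # kPa, additive Gaussian
    spurious_blob_rate: float = 3.0  # Poisson mean per frame
    blob_sigma_mm: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.frame_h < self.grid_h or self.frame_w < self.grid_w:
            raise ValueError("frame dims must be >= tactel grid dims")
        if self.max_pressure <= 0:
            raise ValueError("max_pressure must be positive")
        if self.noise_sigma < 0 or self.spurious_blob_rate < 0:
            raise ValueError("noise parameters must be nonnegative")

    @property
    def mat_mm(self) -> tuple[float, float]:
        return self.grid_h * TACTEL_PITCH_MM, self.grid_w * TACTEL_PITCH_MM


def desk_config(**kw) -> SceneConfig:
    """A desk-scale sensor: a two-module 0.64 m x 0.32 m patch rasterised to
    64 x 40 pixels, matched by a 0.45-scale body (see :func:`desk_body`)."""
    args = dict(grid_h=16, grid_w=8, frame_h=64, frame_w=40, blob_sigma_mm=75.0)
    args.update(kw)
    return SceneConfig(**args)


def desk_body() -> BodyModel:
    return BodyModel().scaled(0.45)


@dataclass
class SyntheticScene:
    clean: np.ndarray
    noisy: np.ndarray
    pose: np.ndarray  # [J, 3] mm
    activity: str
    t: float  # seconds


def _unknown_activity(activity: str) -> ValueError:
    return ValueError(
        f"unknown activity {activity!r}; supported: {', '.join(SUPPORTED_ACTIVITIES)}"
    )


def sample_pose(
    body: BodyModel,
    activity: str,
    rng_seed: int,
    center_mm: tuple[float, float] = (900.0, 320.0),
) -> np.ndarray:
    """Sample a J x 3 pose (mm) for ``activity``; contact joints land on z=0.

    Deterministic given ``rng_seed``.  ``center_mm`` places the body on the
    mat (defaults to the centre of the full-size 45 x 16 mat).
    """
    if activity not in ACTIVITY_CONTACTS:
        raise _unknown_activity(activity)
    g = _rng(rng_seed, "pose", activity)
    neck, torso, uarm, farm, thigh, shank = body.segment_lengths
    leg = thigh + shank
    S = body.span

    cx = center_mm[0] + g.uniform(-0.05, 0.05) * S
    cy = center_mm[1] + g.uniform(-0.05, 0.05) * S

    p = np.zeros((12, 3))

    def put(name, x, y, z):
        p[_J[name]] = (x, y, z)

    fy = 0.06 * S   # lateral half-offset of a foot pair
    sy = 0.08 * S   # lateral half-offset of shoulders/hands
    if activity in ("standing", "wide_stand", "bend", "squat"):
        half = (0.34 if activity == "wide_stand" else 0.30) * S
        half *= 1.0 + g.uniform(-0.08, 0.08)
        crouch = {"standing": 1.0, "wide_stand": 0.95, "bend": 0.9, "squat": 0.45}[activity]
        crouch *= 1.0 + g.uniform(-0.08, 0.08)  # continuous sway / squat depth
        pelvis_z = leg * crouch
        put("l_foot", cx - half, cy - fy, 0)
        put("r_foot", cx + half, cy + fy, 0)
        put("l_knee", cx - half * 0.8, cy - fy, pelvis_z * 0.5)
        put("r_knee", cx + half * 0.8, cy + fy, pelvis_z * 0.5)
        put("pelvis", cx, cy, pelvis_z)
        lean = 0.5 if activity == "bend" else 1.0
        sh_z = pelvis_z + torso * lean
        sh_x = cx + torso * (1 - lean**2) ** 0.5
        put("l_shoulder", sh_x, cy - sy, sh_z)
        put("r_shoulder", sh_x, cy + sy, sh_z)
        put("l_elbow", sh_x, cy - sy * 1.3, sh_z - uarm)
        put("r_elbow", sh_x, cy + sy * 1.3, sh_z - uarm)
        put("l_hand", sh_x, cy - sy * 1.5, sh_z - uarm - farm * 0.9)
        put("r_hand", sh_x, cy + sy * 1.5, sh_z - uarm - farm * 0.9)
        put("head", sh_x, cy, sh_z + neck)
    elif activity in ("plank", "pushup"):
        d = 0.32 * S
        drop = 0.45 if activity == "pushup" else 0.6
        put("l_hand", cx + d, cy - sy, 0)
        put("r_hand", cx + d, cy + sy, 0)
        put("l_foot", cx - d, cy - fy, 0)
        put("r_foot", cx - d, cy + fy, 0)
        put("l_knee", cx - d * 0.5, cy - fy, shank * 0.25)
        put("r_knee", cx - d * 0.5, cy + fy, shank * 0.25)
        put("pelvis", cx, cy, uarm * drop + 0.1 * S)
        put("l_shoulder", cx + d, cy - sy, uarm * 2 * drop)
        put("r_shoulder", cx + d, cy + sy, uarm * 2 * drop)
        put("l_elbow", cx + d, cy - sy, uarm * drop)
        put("r_elbow", cx + d, cy + sy, uarm * drop)
        put("head", cx + d + neck * 0.8, cy, uarm * 2 * drop + 0.05 * S)
    elif activity == "lunge":
        put("l_foot", cx + 0.22 * S, cy - fy, 0)   # front foot
        put("r_foot", cx - 0.28 * S, cy + fy, 0)
        put("r_knee", cx - 0.12 * S, cy + fy, 0)   # back knee down
        put("l_knee", cx + 0.22 * S, cy - fy, shank)
        pelvis_z = thigh * 0.9
        put("pelvis", cx, cy, pelvis_z)
        sh_z = pelvis_z + torso
        put("l_shoulder", cx, cy - sy, sh_z)
        put("r_shoulder", cx, cy + sy, sh_z)
        put("l_elbow", cx, cy - sy * 1.3, sh_z - uarm)
        put("r_elbow", cx, cy + sy * 1.3, sh_z - uarm)
        put("l_hand", cx, cy - sy * 1.5, sh_z - uarm - farm * 0.9)
        put("r_hand", cx, cy + sy * 1.5, sh_z - uarm - farm * 0.9)
        put("head", cx, cy, sh_z + neck)
    elif activity == "sit":
        put("pelvis", cx - 0.15 * S, cy, 0)
        put("l_foot", cx + 0.30 * S, cy - fy, 0)
        put("r_foot", cx + 0.30 * S, cy + fy, 0)
        put("l_knee", cx + 0.18 * S, cy - fy, shank * 0.4)
        put("r_knee", cx + 0.18 * S, cy + fy, shank * 0.4)
        sh_z = torso
        put("l_shoulder", cx - 0.15 * S, cy - sy, sh_z)
        put("r_shoulder", cx - 0.15 * S, cy + sy, sh_z)
        put("l_elbow", cx - 0.05 * S, cy - sy, sh_z - uarm)
        put("r_elbow", cx - 0.05 * S, cy + sy, sh_z - uarm)
        put("l_hand", cx, cy - sy, sh_z - uarm - farm * 0.8)
        put("r_hand", cx, cy + sy, sh_z - uarm - farm * 0.8)
        put("head", cx - 0.15 * S, cy, sh_z + neck)

    # small per-joint jitter; contact joints jitter only in-plane
    contacts = [_J[n] for n in ACTIVITY_CONTACTS[activity]]
    jit = g.normal(0, 0.01 * S, size=(12, 3))
    p = p + jit
    p[contacts, 2] = 0.0

    if body.n_joints != 12:
        raise ValueError("the built-in activity repertoire defines 12 joints")
    return p


def contact_joints(pose: np.ndarray, tol_mm: float = 1.0) -> np.ndarray:
    """Indices of joints on the mat plane (|z| <= tol)."""
    return np.flatnonzero(np.abs(np.asarray(pose)[:, 2]) <= tol_mm)


def posture_spread(pose: np.ndarray, body: BodyModel) -> float:
    """Contact-spread factor for a pose: crouched or prone postures load a
    larger contact area at lower peak pressure than upright standing.

    Returns a multiplier in [1.0, 1.4] for the blob width, derived from the
    head height relative to the body span (an upright head sits at about
    1.18 span above the mat).
    """
    head_z = float(np.asarray(pose)[_J["head"], 2])
    upright = 1.18 * body.span
    drop = np.clip((upright - head_z) / upright, 0.0, 1.0)
    return float(np.clip(1.0 + 0.5 * drop, 1.0, 1.4))


def _pixel_centers(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    mx, my = cfg.mat_mm
    xs = (np.arange(cfg.frame_h) + 0.5) * (mx / cfg.frame_h)
    ys = (np.arange(cfg.frame_w) + 0.5) * (my / cfg.frame_w)
    return xs, ys


def render_pressure(pose: np.ndarray, cfg: SceneConfig,
                    weight_kg: float = 70.0, spread_scale: float = 1.0) -> np.ndarray:
    """Render the noise-free pressure frame for a pose.

    Each contact joint deposits an isotropic Gaussian blob (sigma
    ``cfg.blob_sigma_mm`` times ``spread_scale``) at its mat projection;
    blob amplitude scales linearly with ``weight_kg``, is shared across
    contacts and drops as 1/``spread_scale`` (a larger contact area carries
    lower peak pressure), then the frame is clipped to the sensor ceiling.
    Contacts outside the mat are simply truncated by the frame bounds.
    ``spread_scale`` is normally :func:`posture_spread` of the pose, which
    is how posture height leaves a signature in the frame.
    """
    pose = np.asarray(pose, dtype=float)
    if not np.all(np.isfinite(pose)):
        raise ValueError("pose must be finite")
    frame = np.zeros((cfg.frame_h, cfg.frame_w))
    idx = contact_joints(pose)
    if idx.size == 0:
        return frame
    xs, ys = _pixel_centers(cfg)
    sig2 = 2.0 * (cfg.blob_sigma_mm * spread_scale) ** 2
    amp = 12.0 * (weight_kg / 70.0) * (2.0 / idx.size) / spread_scale
    for j in idx:
        x, y = pose[j, 0], pose[j, 1]
        gx = np.exp(-((xs - x) ** 2) / sig2)
        gy = np.exp(-((ys - y) ** 2) / sig2)
        frame += amp * np.outer(gx, gy)
    return np.clip(frame, 0.0, cfg.max_pressure)


def corrupt(clean: np.ndarray, cfg: SceneConfig, rng_seed: int | None = None) -> np.ndarray:
    """Additive zero-mean Gaussian noise plus Poisson-count spurious blobs.

    Spurious blobs have 3x3 support — strictly smaller than the 5x5 opening
    kernel of the mask-refinement stage, so a morphological opening with
    that kernel removes them entirely.  Output clipped to [0, ceiling].
    Deterministic given the seed (defaults to ``cfg.seed``).
    """
    clean = np.asarray(clean, dtype=float)
    if np.any(clean < 0):
        raise ValueError("clean frame must be nonnegative")
    seed = cfg.seed if rng_seed is None else rng_seed
    if cfg.noise_sigma == 0 and cfg.spurious_blob_rate == 0:
        return clean.copy()
    g = _rng(seed, "corrupt")
    out = clean.copy()
    if cfg.noise_sigma > 0:
        out += g.normal(0.0, cfg.noise_sigma, size=clean.shape)
    n_spur = g.poisson(cfg.spurious_blob_rate)
    kern = np.array([[0.3, 0.6, 0.3], [0.6, 1.0, 0.6], [0.3, 0.6, 0.3]])
    H, W = clean.shape
    for _ in range(n_spur):
        r = int(g.integers(1, max(H - 1, 2)))
        c = int(g.integers(1, max(W - 1, 2)))
        a = g.uniform(1.0, 3.0)
        r0, r1 = max(r - 1, 0), min(r + 2, H)
        c0, c1 = max(c - 1, 0), min(c + 2, W)
        out[r0:r1, c0:c1] += a * kern[: r1 - r0, : c1 - c0]
    return np.clip(out, 0.0, cfg.max_pressure)


DEFAULT_HOLDOUT = ("sit", "squat")


def make_dataset(
    n_frames: int,
    cfg: SceneConfig,
    body: BodyModel | None = None,
    split: tuple[float, float] = (0.8, 0.2),
    activities: Sequence[str] = SUPPORTED_ACTIVITIES,
    holdout: Sequence[str] = DEFAULT_HOLDOUT,
) -> tuple[list[SyntheticScene], dict[str, list[int]]]:
    """Generate paired scenes and an activity-disjoint split.

    Frames cycle through ``activities`` at the mat's 60 Hz frame period and
    are paired with their pose by exact timestamp.  All frames of the
    ``holdout`` activities form the validation split; the remaining frames
    are shuffled and divided frame-wise by ``split`` fractions into train
    and test (the 80/20 protocol with two whole activities held out).
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    body = body or BodyModel()
    unknown = [a for a in activities if a not in ACTIVITY_CONTACTS]
    if unknown:
        raise _unknown_activity(unknown[0])
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("train/test fractions must sum to 1")
    bad = [a for a in holdout if a not in activities]
    if bad:
        raise ValueError(f"holdout activities {bad} not in the activity list")

    mx, my = cfg.mat_mm
    center = (mx / 2.0, my / 2.0)
    scenes: list[SyntheticScene] = []
    for i in range(n_frames):
        act = activities[i % len(activities)]
        pose = sample_pose(body, act, spawn_seed(cfg.seed, "pose", i), center_mm=center)
        clean = render_pressure(pose, cfg, weight_kg=body.weight_kg,
                                spread_scale=posture_spread(pose, body))
        noisy = corrupt(clean, cfg, rng_seed=spawn_seed(cfg.seed, "noise", i))
        scenes.append(SyntheticScene(clean, noisy, pose, act, t=i / 60.0))

    holdset = set(holdout)
    val_idx = [i for i, s in enumerate(scenes) if s.activity in holdset]
    rest = np.array([i for i in range(n_frames) if scenes[i].activity not in holdset])
    g = _rng(cfg.seed, "split")
    g.shuffle(rest)
    n_train = int(round(split[0] * rest.size))
    index = {
        "train": sorted(int(i) for i in rest[:n_train]),
        "test": sorted(int(i) for i in rest[n_train:]),
        "val": val_idx,
    }
    return scenes, index
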