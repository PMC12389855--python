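"""Restoration and pose evaluation metrics.

Stage 1 (image restoration): PSNR, SSIM, MAE and an LPIPS-style perceptual
distance.  The perceptual distance follows the usual recipe — per-layer,
per-position unit-normalised feature maps compared by weighted squared
distance — but uses a built-in fixed-seed random convolutional extractor,
so it needs no pretrained download; its absolute values are therefore not
comparable to published LPIPS numbers, only to itself.

Stage 2 (pose): MPJPE (mean Euclidean joint error, mm) and AKLEB
(per-axis mean absolute coordinate error, mm).

``max_i`` for pressure frames defaults to the 15 kPa sensor ceiling: the
frames are physical measurements, not 8-bit images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._seeding import rng as _rng

DEFAULT_MAX_I = 15.0


def _check_same_shape(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def psnr(x: np.ndarray, y: np.ndarray, max_i: float = DEFAULT_MAX_I) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical inputs."""
    x, y = _check_same_shape(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_i**2 / mse)


def mae(x: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute pixel difference."""
    x, y = _check_same_shape(x, y)
    return float(np.mean(np.abs(x - y)))


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    max_i: float = DEFAULT_MAX_I,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity over Gaussian-weighted sliding windows.

    Local means/variances/covariance are computed with a Gaussian window
    (sigma 1.5, radius (window-1)/2); c1 = (k1*max_i)^2, c2 = (k2*max_i)^2.
    The map border (half a window) is cropped before averaging.
    """
    x, y = _check_same_shape(x, y)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(x.shape):
        raise ValueError("window larger than image")
    r = (window - 1) // 2
    truncate = r / sigma

    def G(a):
        return gaussian_filter(a, sigma=sigma, truncate=truncate, mode="reflect")

    ux, uy = G(x), G(y)
    uxx, uyy, uxy = G(x * x), G(y * y), G(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    c1 = (k1 * max_i) ** 2
    c2 = (k2 * max_i) ** 2
    s = ((2 * ux * uy + c1) * (2 * cxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    return float(s[r:-r or None, r:-r or None].mean())


class RandomConvExtractor:
    """A deterministic 2-layer random convolutional feature extractor.

    Fixed-seed Gaussian 3x3 kernels with ReLU between layers; layer outputs
    serve as the phi_l feature maps of the perceptual distance.
    """

    def __init__(self, channels: tuple[int, ...] = (8, 16), seed: int = 7):
        g = _rng(seed, "lpips")
        self.kernels = []
        c_in = 1
        for c_out in channels:
            w = g.normal(0, 1.0 / np.sqrt(c_in * 9), size=(c_out, c_in, 3, 3))
            self.kernels.append(w)
            c_in = c_out

    def __call__(self, frame: np.ndarray) -> list[np.ndarray]:
        x = np.asarray(frame, dtype=float)[None]  # [1, H, W]
        feats = []
        for li, w in enumerate(self.kernels):
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
            win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
            x = np.einsum("chwij,ocij->ohw", win, w, optimize=True)
            if li < len(self.kernels) - 1:
                x = np.maximum(x, 0.0)
            feats.append(x.copy())
        return feats


_DEFAULT_EXTRACTOR: RandomConvExtractor | None = None


def _default_extractor() -> RandomConvExtractor:
    global _DEFAULT_EXTRACTOR
    if _DEFAULT_EXTRACTOR is None:
        _DEFAULT_EXTRACTOR = RandomConvExtractor()
    return _DEFAULT_EXTRACTOR


def lpips_like(
    x: np.ndarray,
    y: np.ndarray,
    extractor=None,
    weights: tuple[float, ...] | None = None,
) -> float:
    """Perceptual distance: sum_l w_l * mean_position ||phi_l(x) - phi_l(y)||^2
    with unit channel-normalised features; 0 for identical inputs.

    ``extractor`` maps a frame to a list of [C, H, W] feature maps; the
    built-in fixed-seed convolutional extractor is used when None.
    """
    x, y = _check_same_shape(x, y)
    if extractor is None:
        extractor = _default_extractor()
    elif not callable(extractor):
        raise TypeError(
            "extractor must be callable; pass None to use the built-in "
            "fixed-seed convolutional extractor"
        )
    fx, fy = extractor(x), extractor(y)
    if weights is None:
        weights = tuple(1.0 / len(fx) for _ in fx)

    def unit(f):
        n = np.sqrt((f**2).sum(axis=0, keepdims=True)) + 1e-10
        return f / n

    total = 0.0
    for w, a, b in zip(weights, fx, fy):
        d = unit(a) - unit(b)
        total += w * float((d**2).sum(axis=0).mean())
    return total


def mpjpe(pred: np.ndarray, gt: np.ndarray, per_joint_average: bool = True) -> float:
    """Mean per-joint position error in mm over [N, J, 3] batches.

    Default normalisation is 1/(N*J); ``per_joint_average=False`` sums over
    joints and divides by N only.
    """
    pred, gt = _check_same_shape(pred, gt)
    if pred.ndim == 2:
        pred, gt = pred[None], gt[None]
    d = np.linalg.norm(pred - gt, axis=-1)  # [N, J]
    if per_joint_average:
        return float(d.mean())
    return float(d.sum(axis=1).mean())


def akleb(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    """Per-axis (X, Y, Z) mean absolute coordinate error in mm."""
    pred, gt = _check_same_shape(pred, gt)
    if pred.ndim == 2:
        pred, gt = pred[None], gt[None]
    e = np.abs(pred - gt).mean(axis=(0, 1))
    return float(e[0]), float(e[1]), float(e[2])


@dataclass
class RestorationReport:
    psnr_db: float
    ssim: float
    mae: float
    lpips: float
    n_frames: int

    def as_dict(self) -> dict:
        return {"psnr_db": self.psnr_db, "ssim": self.ssim, "mae": self.mae,
                "lpips": self.lpips, "n_frames": self.n_frames}


@dataclass
class PoseReport:
    mpjpe_mm: float
    akleb_mm: tuple[float, float, float]
    n_samples: int
    n_joints: int

    def as_dict(self) -> dict:
        return {"mpjpe_mm": self.mpjpe_mm,
                "akleb_x_mm": self.akleb_mm[0], "akleb_y_mm": self.akleb_mm[1],
                "akleb_z_mm": self.akleb_mm[2],
                "n_samples": self.n_samples, "n_joints": self.n_joints}


def restoration_report(pred_frames, gt_frames, max_i: float = DEFAULT_MAX_I) -> RestorationReport:
    """Average Stage-1 metrics over paired frame lists."""
    ps, ss, ms, ls = [], [], [], []
    for p, g in zip(pred_frames, gt_frames):
        ps.append(psnr(p, g, max_i))
        ss.append(ssim(p, g, max_i))
        ms.append(mae(p, g))
        ls.append(lpips_like(p, g))
    return RestorationReport(
        psnr_db=float(np.mean(ps)), ssim=float(np.mean(ss)),
        mae=float(np.mean(ms)), lpips=float(np.mean(ls)), n_frames=len(ps),
    )


def pose_report(pred: np.ndarray, gt: np.ndarray) -> PoseReport:
    pred = np.asarray(pred, dtype=float)
    return PoseReport(
        mpjpe_mm=mpjpe(pred, gt), akleb_mm=akleb(pred, gt),
        n_samples=pred.shape[0], n_joints=pred.shape[1],
    )
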