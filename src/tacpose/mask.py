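"""Refined-mask generation: threshold the raw pressure frame, then apply a
morphological opening (three erosions followed by three dilations with a
solid 5x5 structuring element) to delete small noise blobs while keeping
the large contact areas.

Pixels outside the frame count as background for the erosions, so the
foreground shrinks conservatively at the border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from skimage.filters import threshold_otsu


@dataclass
class MaskParams:
    threshold: float | str = "otsu"  # absolute kPa, or "otsu"
    n_erosions: int = 3
    n_dilations: int = 3
    kernel: int = 5

    def __post_init__(self):
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 3")
        if self.n_erosions < 0 or self.n_dilations < 0:
            raise ValueError("erosion/dilation counts must be >= 0")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError("threshold must be a number or 'otsu'")


def _otsu_threshold(frame: np.ndarray) -> float | None:
    """Otsu's threshold computed on the nonzero pixels; None if degenerate."""
    vals = frame[frame > 0]
    if vals.size == 0:
        return None
    if np.ptp(vals) == 0:
        return float(vals[0])
    return float(threshold_otsu(vals))


def binarize(frame: np.ndarray, params: MaskParams) -> np.ndarray:
    """Binary mask: 1 where frame >= threshold.

    In 'otsu' mode the threshold comes from the histogram of the frame's
    nonzero pixels; an all-zero frame yields an all-zero mask.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    if params.threshold == "otsu":
        thr = _otsu_threshold(frame)
        if thr is None:
            return np.zeros(frame.shape, dtype=np.uint8)
    else:
        thr = float(params.threshold)
    return (frame >= thr).astype(np.uint8)


def open_mask(mask: np.ndarray, params: MaskParams) -> np.ndarray:
    """n_erosions binary erosions then n_dilations dilations with a solid
    kernel x kernel square; outside-frame pixels are background."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("open_mask expects a binary (0/1) mask")
    structure = np.ones((params.kernel, params.kernel), dtype=bool)
    out = mask.astype(bool)
    if params.n_erosions:
        out = ndimage.binary_erosion(
            out, structure=structure, iterations=params.n_erosions, border_value=0
        )
    if params.n_dilations:
        out = ndimage.binary_dilation(
            out, structure=structure, iterations=params.n_dilations, border_value=0
        )
    return out.astype(np.uint8)


def refine(frame: np.ndarray, params: MaskParams | None = None) -> np.ndarray:
    """Threshold then open: the refined foreground mask of a pressure frame."""
    params = params or MaskParams()
    return open_mask(binarize(frame, params), params)
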