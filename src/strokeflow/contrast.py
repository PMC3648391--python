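"""Speckle contrast and flow-index images from raw frame stacks.

A raw acquisition is a time-ordered stack of intensity frames.  Contrast is
the ratio of the sample standard deviation to the sample mean of intensity,
taken either over time (per pixel, within blocks of consecutive frames) or
over space (within a small moving window of one frame).  The flow index is
``1/k^2``, proportional to red-blood-cell velocity and used as a relative
measure of cerebral blood flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "RawSpeckleStack",
    "ContrastImage",
    "FlowIndexImage",
    "temporal_contrast",
    "spatial_contrast",
    "flow_index",
]

DEFAULT_BLOCK_SIZE = 100  # frames aggregated into one contrast image
DEFAULT_K_FLOOR = 1e-3


@dataclass
class RawSpeckleStack:
    """Time-ordered grayscale speckle frames from one imaging session.

    frames : (n_frames, rows, cols) array of non-negative intensities.
    bregma_px : (row, col) pixel of the bregma anatomical reference.
    """

    frames: np.ndarray
    exposure_time_s: float
    frame_rate_fps: float
    pixel_pitch_mm: float
    bregma_px: tuple[int, int]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (time, rows, cols) array with >= 1 frame")
        if np.any(np.asarray(self.frames[0]) < 0):
            raise ValueError("intensities must be non-negative")
        for name in ("exposure_time_s", "frame_rate_fps", "pixel_pitch_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ContrastImage:
    """Per-pixel speckle contrast k with a validity mask (True = valid)."""

    k: np.ndarray
    mask: np.ndarray
    method: str  # "temporal" | "spatial"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k.shape != self.mask.shape:
            raise ValueError("k and mask shapes differ")
        if np.any(self.k[self.mask] < 0):
            raise ValueError("contrast must be >= 0 on valid pixels")


@dataclass
class FlowIndexImage:
    """Per-pixel flow index 1/k^2; ``floor_applied`` marks floored pixels."""

    flow_index: np.ndarray
    mask: np.ndarray
    floor_applied: np.ndarray
    k_floor: float
    params: dict[str, Any] = field(default_factory=dict)


def temporal_contrast(stack: RawSpeckleStack, block_size: int = DEFAULT_BLOCK_SIZE) -> ContrastImage:
    """Temporal speckle contrast over disjoint blocks of consecutive frames.

    For each pixel and each disjoint block of ``block_size`` frames,
    k = sample SD (n-1 denominator) / sample mean.  When the stack holds
    several blocks the per-block contrast images are averaged pixel-wise
    (e.g. 50 blocks of 100 frames for a 15-min session at ~23 fps).  Pixels
    whose block mean is <= 0 are excluded from that block; pixels with no
    usable block are masked invalid.

    Trailing frames that do not fill a block are ignored.
    """
    if block_size < 2:
        raise ValueError(f"block_size must be >= 2, got {block_size}")
    n = stack.n_frames
    if n < block_size:
        raise ValueError(
            f"stack has {n} frames but block_size={block_size} requires at least {block_size}"
        )
    n_blocks = n // block_size
    h, w = stack.image_shape
    frames = np.asarray(stack.frames[: n_blocks * block_size], dtype=np.float64)
    blocks = frames.reshape(n_blocks, block_size, h, w)
    mean = blocks.mean(axis=1)
    sd = blocks.std(axis=1, ddof=1)
    ok = mean > 0
    k_blocks = np.full_like(mean, np.nan)
    np.divide(sd, mean, out=k_blocks, where=ok)
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        k = np.nansum(k_blocks, axis=0) / np.where(n_ok > 0, n_ok, 1)
    mask = n_ok > 0
    k[~mask] = np.nan
    return ContrastImage(
        k=k,
        mask=mask,
        method="temporal",
        params={"block_size": block_size, "n_blocks": int(n_blocks)},
    )


def spatial_contrast(frame: np.ndarray, window: int = 7) -> ContrastImage:
    """Spatial speckle contrast of one frame over a centered moving window.

    k = moving-window sample SD (n-1) / moving-window mean; the border of
    width ``window // 2`` is masked, as are pixels with non-positive window
    mean.
    """
    from scipy.ndimage import uniform_filter

    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    img = np.asarray(frame, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("frame must be 2-D")
    if min(img.shape) < window:
        raise ValueError(f"frame smaller than window {window}")
    n = window * window
    m1 = uniform_filter(img, size=window, mode="constant")
    m2 = uniform_filter(img * img, size=window, mode="constant")
    var = (m2 - m1 * m1) * (n / (n - 1))
    var = np.clip(var, 0.0, None)  # guard tiny negative round-off
    b = window // 2
    mask = np.zeros(img.shape, dtype=bool)
    mask[b : img.shape[0] - b, b : img.shape[1] - b] = True
    mask &= m1 > 0
    k = np.full(img.shape, np.nan)
    np.divide(np.sqrt(var), m1, out=k, where=mask)
    return ContrastImage(k=k, mask=mask, method="spatial", params={"window": window})


def flow_index(contrast: ContrastImage, k_floor: float = DEFAULT_K_FLOOR) -> FlowIndexImage:
    """Flow index 1/k^2 with an explicit contrast floor.

    ``flow_index = 1 / max(k, k_floor)^2``; pixels where the floor engaged
    are flagged in ``floor_applied`` (they encode measurement failure, not
    flow, and are excluded from downstream ROI means).  Invalid contrast
    pixels stay invalid.
    """
    if k_floor <= 0:
        raise ValueError(f"k_floor must be > 0, got {k_floor}")
    k = contrast.k
    mask = contrast.mask
    floored = mask & (k < k_floor)
    k_eff = np.where(floored, k_floor, k)
    fi = np.full(k.shape, np.nan)
    np.divide(1.0, k_eff * k_eff, out=fi, where=mask)
    return FlowIndexImage(
        flow_index=fi,
        mask=mask,
        floor_applied=floored,
        k_floor=k_floor,
        params=dict(contrast.params, method=contrast.method),
    )
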