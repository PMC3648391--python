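"""Bregma-referenced ROI extraction and relative-CBF ratios.

The measured zone is a rectangle of 6 mm x 4 mm placed 2 mm lateral and
1 mm anterior to the bregma, covering most of the territory supplied by the
middle cerebral artery.  The scalar per session is the arithmetic mean of
the flow index (1/k^2) over valid ROI pixels; relative CBF is that scalar
expressed as a ratio to the same animal's pre-occlusion baseline session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contrast import FlowIndexImage

__all__ = [
    "ROISpec",
    "SessionMeasurement",
    "RCBFRatio",
    "roi_to_pixels",
    "session_mean",
    "rcbf_ratio",
]


@dataclass(frozen=True)
class ROISpec:
    """MCA-territory ROI: size and offsets from bregma, in millimetres.

    The anchor convention locates the ROI's medial-posterior corner at
    (offset_lateral_mm, offset_anterior_mm) from bregma; the rectangle
    extends a further ``width_mm`` laterally and ``height_mm`` anteriorly.
    """

    width_mm: float = 6.0
    height_mm: float = 4.0
    offset_lateral_mm: float = 2.0
    offset_anterior_mm: float = 1.0
    anchor: str = "medial_posterior_corner"

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("ROI width and height must be > 0")
        if self.anchor != "medial_posterior_corner":
            raise ValueError(f"unknown anchor convention: {self.anchor!r}")


@dataclass
class SessionMeasurement:
    """Mean flow index over the valid ROI pixels of one imaging session."""

    animal_id: str
    timepoint: str  # "baseline" | "during_mcao" | "day14"
    mean_flow_index: float
    n_valid_pixels: int
    n_roi_pixels: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_flow_index) or self.mean_flow_index <= 0:
            raise ValueError("mean_flow_index must be finite and > 0")


@dataclass
class RCBFRatio:
    """Relative CBF: session mean flow index over the animal's baseline."""

    animal_id: str
    timepoint: str
    ratio: float


def roi_to_pixels(
    roi: ROISpec,
    pixel_pitch_mm: float,
    bregma_px: tuple[int, int],
    image_shape: tuple[int, int],
    hemisphere: str = "left",
) -> tuple[int, int, int, int]:
    """Convert the millimetre ROI to a half-open pixel rectangle.

    Image convention: row index increases posteriorly, column index
    increases to the animal's right; the left hemisphere is therefore at
    smaller column indices than bregma.  Returns 0-based half-open
    ``(row_start, row_stop, col_start, col_stop)`` with
    ``ceil(height/pitch)`` rows and ``ceil(width/pitch)`` columns.

    Raises ValueError (reporting the missing padding) if the rectangle
    leaves the image.
    """
    if pixel_pitch_mm <= 0:
        raise ValueError("pixel_pitch_mm must be > 0")
    if hemisphere not in ("left", "right"):
        raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    br, bc = bregma_px
    n_rows = math.ceil(roi.height_mm / pixel_pitch_mm)
    n_cols = math.ceil(roi.width_mm / pixel_pitch_mm)
    off_lat = round(roi.offset_lateral_mm / pixel_pitch_mm)
    off_ant = round(roi.offset_anterior_mm / pixel_pitch_mm)

    row_stop = br - off_ant  # anterior of bregma: smaller rows
    row_start = row_stop - n_rows
    if hemisphere == "left":
        col_stop = bc - off_lat
        col_start = col_stop - n_cols
    else:
        col_start = bc + off_lat
        col_stop = col_start + n_cols

    h, w = image_shape
    pad_top = max(0, -row_start)
    pad_bottom = max(0, row_stop - h)
    pad_left = max(0, -col_start)
    pad_right = max(0, col_stop - w)
    if pad_top or pad_bottom or pad_left or pad_right:
        raise ValueError(
            "ROI exits the image; required padding (top, bottom, left, right) = "
            f"({pad_top}, {pad_bottom}, {pad_left}, {pad_right}) px"
        )
    return row_start, row_stop, col_start, col_stop


def session_mean(
    flow: FlowIndexImage,
    roi_px: tuple[int, int, int, int],
    animal_id: str,
    timepoint: str,
    min_valid_fraction: float = 0.9,
) -> SessionMeasurement:
    """Arithmetic mean of the flow index over valid, non-floored ROI pixels.

    A session whose valid-pixel fraction falls below ``min_valid_fraction``
    is rejected as unusable rather than silently averaged.
    """
    r0, r1, c0, c1 = roi_px
    h, w = flow.flow_index.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("ROI rectangle outside flow-index image")
    sub = flow.flow_index[r0:r1, c0:c1]
    valid = flow.mask[r0:r1, c0:c1] & ~flow.floor_applied[r0:r1, c0:c1]
    n_roi = sub.size
    n_valid = int(valid.sum())
    if n_valid < min_valid_fraction * n_roi:
        raise ValueError(
            f"only {n_valid}/{n_roi} valid ROI pixels "
            f"(< {min_valid_fraction:.0%}); session unusable"
        )
    return SessionMeasurement(
        animal_id=animal_id,
        timepoint=timepoint,
        mean_flow_index=float(sub[valid].mean()),
        n_valid_pixels=n_valid,
        n_roi_pixels=n_roi,
    )


def rcbf_ratio(session: SessionMeasurement, baseline: SessionMeasurement) -> RCBFRatio:
    """Relative CBF of a session against the same animal's baseline."""
    if session.animal_id != baseline.animal_id:
        raise ValueError(
            f"animal mismatch: session {session.animal_id!r} vs baseline {baseline.animal_id!r}"
        )
    if baseline.timepoint != "baseline":
        raise ValueError(f"baseline measurement has timepoint {baseline.timepoint!r}")
    return RCBFRatio(
        animal_id=session.animal_id,
        timepoint=session.timepoint,
        ratio=session.mean_flow_index / baseline.mean_flow_index,
    )
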