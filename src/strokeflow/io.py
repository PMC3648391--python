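"""File I/O: speckle stacks as multi-page TIFF with a JSON metadata sidecar,
phantom/QC images as PNG, tidy tables as CSV (via pandas directly)."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .contrast import RawSpeckleStack

__all__ = ["write_speckle_stack", "read_speckle_stack", "write_image"]


def write_speckle_stack(path: str | Path, stack: RawSpeckleStack) -> Path:
    """Write a stack as multi-page grayscale TIFF plus ``<stem>.json`` sidecar."""
    path = Path(path).with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.frames))
    sidecar = {
        "exposure_time_s": stack.exposure_time_s,
        "frame_rate_fps": stack.frame_rate_fps,
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "bregma_px": list(stack.bregma_px),
        "meta": {k: _jsonable(v) for k, v in stack.meta.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_speckle_stack(path: str | Path) -> RawSpeckleStack:
    """Read a stack written by :func:`write_speckle_stack`."""
    path = Path(path).with_suffix(".tif")
    frames = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return RawSpeckleStack(
        frames=frames,
        exposure_time_s=sidecar["exposure_time_s"],
        frame_rate_fps=sidecar["frame_rate_fps"],
        pixel_pitch_mm=sidecar["pixel_pitch_mm"],
        bregma_px=tuple(sidecar["bregma_px"]),
        meta=sidecar.get("meta", {}),
    )


def write_image(path: str | Path, image: np.ndarray) -> Path:
    """Write an RGB or grayscale image (PNG/TIFF chosen by suffix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image))
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
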