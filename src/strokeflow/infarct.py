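"""TTC infarct volumetry by the indirect method.

TTC (2,3,5-triphenyltetrazolium chloride) stains metabolically active tissue
red; infarcted tissue stays pale.  Each coronal section is segmented into
background / viable / pale, split into hemispheres about a midline, and the
infarct volume percentage is computed indirectly as

    100 * (sum A_contra - sum A_ipsi_normal) / sum A_contra

with thickness-weighted sums across sections (weights cancel for
equal-thickness sections).  The indirect form references the ipsilateral
normal area to the contralateral hemisphere, which reduces edema bias
relative to direct pale-area measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "BACKGROUND",
    "VIABLE",
    "PALE",
    "TTCSectionSet",
    "SegmentationParams",
    "SectionAreas",
    "InfarctResult",
    "segment_ttc",
    "render_labels",
    "split_hemispheres",
    "section_areas",
    "infarct_percentage",
]

BACKGROUND, VIABLE, PALE = 0, 1, 2

# default phantom/render colours (RGB, uint8)
LABEL_COLORS = {
    BACKGROUND: (15, 15, 15),
    VIABLE: (180, 40, 50),
    PALE: (235, 205, 185),
}


@dataclass
class TTCSectionSet:
    """Ordered coronal TTC section photographs with shared calibration."""

    sections: list[np.ndarray]  # RGB uint8 images
    section_thickness_mm: float
    pixel_pitch_mm: float
    midlines: list[float] | None = None  # midline column per section

    def __post_init__(self) -> None:
        if len(self.sections) < 1:
            raise ValueError("need at least one section")
        if self.section_thickness_mm <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("thickness and pixel pitch must be > 0")
        if self.midlines is not None and len(self.midlines) != len(self.sections):
            raise ValueError("one midline per section required")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds for the three-class TTC segmentation.

    tissue_threshold : brightness (mean RGB) above which a pixel is tissue.
    pale_threshold : manual red-dominance cut; pixels below it are pale.
        None (default) selects the threshold by Otsu within tissue.
    min_class_contrast : minimum separation of viable/pale red-dominance
        class means for the Otsu split to be accepted; below it the section
        is declared infarct-free (guards against splitting pure noise).
    min_object_px : specks smaller than this are removed from the pale mask.
    """

    tissue_threshold: float = 60.0
    pale_threshold: float | None = None
    min_class_contrast: float = 40.0
    min_object_px: int = 20
    min_tissue_px: int = 100


@dataclass
class SectionAreas:
    """Per-section hemisphere areas in mm^2."""

    area_contralateral_mm2: float
    area_ipsilateral_normal_mm2: float
    area_pale_mm2: float


@dataclass
class InfarctResult:
    """Indirect infarct-volume percentage with per-section contributions."""

    infarct_percent: float
    per_section: list[SectionAreas] = field(default_factory=list)


def _red_dominance(rgb: np.ndarray) -> np.ndarray:
    rgb = rgb.astype(np.float64)
    return rgb[..., 0] - 0.5 * (rgb[..., 1] + rgb[..., 2])


def segment_ttc(section: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Three-class labeling of a TTC section photograph.

    Background is separated by a brightness threshold; within tissue the
    pale (infarct) class is split from viable red tissue on a red-dominance
    score ``R - (G+B)/2`` (Otsu by default, manual override available),
    followed by morphological cleanup.  Raises ValueError when no tissue is
    found.
    """
    p = params or SegmentationParams()
    img = np.asarray(section)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("section must be an RGB image")
    brightness = img.astype(np.float64).mean(axis=2)
    tissue = brightness > p.tissue_threshold
    tissue = ndimage.binary_fill_holes(tissue)
    tissue = remove_small_objects(tissue, max_size=p.min_object_px - 1)
    if tissue.sum() < p.min_tissue_px:
        raise ValueError("no tissue found in section image")

    score = _red_dominance(img)
    if p.pale_threshold is not None:
        pale = tissue & (score < p.pale_threshold)
    else:
        vals = score[tissue]
        thr = threshold_otsu(vals)
        lo, hi = vals[vals < thr], vals[vals >= thr]
        if lo.size == 0 or hi.size == 0 or (hi.mean() - lo.mean()) < p.min_class_contrast:
            pale = np.zeros_like(tissue)  # unimodal: no infarct in this section
        else:
            pale = tissue & (score < thr)
    pale = remove_small_objects(pale, max_size=p.min_object_px - 1)
    pale = ndimage.binary_fill_holes(pale) & tissue

    labels = np.zeros(img.shape[:2], dtype=np.uint8)
    labels[tissue] = VIABLE
    labels[pale] = PALE
    return labels


def render_labels(labels: np.ndarray, colors: dict[int, tuple[int, int, int]] | None = None) -> np.ndarray:
    """Render a label image back to RGB with the canonical class colours."""
    colors = colors or LABEL_COLORS
    out = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for lab, rgb in colors.items():
        out[labels == lab] = rgb
    return out


def split_hemispheres(
    labels: np.ndarray, midline_col: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Split a label image into left/right hemispheres about a vertical midline.

    ``midline_col`` defaults to the tissue centroid column.  Tissue pixels
    with column index < midline go left, the rest right; counts are
    conserved.  Returns (left_labels, right_labels, midline_col).
    """
    tissue = labels != BACKGROUND
    if midline_col is None:
        if not tissue.any():
            midline_col = labels.shape[1] / 2.0
        else:
            midline_col = float(np.nonzero(tissue)[1].mean()) + 0.5
    if not (0 <= midline_col <= labels.shape[1]):
        raise ValueError(f"midline column {midline_col} outside image of width {labels.shape[1]}")
    cols = np.arange(labels.shape[1])
    left_sel = cols[None, :] < midline_col
    left = np.where(left_sel, labels, BACKGROUND)
    right = np.where(~left_sel, labels, BACKGROUND)
    return left, right, float(midline_col)


def section_areas(
    labels: np.ndarray,
    pixel_pitch_mm: float,
    midline_col: float | None = None,
    ipsilateral: str = "left",
) -> SectionAreas:
    """Hemisphere areas (mm^2) of one labeled section.

    The contralateral area counts all tissue pixels on that side; the
    ipsilateral side is split into normal (viable) and pale areas.
    """
    if ipsilateral not in ("left", "right"):
        raise ValueError("ipsilateral must be 'left' or 'right'")
    left, right, _ = split_hemispheres(labels, midline_col)
    ipsi, contra = (left, right) if ipsilateral == "left" else (right, left)
    px = pixel_pitch_mm**2
    return SectionAreas(
        area_contralateral_mm2=float((contra != BACKGROUND).sum() * px),
        area_ipsilateral_normal_mm2=float((ipsi == VIABLE).sum() * px),
        area_pale_mm2=float((ipsi == PALE).sum() * px),
    )


def infarct_percentage(
    areas: list[SectionAreas], thicknesses_mm: list[float] | None = None
) -> InfarctResult:
    """Indirect infarct-volume percentage from per-section areas.

    100 * (sum t*A_contra - sum t*A_ipsi_normal) / sum t*A_contra, with
    section thicknesses ``t`` (equal by default, so they cancel).  Sums run
    across sections before the division — volume semantics, not a mean of
    per-section percentages.
    """
    if len(areas) < 1:
        raise ValueError("need at least one section")
    t = np.ones(len(areas)) if thicknesses_mm is None else np.asarray(thicknesses_mm, float)
    if t.shape != (len(areas),) or np.any(t <= 0):
        raise ValueError("one positive thickness per section required")
    contra = np.array([a.area_contralateral_mm2 for a in areas])
    ipsi_norm = np.array([a.area_ipsilateral_normal_mm2 for a in areas])
    total_contra = float((t * contra).sum())
    if total_contra <= 0:
        raise ValueError("total contralateral area is zero")
    pct = 100.0 * (total_contra - float((t * ipsi_norm).sum())) / total_contra
    return InfarctResult(infarct_percent=pct, per_section=list(areas))
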