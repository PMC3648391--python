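"""Synthetic ground-truth inputs for every pipeline stage.

Four generators emulate the study's raw data with analytically known truth:

* time-integrated dynamic speckle stacks over a cranial-window flow phantom,
  with per-pixel gamma-distributed intensities whose coefficient of
  variation equals the model contrast k(tau_c, T, beta);
* six-section TTC phantoms (mirrored half-ellipse hemispheres, pale ellipse
  segment) with closed-form infarct fractions;
* homogeneous-Poisson CD31+ vessel fields with known density per mm^2;
* ordinal 0-7 neurological score tables with chosen group means.

All randomness flows from one explicit seed per generator call; fixed seed
implies bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contrast import RawSpeckleStack
from .infarct import LABEL_COLORS, PALE, VIABLE, TTCSectionSet
from .rcbf import ROISpec, roi_to_pixels
from .speckle_model import contrast_model, tau_c_from_contrast
from .vessels import FieldImage

__all__ = [
    "FlowPhantom",
    "AcquisitionSpec",
    "TTCPhantomSpec",
    "TTCGroundTruth",
    "VesselFieldSpec",
    "uniform_phantom",
    "mca_phantom",
    "generate_speckle_stack",
    "generate_ttc_phantom",
    "generate_vessel_fields",
    "generate_score_table",
]

K2_FLOOR = 1e-4  # below this the gamma shape parameter 1/k^2 overflows usefully


# --------------------------------------------------------------------------
# speckle
# --------------------------------------------------------------------------


@dataclass
class FlowPhantom:
    """Ground-truth map of speckle decorrelation times over a cranial window.

    tau_map holds tau_c in seconds (velocity is proportional to 1/tau_c);
    window_extent_mm is (width, height) and must agree with the grid shape
    times pixel_pitch_mm to within one pixel.
    """

    tau_map: np.ndarray
    pixel_pitch_mm: float
    bregma_px: tuple[int, int]
    window_extent_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.tau_map = np.asarray(self.tau_map, dtype=float)
        if self.tau_map.ndim != 2:
            raise ValueError("tau_map must be 2-D")
        if not np.all(np.isfinite(self.tau_map)) or np.any(self.tau_map <= 0):
            raise ValueError("all tau_c must be finite and strictly positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        rows, cols = self.tau_map.shape
        w_mm, h_mm = self.window_extent_mm
        if abs(cols * self.pixel_pitch_mm - w_mm) > self.pixel_pitch_mm or abs(
            rows * self.pixel_pitch_mm - h_mm
        ) > self.pixel_pitch_mm:
            raise ValueError("window_extent_mm inconsistent with grid shape x pixel pitch")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera/acquisition parameters for synthetic speckle stacks.

    Defaults follow a 12-bit CCD at 5 ms exposure and 23 fps.
    mean_intensity defaults to 10% of full scale, which keeps the clipped
    tail mass below 1e-6 for every contrast k <= 1.
    """

    n_frames: int
    exposure_time_s: float = 0.005
    frame_rate_fps: float = 23.0
    beta: float = 1.0
    mean_intensity: float | None = None
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure_time_s <= 0:
            raise ValueError("exposure_time_s must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        if self.mean_intensity is not None and not (
            0 < self.mean_intensity <= self.full_scale
        ):
            raise ValueError("mean_intensity outside representable range of bit_depth")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def effective_mean(self) -> float:
        return self.mean_intensity if self.mean_intensity is not None else 0.1 * self.full_scale


def uniform_phantom(
    tau_c: float,
    pixel_pitch_mm: float = 0.2,
    window_extent_mm: tuple[float, float] = (12.0, 10.0),
    bregma_px: tuple[int, int] | None = None,
) -> FlowPhantom:
    """Uniform-flow phantom over the full cranial window."""
    w_mm, h_mm = window_extent_mm
    shape = (round(h_mm / pixel_pitch_mm), round(w_mm / pixel_pitch_mm))
    if bregma_px is None:
        # near the posterior-medial corner so the MCA ROI fits in the window
        bregma_px = (round(0.6 * h_mm / pixel_pitch_mm), round(0.75 * w_mm / pixel_pitch_mm))
    return FlowPhantom(
        tau_map=np.full(shape, float(tau_c)),
        pixel_pitch_mm=pixel_pitch_mm,
        bregma_px=bregma_px,
        window_extent_mm=window_extent_mm,
    )


def mca_phantom(
    flow_ratio: float,
    baseline_k2: float = 0.2,
    exposure_time_s: float = 0.005,
    beta: float = 1.0,
    pixel_pitch_mm: float = 0.2,
    roi: ROISpec | None = None,
    margin_mm: float = 1.0,
    hemisphere: str = "left",
) -> tuple[FlowPhantom, FlowPhantom]:
    """Baseline and session phantoms whose ROI flow-index ratio is ``flow_ratio``.

    The session phantom alters tau_c inside the MCA ROI (expanded by
    ``margin_mm`` on every side) so that the model flow index 1/k^2 there is
    exactly ``flow_ratio`` times the baseline value; outside the region the
    session equals the baseline.  Emulates occlusion (ratio < 1) and the
    hyperemic post-exercise regime (ratio > 1).
    """
    if flow_ratio <= 0:
        raise ValueError("flow_ratio must be > 0")
    k2_session = baseline_k2 / flow_ratio
    if not (K2_FLOOR < k2_session < beta):
        raise ValueError(
            f"session k^2 = baseline_k2/flow_ratio = {k2_session:.4g} not in "
            f"({K2_FLOOR}, beta={beta}); choose a different baseline_k2"
        )
    tau_base = tau_c_from_contrast(baseline_k2, exposure_time_s, beta)
    tau_sess = tau_c_from_contrast(k2_session, exposure_time_s, beta)
    baseline = uniform_phantom(tau_base, pixel_pitch_mm=pixel_pitch_mm)
    session = uniform_phantom(tau_base, pixel_pitch_mm=pixel_pitch_mm)
    roi = roi or ROISpec()
    r0, r1, c0, c1 = roi_to_pixels(
        roi, pixel_pitch_mm, baseline.bregma_px, baseline.tau_map.shape, hemisphere
    )
    m = round(margin_mm / pixel_pitch_mm)
    h, w = session.tau_map.shape
    session.tau_map[max(0, r0 - m) : min(h, r1 + m), max(0, c0 - m) : min(w, c1 + m)] = tau_sess
    return baseline, session


def generate_speckle_stack(phantom: FlowPhantom, acq: AcquisitionSpec) -> RawSpeckleStack:
    """Synthetic raw speckle stack with gamma-marginal pixel statistics.

    Per pixel, frame intensities are i.i.d. gamma with shape
    M = 1 / k^2(tau_c, T, beta) and mean ``acq.effective_mean``, rounded and
    clipped to the detector bit depth.  The coefficient of variation of a
    gamma(M) variate is 1/sqrt(M) = k, so the temporal sample contrast
    converges to the model contrast as the frame count grows.
    """
    k2 = contrast_model(phantom.tau_map, acq.exposure_time_s, acq.beta)
    if np.any(k2 < K2_FLOOR):
        raise ValueError(
            f"model k^2 below floor {K2_FLOOR}: gamma shape would overflow; "
            "increase tau_c or exposure"
        )
    shape_m = 1.0 / k2
    mean = acq.effective_mean
    rng = np.random.default_rng(acq.seed)
    frames = rng.gamma(shape_m, mean / shape_m, size=(acq.n_frames,) + phantom.tau_map.shape)
    np.rint(frames, out=frames)
    np.clip(frames, 0, acq.full_scale, out=frames)
    return RawSpeckleStack(
        frames=frames.astype(np.uint16),
        exposure_time_s=acq.exposure_time_s,
        frame_rate_fps=acq.frame_rate_fps,
        pixel_pitch_mm=phantom.pixel_pitch_mm,
        bregma_px=phantom.bregma_px,
        meta={
            "seed": acq.seed,
            "beta": acq.beta,
            "bit_depth": acq.bit_depth,
            "mean_intensity": mean,
            "model_k2_min": float(k2.min()),
            "model_k2_max": float(k2.max()),
        },
    )


# --------------------------------------------------------------------------
# TTC phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TTCPhantomSpec:
    """Geometry, staining colours and infarct load of a TTC phantom brain.

    Hemispheres are mirrored half-ellipses about a vertical midline; the
    pale (infarct) region of each section is a half-ellipse segment scaled
    by sqrt(infarct_fraction) so its area is a closed-form fraction of the
    ipsilateral hemisphere.  ``infarct_fraction`` may be a scalar or one
    value per section, each in [0, 1).
    """

    infarct_fraction: float | Sequence[float] = 0.0
    n_sections: int = 6
    section_thickness_mm: float = 2.0
    base_semi_axes_mm: tuple[float, float] = (5.5, 4.0)
    section_profile: Sequence[float] = (0.7, 0.9, 1.0, 1.0, 0.9, 0.7)
    pixel_pitch_mm: float = 0.05
    ipsilateral: str = "left"
    noise_sigma: float = 5.0
    seed: int = 0

    def fractions(self) -> np.ndarray:
        f = np.asarray(self.infarct_fraction, dtype=float)
        if f.ndim == 0:
            f = np.full(self.n_sections, float(f))
        if f.shape != (self.n_sections,):
            raise ValueError("infarct_fraction must be scalar or one value per section")
        if np.any(f < 0) or np.any(f >= 1):
            raise ValueError("infarct fractions must lie in [0, 1)")
        return f


@dataclass
class TTCGroundTruth:
    """Analytic and pixel-exact truth accompanying a generated phantom."""

    infarct_percent: float  # from pixel counts of the noise-free label masks
    infarct_percent_analytic: float  # from closed-form ellipse areas
    fractions: np.ndarray
    label_images: list[np.ndarray]
    hemisphere_areas_mm2: np.ndarray


def _section_labels(
    a_mm: float, b_mm: float, frac: float, pitch: float, ipsilateral: str
) -> np.ndarray:
    """Noise-free label image of one section (exactly mirror-symmetric grid)."""
    a_px, b_px = a_mm / pitch, b_mm / pitch
    margin = 4
    w = 2 * (int(np.ceil(a_px)) + margin)  # even width: midline between columns
    h = 2 * (int(np.ceil(b_px)) + margin)
    y, x = np.mgrid[0:h, 0:w]
    x = x - (w - 1) / 2.0  # half-integer coords, exact mirror symmetry
    y = y - (h - 1) / 2.0
    tissue = (x / a_px) ** 2 + (y / b_px) ** 2 <= 1.0
    labels = np.zeros((h, w), dtype=np.uint8)
    labels[tissue] = VIABLE
    if frac > 0:
        g = np.sqrt(frac)
        delta = 0.5 * a_px * (1.0 - g)  # keeps the pale segment strictly inside
        sgn = -1.0 if ipsilateral == "left" else 1.0
        xc = sgn * delta
        u = x - xc
        inside = (u / (g * a_px)) ** 2 + (y / (g * b_px)) ** 2 <= 1.0
        half = u <= 0 if ipsilateral == "left" else u >= 0
        labels[tissue & inside & half] = PALE
    return labels


def generate_ttc_phantom(spec: TTCPhantomSpec) -> tuple[TTCSectionSet, TTCGroundTruth]:
    """Render a TTC section set plus its ground-truth infarct percentage.

    The indirect formula on this edema-free symmetric phantom reduces to
    100 * sum(pale area) / sum(contralateral area); the ground truth is
    evaluated both analytically (ellipse areas) and by pixel count on the
    noise-free label masks (exact for the rendered images).
    """
    fracs = spec.fractions()
    if len(spec.section_profile) != spec.n_sections:
        raise ValueError("section_profile length must equal n_sections")
    rng = np.random.default_rng(spec.seed)
    a0, b0 = spec.base_semi_axes_mm
    sections, label_images = [], []
    hemi_areas = []
    pale_px_total = 0
    contra_px_total = 0
    for s, (scale, frac) in enumerate(zip(spec.section_profile, fracs)):
        a_mm, b_mm = a0 * scale, b0 * scale
        labels = _section_labels(a_mm, b_mm, frac, spec.pixel_pitch_mm, spec.ipsilateral)
        w = labels.shape[1]
        left = labels[:, : w // 2]
        right = labels[:, w // 2 :]
        ipsi, contra = (left, right) if spec.ipsilateral == "left" else (right, left)
        pale_px_total += int((ipsi == PALE).sum())
        contra_px_total += int((contra != 0).sum())
        hemi_areas.append(np.pi * a_mm * b_mm / 2.0)
        rgb = np.zeros(labels.shape + (3,), dtype=np.float64)
        for lab, color in LABEL_COLORS.items():
            rgb[labels == lab] = color
        rgb += rng.normal(0.0, spec.noise_sigma, size=rgb.shape)
        sections.append(np.clip(np.rint(rgb), 0, 255).astype(np.uint8))
        label_images.append(labels)
    hemi_areas = np.asarray(hemi_areas)
    pct_pixel = 100.0 * pale_px_total / contra_px_total
    pct_analytic = 100.0 * float((fracs * hemi_areas).sum() / hemi_areas.sum())
    section_set = TTCSectionSet(
        sections=sections,
        section_thickness_mm=spec.section_thickness_mm,
        pixel_pitch_mm=spec.pixel_pitch_mm,
        midlines=[img.shape[1] / 2.0 for img in label_images],
    )
    truth = TTCGroundTruth(
        infarct_percent=pct_pixel,
        infarct_percent_analytic=pct_analytic,
        fractions=fracs,
        label_images=label_images,
        hemisphere_areas_mm2=hemi_areas,
    )
    return section_set, truth


# --------------------------------------------------------------------------
# vessel fields
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselFieldSpec:
    """Homogeneous-Poisson CD31+ cell fields.

    Cell counts per field are Poisson(density_per_mm2 * field_area_mm2);
    centroids are uniform inside the field minus a border margin so rendered
    blobs never touch the field edge.  ``min_separation_px > 0`` enforces
    non-overlapping blobs (for detector fixtures; it thins the process
    slightly, so leave it 0 when Poisson counts matter).
    """

    density_per_mm2: float
    field_area_mm2: float = 0.25
    n_fields: int = 5
    pixel_pitch_mm: float = 0.004  # ~4 um/px at 400x
    cell_radius_px: float = 3.0
    cell_intensity: float = 200.0
    background_intensity: float = 30.0
    noise_sigma: float = 8.0
    min_separation_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_per_mm2 < 0:
            raise ValueError("density must be >= 0")
        if self.field_area_mm2 <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("area and pixel pitch must be > 0")

    @property
    def side_px(self) -> int:
        return round(np.sqrt(self.field_area_mm2) / self.pixel_pitch_mm)

    @property
    def margin_px(self) -> float:
        return self.cell_radius_px + 2.0


def _place_centroids(
    n: int, side: int, margin: float, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = margin, side - margin
    if n == 0:
        return np.empty((0, 2))
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(lo, hi, size=2)
        if min_sep > 0 and pts and np.min(
            np.linalg.norm(np.asarray(pts) - cand, axis=1)
        ) < min_sep:
            tries += 1
            if tries > 1000 * n:
                raise ValueError("cannot place non-overlapping cells; field too crowded")
            continue
        pts.append(cand)
    return np.asarray(pts)


def generate_vessel_fields(
    spec: VesselFieldSpec, render: bool = True
) -> tuple[list[FieldImage] | None, list[np.ndarray]]:
    """Generate vessel fields; returns (images or None, ground-truth centroids).

    With ``render=False`` only the Poisson centroid lists are produced,
    which is enough for estimator calibration at many replicates.
    """
    side = spec.side_px
    if 2 * spec.margin_px >= side:
        raise ValueError(
            f"cell radius {spec.cell_radius_px} px too large for a {side} px field"
        )
    rng = np.random.default_rng(spec.seed)
    lam = spec.density_per_mm2 * spec.field_area_mm2
    centroids = [
        _place_centroids(int(rng.poisson(lam)), side, spec.margin_px, spec.min_separation_px, rng)
        for _ in range(spec.n_fields)
    ]
    if not render:
        return None, centroids
    fields = []
    for pts in centroids:
        img = np.full((side, side), spec.background_intensity, dtype=np.float64)
        r2 = spec.cell_radius_px**2
        for cy, cx in pts:
            y0, y1 = int(cy - spec.cell_radius_px) - 1, int(cy + spec.cell_radius_px) + 2
            x0, x1 = int(cx - spec.cell_radius_px) - 1, int(cx + spec.cell_radius_px) + 2
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r2
            img[y0:y1, x0:x1][disk] = spec.cell_intensity
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        fields.append(FieldImage(image=img, field_area_mm2=spec.field_area_mm2))
    return fields, centroids


# --------------------------------------------------------------------------
# neurological scores
# --------------------------------------------------------------------------


def generate_score_table(
    group_means: dict[str, float],
    n_per_group: int = 12,
    days: Sequence[str] = ("day1",),
    sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ordinal 0-7 neurological score tables with chosen group means.

    Scores are drawn from a normal about each group mean, rounded to the
    nearest integer and clipped to the 0-7 scale (0 = no deficit, 7 = dead).
    Returns a tidy table (animal_id, group, day, score).
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    for g, m in group_means.items():
        if not (0.0 <= m <= 7.0):
            raise ValueError(f"group {g!r} mean {m} outside the 0-7 scale")
    rng = np.random.default_rng(seed)
    rows = []
    for g, m in group_means.items():
        for i in range(n_per_group):
            for day in days:
                raw = rng.normal(m, sd)
                score = int(np.clip(np.rint(raw), 0, 7))
                rows.append(
                    {"animal_id": f"{g}_{i:02d}", "group": g, "day": day, "score": score}
                )
    return pd.DataFrame(rows)
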