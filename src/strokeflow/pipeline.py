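"""End-to-end analysis chains composed from the stage modules.

These are the compositions the study's endpoints require: speckle stack ->
contrast -> flow index -> ROI mean -> rCBF ratio; TTC phantom ->
segmentation -> indirect infarct percentage; vessel fields -> detection ->
density per mm^2.  Each function runs one synthetic animal with a known
ground truth, which makes them the working units for calibration runs.
"""

from __future__ import annotations

import numpy as np

from .contrast import flow_index, temporal_contrast
from .infarct import infarct_percentage, section_areas, segment_ttc
from .rcbf import ROISpec, rcbf_ratio, roi_to_pixels, session_mean
from .synthetic import (
    AcquisitionSpec,
    TTCPhantomSpec,
    VesselFieldSpec,
    generate_speckle_stack,
    generate_ttc_phantom,
    generate_vessel_fields,
    mca_phantom,
)
from .vessels import density, detect_cells

__all__ = [
    "measure_rcbf_ratio",
    "measure_infarct_percent",
    "measure_vessel_density",
]


def measure_rcbf_ratio(
    flow_ratio: float,
    seed: int,
    n_frames: int = 1000,
    block_size: int = 100,
    baseline_k2: float = 0.2,
    pixel_pitch_mm: float = 0.25,
    timepoint: str = "during_mcao",
) -> float:
    """Recover a known ROI flow-index ratio through the full speckle pipeline.

    Builds baseline and session phantoms whose model ratio is
    ``flow_ratio``, simulates both acquisitions, computes temporal contrast
    and flow index, averages over the bregma-referenced MCA ROI, and returns
    the measured session/baseline ratio.
    """
    base, sess = mca_phantom(flow_ratio, baseline_k2=baseline_k2, pixel_pitch_mm=pixel_pitch_mm)
    ss = np.random.SeedSequence(seed)
    seed_b, seed_s = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    roi_px = roi_to_pixels(ROISpec(), pixel_pitch_mm, base.bregma_px, base.tau_map.shape)
    measurements = {}
    for name, phantom, sd in (("baseline", base, seed_b), ("session", sess, seed_s)):
        stack = generate_speckle_stack(phantom, AcquisitionSpec(n_frames=n_frames, seed=sd))
        fi = flow_index(temporal_contrast(stack, block_size=block_size))
        measurements[name] = session_mean(
            fi, roi_px, animal_id=f"sim{seed}", timepoint="baseline" if name == "baseline" else timepoint
        )
    return rcbf_ratio(measurements["session"], measurements["baseline"]).ratio


def measure_infarct_percent(spec: TTCPhantomSpec) -> tuple[float, float]:
    """Segment a generated TTC phantom and apply the indirect formula.

    Returns (measured_percent, ground_truth_percent), the latter from pixel
    counts of the noise-free label masks.
    """
    section_set, truth = generate_ttc_phantom(spec)
    areas = [
        section_areas(segment_ttc(img), section_set.pixel_pitch_mm, midline)
        for img, midline in zip(section_set.sections, section_set.midlines)
    ]
    result = infarct_percentage(areas, [section_set.section_thickness_mm] * len(areas))
    return result.infarct_percent, truth.infarct_percent


def measure_vessel_density(spec: VesselFieldSpec, render: bool = True) -> float:
    """Density per mm^2 for one synthetic animal (five random fields).

    With ``render=True`` cells are detected from the rendered images; with
    ``render=False`` the generator's ground-truth counts are used directly
    (for estimator calibration at many replicates).
    """
    fields, centroids = generate_vessel_fields(spec, render=render)
    if render:
        counts = [len(detect_cells(f)) for f in fields]
    else:
        counts = [len(c) for c in centroids]
    return density(counts, spec.field_area_mm2).density_per_mm2
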