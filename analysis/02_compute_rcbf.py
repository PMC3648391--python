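"""Compute relative CBF for every simulated session in the cohort manifest.

Reads the stacks written by 01_simulate_speckle_cohort.py, forms temporal
contrast over 100-frame blocks, inverts to the 1/k^2 flow index, averages
over the 6 mm x 4 mm MCA ROI and expresses each session as a ratio to the
same animal's baseline.  Writes results/rcbf_ratios.csv and pseudocolor QC
images to scratch/qc/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from strokeflow import ROISpec, flow_index, rcbf_ratio, roi_to_pixels, session_mean, temporal_contrast
from strokeflow.io import read_speckle_stack

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = pd.read_csv(ROOT / "results" / "speckle_manifest.csv")
    measurements = {}
    qc_dir = ROOT / "scratch" / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    for rec in manifest.itertuples():
        stack = read_speckle_stack(ROOT / rec.stack_path)
        fi = flow_index(temporal_contrast(stack, block_size=100))
        roi_px = roi_to_pixels(
            ROISpec(), stack.pixel_pitch_mm, stack.bregma_px, fi.flow_index.shape
        )
        m = session_mean(fi, roi_px, rec.animal_id, rec.timepoint)
        measurements[(rec.animal_id, rec.timepoint)] = m
        if rec.timepoint == "during_mcao":
            fig, ax = plt.subplots(figsize=(4, 3))
            im = ax.imshow(fi.flow_index, cmap="jet")
            r0, r1, c0, c1 = roi_px
            ax.add_patch(
                plt.Rectangle((c0, r0), c1 - c0, r1 - r0, fill=False, edgecolor="k")
            )
            fig.colorbar(im, label="1/k$^2$")
            ax.set_title(f"{rec.animal_id} {rec.timepoint}")
            fig.savefig(qc_dir / f"{rec.animal_id}_{rec.timepoint}.png", dpi=100)
            plt.close(fig)

    rows = []
    for rec in manifest.itertuples():
        m = measurements[(rec.animal_id, rec.timepoint)]
        base = measurements[(rec.animal_id, "baseline")]
        rows.append(
            {
                "animal_id": rec.animal_id,
                "group": rec.group,
                "timepoint": rec.timepoint,
                "mean_flow_index": m.mean_flow_index,
                "n_valid_pixels": m.n_valid_pixels,
                "rcbf_ratio": rcbf_ratio(m, base).ratio,
                "model_flow_ratio": rec.model_flow_ratio,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "rcbf_ratios.csv", index=False)
    summary = (
        df[df.timepoint != "baseline"]
        .groupby(["group", "timepoint"])["rcbf_ratio"]
        .agg(["mean", "std"])
        .round(3)
    )
    print("rCBF ratios vs baseline (mean over animals):")
    print(summary)
    print("-> results/rcbf_ratios.csv; QC images in scratch/qc/")


if __name__ == "__main__":
    main()
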