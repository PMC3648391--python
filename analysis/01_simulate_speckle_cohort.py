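"""Simulate the speckle-flowmetry cohort: baseline, during-occlusion and
day-14 sessions per animal, written as multi-page TIFF stacks + JSON sidecars.

Groups follow the study design: sham (no flow change), non-exercise (occlusion
to ~0.31 of baseline, spontaneous recovery to ~1.0 at day 14) and early
exercise (same occlusion, day-14 hyperemia at ~1.3x baseline).  Stacks go to
scratch/speckle/ (bulky, regenerable); the session manifest with ground-truth
ratios goes to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from strokeflow import AcquisitionSpec, generate_speckle_stack, mca_phantom, uniform_phantom
from strokeflow.io import write_speckle_stack
from strokeflow.speckle_model import tau_c_from_contrast

ROOT = Path(__file__).resolve().parents[1]
SEED = 20130426
N_PER_GROUP = 2  # animals per group at this demonstration scale
N_FRAMES = 1000  # 10 blocks of 100 frames per session
PITCH_MM = 0.25

GROUP_RATIOS = {  # model ROI flow ratio per (group, timepoint)
    "sham": {"during_mcao": 1.0, "day14": 1.0},
    "non_exercise": {"during_mcao": 0.31, "day14": 1.0},
    "early_exercise": {"during_mcao": 0.31, "day14": 1.3},
}


def main() -> None:
    out_dir = ROOT / "scratch" / "speckle"
    rng = np.random.default_rng(SEED)
    rows = []
    for group, ratios in GROUP_RATIOS.items():
        for i in range(N_PER_GROUP):
            animal = f"{group}_{i:02d}"
            for timepoint in ("baseline", "during_mcao", "day14"):
                ratio = 1.0 if timepoint == "baseline" else ratios[timepoint]
                if ratio == 1.0:
                    phantom = uniform_phantom(
                        tau_c_from_contrast(0.2, 0.005), pixel_pitch_mm=PITCH_MM
                    )
                else:
                    _, phantom = mca_phantom(ratio, pixel_pitch_mm=PITCH_MM)
                seed = int(rng.integers(2**31))
                stack = generate_speckle_stack(
                    phantom, AcquisitionSpec(n_frames=N_FRAMES, seed=seed)
                )
                path = write_speckle_stack(out_dir / f"{animal}_{timepoint}", stack)
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "timepoint": timepoint,
                        "model_flow_ratio": ratio,
                        "seed": seed,
                        "stack_path": str(path.relative_to(ROOT)),
                    }
                )
    manifest = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    manifest.to_csv(ROOT / "results" / "speckle_manifest.csv", index=False)
    print(f"wrote {len(rows)} sessions for {3 * N_PER_GROUP} animals -> {out_dir}")
    print(f"manifest -> results/speckle_manifest.csv")


if __name__ == "__main__":
    main()
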