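#!/usr/bin/env python
"""Component-level spectral analysis: manual ROIs vs automated segmentation.

On a default synthetic section (BrM 549 nm, lipofuscin 575 nm,
melanolipofuscin 578 nm), compares granule-sized manual ROI class means
against the automated threshold + band-split peaks, mirroring the two
analysis arms of the study.  Writes results/component_peaks.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from afspectra.pipeline import analyze_section
from afspectra.roi_analysis import ROI, analyze_rois
from afspectra.synthetic_scene import (
    BRM,
    LIPOFUSCIN,
    MELANOLIPOFUSCIN,
    SceneConfig,
    render_section,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def granule_rois(gt, label, name, k=5, size=12):
    px = np.argwhere(gt.labels == label)
    return [ROI(name, px[i * size : (i + 1) * size]) for i in range(k)]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cube, gt = render_section(SceneConfig(seed=30))

    rois = (
        granule_rois(gt, LIPOFUSCIN, "lipofuscin")
        + granule_rois(gt, MELANOLIPOFUSCIN, "melanolipofuscin")
        + granule_rois(gt, BRM, "brm")
    )
    manual = analyze_rois(cube, rois)
    auto = analyze_section(cube)

    rows = []
    for name, truth in (("lipofuscin", 575.0), ("melanolipofuscin", 578.0), ("brm", 549.0)):
        rows.append(
            {
                "component": name,
                "true_peak_nm": truth,
                "manual_roi_mean_nm": manual.class_means.get(name, float("nan")),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "component_peaks.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(
        f"automated segmentation: BrM {auto.brm_peak_nm:.2f} nm, RPE {auto.rpe_peak_nm:.2f} nm, "
        f"combined {auto.combined_peak_nm:.2f} nm"
    )
    print(f"BrM is blue-shifted vs RPE by {auto.rpe_peak_nm - auto.brm_peak_nm:.1f} nm "
          f"(generated difference: 26 nm)")


if __name__ == "__main__":
    main()
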