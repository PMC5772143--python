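#!/usr/bin/env python
"""Virtual-lesion analysis of the segmented U-bundle.

Rebuilds the ETC model on session 1 (warm-started from the stored weight
vector), removes the bundle, re-optimises the remaining path-neighbourhood
streamlines in the bundle's voxels, and compares lesioned vs unlesioned
R_rmse distributions against the held-out session 2 via the strength of
evidence S.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tractlife import io as tio
from tractlife.fascicle_eval import build_life_model, nnls_projected_gradient, virtual_lesion
from tractlife.bundle_ops import segment_by_endpoints

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    phantom = ROOT / "phantom"
    dwi1 = tio.read_volume(phantom / "dwi_session1.nii.gz")
    dwi2 = tio.read_volume(phantom / "dwi_session2.nii.gz")
    gtab = tio.read_gradient_table(phantom / "dwi")
    wm = tio.read_volume(phantom / "wm_mask.nii.gz").data.astype(bool)
    labels = tio.read_label_volume(phantom / "roi_labels.nii.gz")

    optimised = tio.read_tractogram(ROOT / "connectome" / "etc_optimised.tck")
    weights = pd.read_csv(ROOT / "connectome" / "etc_weights.tsv", sep="\t")["weight"].to_numpy()

    model = build_life_model(optimised, dwi1, gtab, wm)
    w0 = weights[weights > 0]  # optimised TCK holds the positive-weight subset
    model.weights, model.objective_history, _ = nnls_projected_gradient(
        model.M, model.y, max_iter=300, tol=1e-6, w0=w0
    )

    roi_a = labels.centers("superior_parietal_like")
    roi_b = labels.centers("supramarginal_like")
    bundle = segment_by_endpoints(optimised, roi_a, roi_b, dist_mm=3.0)

    result = virtual_lesion(model, bundle.indices, dwi1, dwi2)

    out = ROOT / "lesion"
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "n_voxels": result.n_voxels,
        "mean_R_rmse_unlesioned": float(np.mean(result.unlesioned.values)),
        "mean_R_rmse_lesioned": float(np.mean(result.lesioned.values)),
        "sd_R_rmse_unlesioned": float(np.std(result.unlesioned.values, ddof=1)),
        "sd_R_rmse_lesioned": float(np.std(result.lesioned.values, ddof=1)),
        "S": result.S,
    }
    (out / "virtual_lesion.json").write_text(json.dumps(report, indent=1))
    pd.DataFrame(
        {"unlesioned": result.unlesioned.values, "lesioned": result.lesioned.values}
    ).to_csv(out / "rrmse_per_voxel.tsv", sep="\t", index=False)

    print(f"lesion report written to {out}")
    for k, v in report.items():
        print(f"  {k}: {v:.4g}" if isinstance(v, float) else f"  {k}: {v}")


if __name__ == "__main__":
    main()
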