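#!/usr/bin/env python
"""Segment the U-bundle from the optimised ETC and map its endpoints.

Applies the endpoint rule (both terminals within 3 mm of the two grey
ROIs, pass-throughs excluded), the three outlier rules (15 mm minimum,
3 SD length, 3 SD position), then writes the bundle TCK, the endpoint
density map, and the ROI-proximity table (3 / 4.5 mm thresholds).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tractlife import io as tio
from tractlife.bundle_ops import endpoint_density, remove_outliers, roi_proximity, segment_by_endpoints

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    phantom = ROOT / "phantom"
    labels = tio.read_label_volume(phantom / "roi_labels.nii.gz")
    optimised = tio.read_tractogram(ROOT / "connectome" / "etc_optimised.tck")

    roi_a = labels.centers("superior_parietal_like")
    roi_b = labels.centers("supramarginal_like")
    bundle = segment_by_endpoints(optimised, roi_a, roi_b, dist_mm=3.0, name="u_bundle")
    n_before = len(bundle)
    bundle = remove_outliers(bundle, anchor=roi_a.mean(axis=0))

    density = endpoint_density(bundle, labels, dist_mm=3.0)
    proximity = roi_proximity(
        bundle,
        {"superior_parietal_like": roi_a, "supramarginal_like": roi_b},
        thresholds_mm=(3.0, 4.5),
    )

    out = ROOT / "bundle"
    out.mkdir(parents=True, exist_ok=True)
    tio.write_tractogram(bundle.streamlines, out / "u_bundle.tck")
    tio.write_volume(density.counts, out / "endpoint_counts.nii.gz")
    tio.write_volume(density.normalised, out / "endpoint_density_norm.nii.gz")
    prox = pd.DataFrame(proximity.as_records())
    prox.to_csv(out / "roi_proximity.tsv", sep="\t", index=False)

    lengths = bundle.streamlines.lengths()
    print(f"bundle written to {out}")
    print(f"  segmented {n_before} streamlines, {len(bundle)} after outlier removal")
    print(f"  mean length {lengths.mean() / 10:.2f} cm (SD {lengths.std(ddof=1) / 10:.2f})")
    print(prox.to_string(index=False))


if __name__ == "__main__":
    main()
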