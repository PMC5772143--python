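"""Tract segmentation by endpoint ROIs, outlier removal, endpoint maps.

A tract is segmented from a candidate tractogram as the set of streamlines
with one *terminal* point within a distance threshold (default 3 mm) of
one grey-matter ROI and the other terminal point within the threshold of
the second ROI; streamlines merely passing through an ROI do not qualify.
The segmented tract is refined by three outlier rules: minimum length
(15 mm), length more than 3 SD above the tract mean, and position more
than 3 SD from the mean tract position (computed on streamlines resampled
to 100 equidistant nodes).  All distances are Euclidean in mm between
streamline terminal points and voxel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import LabelVolume, Tractogram, Volume, resample_streamline

__all__ = [
    "TractBundle",
    "EndpointDensityMap",
    "ProximityReport",
    "segment_by_endpoints",
    "remove_outliers",
    "endpoint_density",
    "roi_proximity",
]

N_NODES = 100  # resampling nodes for the mean-position computation


@dataclass
class TractBundle:
    streamlines: Tractogram
    name: str
    indices: np.ndarray  # into the parent tractogram
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class EndpointDensityMap:
    counts: Volume  # integer endpoint counts per grey voxel
    normalised: Volume  # counts / max(counts), in [0, 1]


@dataclass
class ProximityReport:
    proportions: dict  # (roi name, threshold mm) -> proportion in [0, 1]

    def as_records(self):
        return [
            {"roi": roi, "threshold_mm": thr, "proportion": p}
            for (roi, thr), p in sorted(self.proportions.items())
        ]


def _roi_centers(roi) -> np.ndarray:
    """Accept an (n, 3) mm array or (LabelVolume, label) selection."""
    if isinstance(roi, tuple) and isinstance(roi[0], LabelVolume):
        return roi[0].centers(roi[1])
    return np.atleast_2d(np.asarray(roi, dtype=float))


def segment_by_endpoints(
    tractogram: Tractogram,
    roi_a,
    roi_b,
    dist_mm: float = 3.0,
    name: str = "bundle",
) -> TractBundle:
    """Streamlines whose two terminal points end near the two ROIs.

    ``roi_a`` / ``roi_b`` are (n, 3) mm voxel-center arrays or
    ``(LabelVolume, label)`` selections; they must be non-empty and
    disjoint.  A streamline is retained iff one terminal point is within
    ``dist_mm`` of some ROI-A voxel center and the *other* terminal point
    is within ``dist_mm`` of some ROI-B voxel center.
    """
    ca, cb = _roi_centers(roi_a), _roi_centers(roi_b)
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("ROIs must be non-empty")
    if len(ca) and len(cb):
        shared = cKDTree(ca).query_ball_tree(cKDTree(cb), r=1e-9)
        if any(shared):
            raise ValueError("ROIs must be disjoint")
    if len(tractogram) == 0:
        return TractBundle(tractogram.subset([]), name, np.empty(0, dtype=int))

    ta, tb = cKDTree(ca), cKDTree(cb)
    first = np.stack([s[0] for s in tractogram])
    last = np.stack([s[-1] for s in tractogram])
    fa = ta.query(first)[0] <= dist_mm
    la = ta.query(last)[0] <= dist_mm
    fb = tb.query(first)[0] <= dist_mm
    lb = tb.query(last)[0] <= dist_mm
    keep = (fa & lb) | (fb & la)
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        warnings.warn("segmentation produced an empty bundle", stacklevel=2)
    return TractBundle(
        streamlines=tractogram.subset(idx),
        name=name,
        indices=idx,
        params={"dist_mm": dist_mm},
    )


def _aligned_nodes(streamlines, anchor: np.ndarray | None) -> np.ndarray:
    """Resample to N_NODES and flip so corresponding nodes match ends.

    Streamlines are flipped so their first node is nearer ``anchor`` (the
    ROI-A centroid when segmentation supplies one); without an anchor the
    first streamline defines the reference orientation.
    """
    nodes = np.stack([resample_streamline(s, N_NODES) for s in streamlines])
    if anchor is not None:
        flip = np.linalg.norm(nodes[:, 0] - anchor, axis=1) > np.linalg.norm(
            nodes[:, -1] - anchor, axis=1
        )
    else:
        ref = nodes[0]
        d_keep = np.linalg.norm(nodes[:, 0] - ref[0], axis=1) + np.linalg.norm(
            nodes[:, -1] - ref[-1], axis=1
        )
        d_flip = np.linalg.norm(nodes[:, 0] - ref[-1], axis=1) + np.linalg.norm(
            nodes[:, -1] - ref[0], axis=1
        )
        flip = d_flip < d_keep
    nodes[flip] = nodes[flip, ::-1]
    return nodes


def remove_outliers(
    bundle: TractBundle,
    len_sd: float = 3.0,
    min_len_mm: float = 15.0,
    pos_sd: float = 3.0,
    anchor: np.ndarray | None = None,
) -> TractBundle:
    """Refine a bundle by the three outlier rules, applied in this order:

    1. drop streamlines shorter than ``min_len_mm``;
    2. drop streamlines longer than the (current) mean length + ``len_sd`` SD;
    3. drop streamlines whose mean node distance to the (current) mean
       streamline is >= ``pos_sd`` SD above the mean of those distances.

    Statistics are recomputed on the set entering each step.  With fewer
    than 3 streamlines the SD-based rules are skipped.
    """
    if len(bundle) == 0:
        raise ValueError("bundle is empty")
    tg = bundle.streamlines
    keep = np.arange(len(tg))

    lengths = tg.lengths()
    keep = keep[lengths[keep] >= min_len_mm]

    if len(keep) >= 3:
        l = lengths[keep]
        keep = keep[l <= l.mean() + len_sd * l.std(ddof=1)]
    elif len(keep):
        warnings.warn("fewer than 3 streamlines; SD-based outlier rules skipped", stacklevel=2)

    if len(keep) >= 3:
        nodes = _aligned_nodes([tg[i] for i in keep], anchor)
        mean_sl = nodes.mean(axis=0)
        d = np.linalg.norm(nodes - mean_sl[None], axis=2).mean(axis=1)
        keep = keep[d <= d.mean() + pos_sd * d.std(ddof=1)]

    return TractBundle(
        streamlines=tg.subset(keep),
        name=bundle.name,
        indices=bundle.indices[keep] if len(bundle.indices) else keep,
        params={**bundle.params, "len_sd": len_sd, "min_len_mm": min_len_mm, "pos_sd": pos_sd},
    )


def endpoint_density(
    bundle: TractBundle, grey: LabelVolume | np.ndarray, dist_mm: float = 3.0
) -> EndpointDensityMap:
    """Count terminal points (2 per streamline) near each grey voxel center."""
    if isinstance(grey, LabelVolume):
        grid = grey.grid
        grey_idx = np.argwhere(grey.labels > 0)
    else:
        raise TypeError("grey must be a LabelVolume")
    if len(grey_idx) == 0:
        raise ValueError("grey selection is non-empty by precondition")
    centers = grid.voxel_centers(grey_idx)
    counts = np.zeros(grid.shape, dtype=int)
    ends = bundle.streamlines.endpoints()
    if len(ends):
        tree = cKDTree(ends)
        n_near = tree.query_ball_point(centers, r=dist_mm, return_length=True)
        counts[tuple(grey_idx.T)] = n_near
    norm = counts / counts.max() if counts.max() > 0 else counts.astype(float)
    return EndpointDensityMap(
        counts=Volume(grid, counts), normalised=Volume(grid, norm.astype(float))
    )


def roi_proximity(
    bundle: TractBundle, rois: dict, thresholds_mm=(3.0, 4.5)
) -> ProximityReport:
    """Proportion of each ROI's voxel centers within threshold of any endpoint.

    ``rois`` maps name -> (n, 3) mm center array or (LabelVolume, label).
    """
    ends = bundle.streamlines.endpoints()
    tree = cKDTree(ends) if len(ends) else None
    out = {}
    for name, roi in rois.items():
        centers = _roi_centers(roi)
        if len(centers) == 0:
            raise ValueError(f"ROI {name!r} is empty")
        for thr in thresholds_mm:
            if tree is None:
                out[(name, float(thr))] = 0.0
            else:
                d, _ = tree.query(centers)
                out[(name, float(thr))] = float(np.mean(d <= thr))
    return ProximityReport(proportions=out)
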