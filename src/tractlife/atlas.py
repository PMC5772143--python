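"""Binary visitation maps and the percentage-overlap probabilistic atlas.

Each subject's tract yields a binary visitation map: a voxel is 1 iff any
streamline of the tract intersects it (streamlines are resampled to at
most half-voxel steps first so no voxels are skipped).  Per-subject maps
are normalised to a common template grid with a supplied affine
(nearest-neighbour, so maps stay binary) and averaged into a percentage
overlap atlas, optionally thresholded at strictly greater than a given
percentage of the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ImageGrid, Volume, resample_streamline

__all__ = ["VisitationMap", "OverlapAtlas", "visitation_map", "normalise_map", "percentage_overlap"]


@dataclass
class VisitationMap:
    volume: Volume  # binary
    subject_id: str = ""

    def __post_init__(self):
        vals = np.unique(self.volume.data)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("visitation map must be binary")


@dataclass
class OverlapAtlas:
    volume: Volume  # percentages in [0, 100]
    n_subjects: int
    threshold_pct: float

    def thresholded(self) -> Volume:
        """Zero voxels at or below threshold_pct (strict 'greater than')."""
        data = self.volume.data.copy()
        data[data <= self.threshold_pct] = 0.0
        return Volume(self.volume.grid, data)


def visitation_map(bundle, grid: ImageGrid, subject_id: str = "") -> VisitationMap:
    """Binary per-voxel indicator that any streamline intersects the voxel.

    ``bundle`` is a Tractogram or TractBundle.  Streamlines are resampled
    to <= half the smallest voxel dimension before nearest-voxel lookup,
    which guarantees 26-connected continuity along each path.
    """
    streamlines = getattr(bundle, "streamlines", bundle)
    data = np.zeros(grid.shape, dtype=np.uint8)
    max_step = float(grid.voxel_size.min()) / 2.0
    for s in streamlines:
        s = np.asarray(s, dtype=float)
        seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
        total = seg.sum()
        if total > 0:
            n = max(int(np.ceil(total / max_step)) + 1, len(s))
            s = resample_streamline(s, n)
        idx = grid.nearest_voxel(s)
        ok = grid.contains(idx)
        idx = idx[ok]
        if len(idx):
            data[tuple(idx.T)] = 1
    return VisitationMap(volume=Volume(grid, data), subject_id=subject_id)


def normalise_map(
    vmap: VisitationMap, affine_subject_to_template: np.ndarray, template_grid: ImageGrid
) -> VisitationMap:
    """Nearest-neighbour resampling of a binary map onto a template grid."""
    A = np.asarray(affine_subject_to_template, dtype=float)
    if A.shape != (4, 4) or abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")
    src = vmap.volume
    # template voxel center -> template mm -> subject mm -> subject voxel
    tidx = np.indices(template_grid.shape).reshape(3, -1).T.astype(float)
    t_mm = np.atleast_2d(template_grid.voxel_to_mm(tidx))
    Ainv = np.linalg.inv(A)
    s_mm = t_mm @ Ainv[:3, :3].T + Ainv[:3, 3]
    s_idx = np.rint(np.atleast_2d(src.grid.mm_to_voxel(s_mm))).astype(int)
    ok = src.grid.contains(s_idx)
    out = np.zeros(len(tidx), dtype=np.uint8)
    out[ok] = src.data[tuple(s_idx[ok].T)]
    if not out.any() and src.data.any():
        warnings.warn("normalised map is empty: source falls outside the template grid", stacklevel=2)
    return VisitationMap(
        volume=Volume(template_grid, out.reshape(template_grid.shape)),
        subject_id=vmap.subject_id,
    )


def percentage_overlap(maps: list, threshold_pct: float = 25.0) -> OverlapAtlas:
    """Per-voxel percentage of subjects whose tract visits the voxel."""
    if len(maps) == 0:
        raise ValueError("need at least one visitation map")
    grid = maps[0].volume.grid
    for m in maps[1:]:
        if m.volume.grid.shape != grid.shape or not np.allclose(
            m.volume.grid.affine, grid.affine
        ):
            raise ValueError("all maps must share one grid")
    stack = np.stack([m.volume.data for m in maps]).astype(float)
    pct = 100.0 * stack.mean(axis=0)
    return OverlapAtlas(
        volume=Volume(grid, pct), n_subjects=len(maps), threshold_pct=threshold_pct
    )
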