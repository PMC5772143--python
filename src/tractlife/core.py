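"""Spatial data model shared by every stage of the pipeline.

Conventions
-----------
* Voxel indices are 0-based and a voxel's millimetre position is the
  position of its **center** under the grid affine.
* Streamline points live in millimetre ("scanner") space, matching the
  TCK convention.
* Every RNG-dependent operation takes an explicit integer seed which is
  recorded in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GradientTable",
    "ImageGrid",
    "Volume",
    "LabelVolume",
    "Tractogram",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk file or in-memory structure violates a format contract."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion acquisition scheme: b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or 3 not in bvecs.shape:
            raise FormatError("bvecs must be an (n, 3) or (3, n) array")
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) length mismatch"
            )
        dw = bvals > 0
        if np.any(dw):
            norms = np.linalg.norm(bvecs[dw], axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-4):
                raise FormatError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3-D voxel lattice with a voxel-index -> mm affine."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise FormatError("grid shape must be 3 positive integers")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise FormatError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per axis, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (idx @ self.affine[:3, :3].T + self.affine[:3, 3]).squeeze()

    def mm_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of mm points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = self.inverse_affine
        return (pts @ inv[:3, :3].T + inv[:3, 3]).squeeze()

    def nearest_voxel(self, pts: np.ndarray) -> np.ndarray:
        return np.rint(np.atleast_2d(self.mm_to_voxel(pts))).astype(int)

    def contains(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        ok = np.ones(len(idx), dtype=bool)
        for ax in range(3):
            ok &= (idx[:, ax] >= 0) & (idx[:, ax] < self.shape[ax])
        return ok

    def voxel_centers(self, idx: np.ndarray) -> np.ndarray:
        """mm centers of the given integer voxel indices."""
        return np.atleast_2d(self.voxel_to_mm(np.asarray(idx, dtype=float)))

    @classmethod
    def isotropic(cls, shape, voxel_size_mm: float) -> "ImageGrid":
        aff = np.diag([voxel_size_mm] * 3 + [1.0])
        return cls(tuple(shape), aff)


@dataclass
class Volume:
    """Per-voxel scalar, vector, or 4th-dimension signal series on a grid."""

    grid: ImageGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape[:3] != self.grid.shape:
            raise FormatError(
                f"data leading dims {self.data.shape[:3]} != grid shape {self.grid.shape}"
            )


@dataclass
class LabelVolume:
    """Integer label volume with a label -> name map."""

    grid: ImageGrid
    labels: np.ndarray
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise FormatError("labels shape must equal grid shape")
        if np.any(self.labels < 0):
            raise FormatError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(int(k) for k in self.names)
        if missing:
            raise FormatError(f"labels {sorted(missing)} missing from names map")

    def select(self, which) -> np.ndarray:
        """Integer voxel indices (n, 3) for a label id or name."""
        if isinstance(which, str):
            matches = [k for k, v in self.names.items() if v == which]
            if not matches:
                raise KeyError(f"no label named {which!r}")
            which = matches[0]
        return np.argwhere(self.labels == int(which))

    def centers(self, which) -> np.ndarray:
        """mm centers of the voxels carrying a label."""
        return self.grid.voxel_centers(self.select(which))


@dataclass
class Tractogram:
    """Ordered 3-D point sequences in mm with generation provenance."""

    streamlines: Sequence[np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.streamlines = [np.asarray(s, dtype=float).reshape(-1, 3) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]

    def lengths(self) -> np.ndarray:
        """Arc length of each streamline in mm."""
        return np.array(
            [np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1)) for s in self.streamlines]
        )

    def subset(self, indices, **extra_provenance) -> "Tractogram":
        indices = np.asarray(indices, dtype=int)
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        prov["parent_indices"] = indices.tolist()
        return Tractogram([self.streamlines[i] for i in indices], prov)

    def endpoints(self) -> np.ndarray:
        """Terminal points, (2 * n_streamlines, 3): first and last point of each."""
        if len(self) == 0:
            return np.empty((0, 3))
        return np.concatenate(
            [np.stack([s[0], s[-1]]) for s in self.streamlines], axis=0
        )


def resample_streamline(points: np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a polyline to ``n_nodes`` equidistant (arc-length) nodes."""
    points = np.asarray(points, dtype=float)
    if len(points) == 1:
        return np.repeat(points, n_nodes, axis=0)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(points[:1], n_nodes, axis=0)
    t = np.linspace(0.0, total, n_nodes)
    return np.column_stack([np.interp(t, s, points[:, ax]) for ax in range(3)])
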