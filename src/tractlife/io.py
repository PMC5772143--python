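"""File I/O: FSL bvals/bvecs, NIfTI-1 volumes, TCK/TRK streamlines, affines.

All readers/writers are involutive round-trips at the tolerances stated in
their docstrings.  TCK is the canonical streamline format (written and
read); TRK is supported read-only.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import streamlines as nib_streamlines

from .core import FormatError, GradientTable, ImageGrid, LabelVolume, Tractogram, Volume

__all__ = [
    "read_gradient_table",
    "write_gradient_table",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "read_tractogram",
    "write_tractogram",
    "read_affine",
    "write_affine",
]


# ---------------------------------------------------------------------------
# gradient tables (FSL dialect: bvals one row, bvecs three rows)

def read_gradient_table(path) -> GradientTable:
    path = Path(path)
    bvals = np.loadtxt(str(path.with_suffix(".bvals")), ndmin=1)
    bvecs = np.loadtxt(str(path.with_suffix(".bvecs")), ndmin=2)
    if bvecs.shape[0] != 3:
        raise FormatError("bvecs file must have three rows of components")
    if bvecs.shape[1] != len(bvals):
        raise FormatError(
            f"bvals ({len(bvals)}) and bvecs ({bvecs.shape[1]}) length mismatch"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs.T)


def write_gradient_table(gtab: GradientTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(str(path.with_suffix(".bvals")), gtab.bvals[None, :], fmt="%.8g")
    np.savetxt(str(path.with_suffix(".bvecs")), gtab.bvecs.T, fmt="%.10g")


# ---------------------------------------------------------------------------
# NIfTI volumes

def _grid_from_nifti(img) -> ImageGrid:
    affine = img.affine
    if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise FormatError("NIfTI affine missing or singular")
    return ImageGrid(shape=img.shape[:3], affine=np.asarray(affine))


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    return Volume(grid=_grid_from_nifti(img), data=np.asarray(img.dataobj))


def write_volume(vol: Volume, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data)
    if data.dtype == bool:  # NIfTI has no boolean dtype
        data = data.astype(np.uint8)
    elif data.dtype in (np.int64, np.uint64):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, vol.grid.affine)
    nib.save(img, str(path))


def read_label_volume(path, names=None) -> LabelVolume:
    """Load an integer label NIfTI; ``names`` is read from a JSON sidecar if present."""
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(int)
    if names is None:
        sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json")
        if sidecar.exists():
            names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        else:
            names = {int(v): f"label_{int(v)}" for v in np.unique(labels) if v != 0}
    return LabelVolume(grid=_grid_from_nifti(img), labels=labels, names=names)


def write_label_volume(lab: LabelVolume, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(lab.labels.astype(np.int32), lab.grid.affine)
    nib.save(img, str(path))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in lab.names.items()}, indent=1))


# ---------------------------------------------------------------------------
# streamlines

def read_tractogram(path) -> Tractogram:
    """Read TCK or TRK (mm coordinates). An empty file yields an empty Tractogram."""
    tf = nib_streamlines.load(str(path))
    sls = [np.asarray(s, dtype=float) for s in tf.streamlines]
    if not sls:
        warnings.warn(f"{path}: no streamlines", stacklevel=2)
    prov = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
    return Tractogram(streamlines=sls, provenance=prov)


def write_tractogram(tg: Tractogram, path) -> None:
    """Write TCK with a JSON provenance sidecar."""
    path = Path(path)
    if path.suffix.lower() != ".tck":
        raise FormatError("streamlines are written as TCK only")
    path.parent.mkdir(parents=True, exist_ok=True)
    sls = nib_streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tg.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib_streamlines.save(sls, str(path))
    if tg.provenance:
        Path(str(path) + ".json").write_text(json.dumps(tg.provenance, indent=1, default=str))


# ---------------------------------------------------------------------------
# plain-text 4x4 affines (template normalisation inputs)

def read_affine(path) -> np.ndarray:
    aff = np.loadtxt(str(path))
    if aff.shape != (4, 4):
        raise FormatError("affine file must contain a 4x4 matrix")
    return aff


def write_affine(affine: np.ndarray, path) -> None:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise FormatError("affine must be 4x4")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(str(path), affine, fmt="%.12g")
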