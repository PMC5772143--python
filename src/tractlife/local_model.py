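"""Per-voxel orientation models: diffusion tensor and single-shell CSD.

The tensor fit is the standard log-linear least-squares fit of the
diffusion tensor to log-attenuations, yielding FA and the principal
diffusion direction (PDD).  Constrained spherical deconvolution (CSD)
estimates a fiber orientation distribution (FOD) per voxel as real
even-order spherical-harmonic coefficients (lmax = 8 by default) by
deconvolving a single-fiber response kernel with iterated soft
non-negativity constraints.  Both are invariant to global signal scaling
because they operate on attenuations relative to the mean b = 0 signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from .core import GradientTable, ImageGrid, Volume
from .harmonics import (
    convolution_factors,
    n_coeffs,
    real_sh_basis,
    sh_degrees,
    sphere_basis,
    spherical_to_cart,
    cart_to_spherical,
    rotation_to_z,
    unit_sphere,
)

__all__ = [
    "TensorVolume",
    "FODVolume",
    "PeakVolume",
    "fit_tensor",
    "estimate_response",
    "stick_response",
    "deconvolve_fod",
    "extract_peaks",
]

EPS_SIGNAL = 1e-6


@dataclass
class TensorVolume:
    grid: ImageGrid
    evals: np.ndarray  # (..., 3) descending, mm^2/s
    evecs: np.ndarray  # (..., 3, 3), evecs[..., :, i] is i-th eigenvector
    fa: np.ndarray
    mask: np.ndarray

    @property
    def pdd(self) -> np.ndarray:
        """Principal diffusion direction (first eigenvector)."""
        return self.evecs[..., :, 0]


@dataclass
class FODVolume:
    grid: ImageGrid
    coeffs: np.ndarray  # (..., n_coeffs)
    lmax: int
    mask: np.ndarray
    converged: np.ndarray | None = None

    def amplitudes(self, dirs: np.ndarray, idx) -> np.ndarray:
        """FOD amplitudes at unit vectors for a voxel index."""
        B = real_sh_basis(self.lmax, dirs)
        return B @ self.coeffs[tuple(idx)]


@dataclass
class PeakVolume:
    grid: ImageGrid
    directions: np.ndarray  # (..., max_peaks, 3)
    amplitudes: np.ndarray  # (..., max_peaks), descending, 0 = absent
    mask: np.ndarray

    def peaks_at(self, idx):
        a = self.amplitudes[tuple(idx)]
        d = self.directions[tuple(idx)]
        keep = a > 0
        return d[keep], a[keep]


# ---------------------------------------------------------------------------
# tensor


def fit_tensor(dwi: Volume, gtab: GradientTable, mask: np.ndarray | None = None) -> TensorVolume:
    """Log-linear least-squares tensor fit.

    Requires >= 6 diffusion-weighted directions.  Signals are clamped at a
    small positive epsilon before taking logs.
    """
    if int(gtab.dwi_mask.sum()) < 6:
        raise ValueError("tensor fit needs at least 6 diffusion-weighted directions")
    data = np.asarray(dwi.data, dtype=float)
    if mask is None:
        mask = np.ones(dwi.grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    b = gtab.bvals
    g = gtab.bvecs
    # design for ln S = ln S0 - b g^T D g
    X = np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones(len(b)),
        ]
    )
    pinv = np.linalg.pinv(X)

    sig = data[mask]
    s0 = sig[:, gtab.b0_mask].mean(axis=1)
    floor = EPS_SIGNAL * np.maximum(s0, 1.0)[:, None]
    logs = np.log(np.maximum(sig, floor))
    coef = logs @ pinv.T  # (n, 7)

    D = np.empty((len(coef), 3, 3))
    D[:, 0, 0] = coef[:, 0]
    D[:, 1, 1] = coef[:, 1]
    D[:, 2, 2] = coef[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = coef[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = coef[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = coef[:, 5]

    w, v = np.linalg.eigh(D)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]

    fa = fractional_anisotropy(w)

    shape = dwi.grid.shape
    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    fa_vol = np.zeros(shape)
    evals[mask] = w
    evecs[mask] = v
    fa_vol[mask] = fa
    return TensorVolume(grid=dwi.grid, evals=evals, evecs=evecs, fa=fa_vol, mask=mask)


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """Standard normalised-variance FA of eigenvalue triples (..., 3)."""
    evals = np.asarray(evals, dtype=float)
    l1, l2, l3 = evals[..., 0], evals[..., 1], evals[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5 * num / den)
    return np.clip(np.nan_to_num(fa), 0.0, 1.0)


# ---------------------------------------------------------------------------
# single-fiber response


def _attenuations(data, gtab):
    s0 = data[..., gtab.b0_mask].mean(axis=-1)
    s0 = np.maximum(s0, EPS_SIGNAL)
    return data[..., gtab.dwi_mask] / s0[..., None]


def stick_response(
    gtab: GradientTable, lmax: int = 8, d_axial: float = 1.7e-3, d_radial: float = 0.2e-3
) -> np.ndarray:
    """Analytic zonal response of a single stick/tensor compartment.

    Returns one zonal SH coefficient per even l, obtained by Gauss-Legendre
    projection of exp(-b (d_r + (d_a - d_r) cos^2 theta)) onto Y_l0.
    """
    b = float(gtab.bvals[gtab.dwi_mask].mean())
    x, w = np.polynomial.legendre.leggauss(64)  # x = cos(theta)
    att = np.exp(-b * (d_radial + (d_axial - d_radial) * x**2))
    theta = np.arccos(x)
    dirs = spherical_to_cart(theta, np.zeros_like(theta))
    B = real_sh_basis(lmax, dirs)
    # zonal (m = 0) column index for degree l: offset of block l plus l
    idx = []
    off = 0
    for l in range(0, lmax + 1, 2):
        idx.append(off + l)
        off += 2 * l + 1
    Y0 = B[:, idx]  # (64, n_l)
    return 2.0 * np.pi * (w[:, None] * att[:, None] * Y0).sum(axis=0)


def estimate_response(
    dwi: Volume,
    gtab: GradientTable,
    tensor: TensorVolume,
    fa_threshold: float = 0.7,
    lmax: int = 8,
    min_voxels: int = 20,
) -> np.ndarray:
    """Single-fiber response from high-FA voxels (zonal SH coefficients).

    Each high-FA voxel's attenuation profile is rotated so its PDD aligns
    with +z and projected onto the zonal (m = 0) even SH basis; the response
    is the mean over voxels.  With fewer than ``min_voxels`` candidates the
    analytic stick response is returned with a warning.
    """
    sel = tensor.mask & (tensor.fa >= fa_threshold)
    n = int(sel.sum())
    if n < min_voxels:
        warnings.warn(
            f"only {n} voxels above FA {fa_threshold}; falling back to analytic stick response",
            stacklevel=2,
        )
        return stick_response(gtab, lmax=lmax)

    data = np.asarray(dwi.data, dtype=float)
    att = _attenuations(data, gtab)[sel]  # (n, n_dw)
    pdds = tensor.pdd[sel]
    gdirs = gtab.bvecs[gtab.dwi_mask]

    idx = []
    off = 0
    for l in range(0, lmax + 1, 2):
        idx.append(off + l)
        off += 2 * l + 1

    coefs = np.empty((n, len(idx)))
    for i in range(n):
        Rm = rotation_to_z(pdds[i])
        rot = gdirs @ Rm.T
        B = real_sh_basis(lmax, rot)[:, idx]
        coefs[i], *_ = np.linalg.lstsq(B, att[i], rcond=None)
    return coefs.mean(axis=0)


# ---------------------------------------------------------------------------
# constrained spherical deconvolution


def deconvolve_fod(
    dwi: Volume,
    gtab: GradientTable,
    response: np.ndarray,
    lmax: int = 8,
    mask: np.ndarray | None = None,
    reg_lambda: float = 1.0,
    tau: float = 0.1,
    max_iter: int = 50,
) -> FODVolume:
    """Single-shell CSD with iterated soft non-negativity constraints.

    Per voxel, solves  min ||A f - s||^2 + lambda^2 ||B_neg f||^2  where A
    is the SH forward-convolution matrix evaluated at the gradient
    directions and B_neg collects dense-sphere rows whose current FOD
    amplitude falls below ``tau`` x (mean initial amplitude).  Iteration
    stops when the constraint set is stable or after ``max_iter`` rounds;
    non-converged voxels are flagged, not discarded.
    """
    if lmax % 2:
        raise ValueError("lmax must be even")
    grid = dwi.grid
    data = np.asarray(dwi.data, dtype=float)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    att = _attenuations(data, gtab)[mask]  # (n_vox, n_dw)
    gdirs = gtab.bvecs[gtab.dwi_mask]

    nc = n_coeffs(lmax)
    k = convolution_factors(response, lmax)  # (nc,)
    A = real_sh_basis(lmax, gdirs) * k[None, :]  # (n_dw, nc)
    Bs = sphere_basis(lmax)  # (724, nc)

    AtA = A.T @ A
    lam2 = reg_lambda**2

    # initialisation: ridge-regularised unconstrained solution
    init_solver = np.linalg.solve(AtA + 1e-3 * np.trace(AtA) / nc * np.eye(nc), A.T)

    n_vox = att.shape[0]
    coeffs = np.zeros((n_vox, nc))
    converged = np.zeros(n_vox, dtype=bool)
    for v in range(n_vox):
        s = att[v]
        f = init_solver @ s
        amp = Bs @ f
        thr = tau * max(amp.mean(), 0.0)
        Aty = A.T @ s
        prev_neg = None
        ok = False
        for _ in range(max_iter):
            neg = amp < thr
            if prev_neg is not None and np.array_equal(neg, prev_neg):
                ok = True
                break
            prev_neg = neg
            Bn = Bs[neg]
            H = AtA + lam2 * (Bn.T @ Bn)
            try:
                f = np.linalg.solve(H, Aty)
            except np.linalg.LinAlgError:
                f = np.linalg.lstsq(H, Aty, rcond=None)[0]
            amp = Bs @ f
        coeffs[v] = f
        converged[v] = ok
    if not converged.all():
        warnings.warn(
            f"CSD constraint set did not stabilise in {max_iter} iterations for "
            f"{int((~converged).sum())} voxels; last iterate kept",
            stacklevel=2,
        )

    out = np.zeros(grid.shape + (nc,))
    out[mask] = coeffs
    conv = np.zeros(grid.shape, dtype=bool)
    conv[mask] = converged
    return FODVolume(grid=grid, coeffs=out, lmax=lmax, mask=mask, converged=conv)


# ---------------------------------------------------------------------------
# peak extraction


def _canonical(d: np.ndarray) -> np.ndarray:
    """Antipodal canonicalisation: first nonzero component >= 0."""
    for c in d:
        if c > 1e-12:
            return d
        if c < -1e-12:
            return -d
    return d


@lru_cache(maxsize=4)
def _neighbour_table(cap_deg: float = 16.0):
    """Padded neighbour-index table on the default sphere for maximum tests."""
    dirs = unit_sphere()
    cos_nb = np.cos(np.deg2rad(cap_deg))
    dot = dirs @ np.asarray(dirs).T
    lists = [np.flatnonzero((dot[i] >= cos_nb) & (dot[i] < 1 - 1e-12)) for i in range(len(dirs))]
    width = max(len(l) for l in lists)
    table = np.full((len(dirs), width), -1, dtype=int)
    for i, l in enumerate(lists):
        table[i, : len(l)] = l
    return table


def _cap_grid(d0: np.ndarray, radius_rad: float, n_ring: int = 8, n_r: int = 4) -> np.ndarray:
    """Unit vectors covering a spherical cap around d0."""
    R = rotation_to_z(d0).T  # maps +z to d0
    rr = np.linspace(radius_rad / n_r, radius_rad, n_r)
    ph = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    theta = np.repeat(rr, n_ring)
    phi = np.tile(ph, n_r)
    local = spherical_to_cart(theta, phi)
    return np.vstack([d0, local @ R.T])


def _refine_peak(f: np.ndarray, lmax: int, d0: np.ndarray, levels=(8.0, 2.0, 0.5, 0.125)):
    """Hierarchical cap-grid ascent of the FOD amplitude from a seed direction."""
    d = d0
    a = float((real_sh_basis(lmax, d[None]) @ f)[0])
    for deg in levels:
        grid = _cap_grid(d, np.deg2rad(deg))
        amps = real_sh_basis(lmax, grid) @ f
        j = int(np.argmax(amps))
        d, a = grid[j], float(amps[j])
    return d / np.linalg.norm(d), a


def extract_peaks(
    fod: FODVolume,
    max_peaks: int = 3,
    min_relative_amplitude: float = 0.1,
    min_separation_deg: float = 25.0,
) -> PeakVolume:
    """FOD local maxima over the dense sphere refined by hierarchical ascent.

    Peaks closer than ``min_separation_deg`` are merged keeping the larger;
    peaks below ``min_relative_amplitude`` x the largest are dropped.
    """
    dirs = unit_sphere()
    Bs = sphere_basis(fod.lmax)
    nb = _neighbour_table()

    shape = fod.grid.shape
    directions = np.zeros(shape + (max_peaks, 3))
    amplitudes = np.zeros(shape + (max_peaks,))

    cos_sep = np.cos(np.deg2rad(min_separation_deg))
    vox = np.argwhere(fod.mask)
    for ijk in vox:
        f = fod.coeffs[tuple(ijk)]
        if not np.any(f):
            continue
        amp = Bs @ f
        if amp.max() <= 0:
            continue
        amp_nb = np.where(nb >= 0, amp[nb], -np.inf)
        cand = np.flatnonzero((amp > 0) & (amp >= amp_nb.max(axis=1)))
        refined = []
        for i in cand:
            d, a = _refine_peak(f, fod.lmax, np.asarray(dirs[i]))
            refined.append((_canonical(d), a))
        # merge antipodal/nearby duplicates, keep larger
        refined.sort(key=lambda t: -t[1])
        kept = []
        for d, a in refined:
            if any(abs(d @ kd) >= cos_sep for kd, _ in kept):
                continue
            kept.append((d, a))
        if not kept:
            continue
        a_max = kept[0][1]
        kept = [(d, a) for d, a in kept if a >= min_relative_amplitude * a_max][:max_peaks]
        for p, (d, a) in enumerate(kept):
            directions[tuple(ijk)][p] = d
            amplitudes[tuple(ijk)][p] = a
    return PeakVolume(grid=fod.grid, directions=directions, amplitudes=amplitudes, mask=fod.mask)
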