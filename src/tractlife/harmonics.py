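"""Real even-order spherical harmonics and unit-sphere sample sets.

Basis convention (fixed across the package): real, orthonormal, even orders
only, coefficients ordered as (l, m) with l = 0, 2, ..., lmax and, within
each l, m = -l, ..., l.  For lmax even the coefficient count is
(lmax + 1)(lmax + 2) / 2.  Antipodal symmetry is built in: only even l
appear, so every represented function satisfies f(-u) = f(u).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "n_coeffs",
    "sh_degrees",
    "real_sh_basis",
    "unit_sphere",
    "cart_to_spherical",
    "spherical_to_cart",
    "convolution_factors",
    "rotation_to_z",
]


def n_coeffs(lmax: int) -> int:
    if lmax % 2:
        raise ValueError("lmax must be even")
    return (lmax + 1) * (lmax + 2) // 2


def sh_degrees(lmax: int) -> np.ndarray:
    """Degree l of each coefficient in the package ordering."""
    ls = []
    for l in range(0, lmax + 1, 2):
        ls.extend([l] * (2 * l + 1))
    return np.array(ls, dtype=int)


def cart_to_spherical(dirs: np.ndarray):
    """Unit vectors -> (polar theta in [0, pi], azimuth phi in [-pi, pi])."""
    dirs = np.atleast_2d(dirs)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    return theta, phi


def spherical_to_cart(theta, phi) -> np.ndarray:
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def real_sh_basis(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the real even SH basis at unit vectors; shape (n_dirs, n_coeffs)."""
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    theta, phi = cart_to_spherical(dirs)
    cols = []
    for l in range(0, lmax + 1, 2):
        # complex Y_l^m for m = 0..l; scipy's sph_harm_y(l, m, polar, azimuth)
        for m in range(-l, l + 1):
            am = abs(m)
            y = sph_harm_y(l, am, theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** am * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** am * y.real)
    return np.column_stack(cols)


@lru_cache(maxsize=8)
def unit_sphere(n_hemi: int = 362):
    """Antipodally symmetric sphere sample: ``2 * n_hemi`` unit vectors.

    Points are a Fibonacci spiral over the upper hemisphere followed by
    their antipodes, so ``antipode(i) = (i + n_hemi) % (2 n_hemi)``.
    """
    i = np.arange(n_hemi)
    z = (i + 0.5) / n_hemi  # (0, 1): strictly upper hemisphere
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(1.0 - z**2)
    upper = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs = np.vstack([upper, -upper])
    dirs.setflags(write=False)
    return dirs


@lru_cache(maxsize=32)
def sphere_basis(lmax: int, n_hemi: int = 362) -> np.ndarray:
    """Cached SH basis matrix on the default sphere sample."""
    b = real_sh_basis(lmax, unit_sphere(n_hemi))
    b.setflags(write=False)
    return b


def convolution_factors(response_zonal: np.ndarray, lmax: int) -> np.ndarray:
    """Per-coefficient factors turning FOD SH coeffs into signal SH coeffs.

    For an axially symmetric kernel with zonal coefficients r_l (one per even
    l), spherical convolution multiplies each (l, m) coefficient by
    sqrt(4 pi / (2l + 1)) * r_l  (Funk-Hecke).
    """
    ls = sh_degrees(lmax)
    r_per_l = {l: response_zonal[k] for k, l in enumerate(range(0, lmax + 1, 2))}
    return np.array([np.sqrt(4.0 * np.pi / (2 * l + 1)) * r_per_l[l] for l in ls])


def rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ v = +z (v a unit vector)."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(v @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)
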