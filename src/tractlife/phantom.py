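"""Synthetic two-session diffusion phantom.

The phantom emulates the statistical structure the downstream analysis
assumes: a curved U-shaped white-matter bundle whose two ends terminate
underneath two cortical grey-matter ROI patches (the analog of a short
association tract wrapping around a sulcus), a straight distractor bundle
crossing the U-bundle's apex at ~90 degrees, isotropic background, Rician
noise, and a repeated (two-session) single-shell acquisition: 64 gradient
directions at b = 1000 s/mm^2 plus two b = 0 volumes, 2-mm isotropic voxels.

The noiseless forward model in a voxel with orientations t_k and volume
fractions f_k is the standard multi-compartment stick/tensor model

    S(theta, b) = s0 * [ f_iso exp(-b d_iso)
                         + sum_k f_k exp(-b (d_r + (d_a - d_r)(theta . t_k)^2)) ]

with f_iso = 1 - sum_k f_k.  Rician noise of scale sigma is applied
independently per session; both sessions share the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import GradientTable, ImageGrid, LabelVolume, Volume, resample_streamline

__all__ = [
    "BundleGeometry",
    "PhantomSpec",
    "PhantomTruth",
    "default_gradient_table",
    "make_u_bundle_spec",
    "generate_phantom",
]

# typical white matter / CSF diffusivities (mm^2/s)
D_AXIAL = 1.7e-3
D_RADIAL = 0.2e-3
D_ISO = 3.0e-3
S0 = 100.0


class ConfigurationError(ValueError):
    """Phantom geometry does not fit the requested grid."""


@dataclass
class BundleGeometry:
    """A tube around a centerline polyline (mm)."""

    name: str
    centerline: np.ndarray  # (n, 3) control points, mm
    radius: float  # mm
    volume_fraction: float = 1.0

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if len(self.centerline) < 3:
            raise ValueError("centerline needs >= 3 control points")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0 < self.volume_fraction <= 1:
            raise ValueError("volume_fraction must be in (0, 1]")
        if self.arc_length() < 4 * self.radius:
            raise ValueError("centerline arc length must be >= 4 x radius")

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))

    def dense(self, spacing_mm: float = 0.25) -> np.ndarray:
        n = max(int(np.ceil(self.arc_length() / spacing_mm)) + 1, 2)
        return resample_streamline(self.centerline, n)


@dataclass
class PhantomSpec:
    grid: ImageGrid
    bundles: List[BundleGeometry]
    gtab: GradientTable
    s0: float = S0
    d_axial: float = D_AXIAL
    d_radial: float = D_RADIAL
    d_iso: float = D_ISO
    noise_sigma: float = 2.0
    n_sessions: int = 2
    seed: int = 0
    roi_centers: dict = field(default_factory=dict)  # name -> (center mm, radius mm)
    jitter_mm: tuple = (0.0, 0.0, 0.0)  # rigid offset of the whole assembly

    def __post_init__(self):
        if not self.d_axial > self.d_radial >= 0:
            raise ValueError("require d_axial > d_radial >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


@dataclass
class PhantomTruth:
    """Ground truth: per-voxel orientations/fractions, masks and ROI labels."""

    grid: ImageGrid
    bundle_names: List[str]
    fractions: np.ndarray  # (n_bundles, nx, ny, nz)
    orientations: np.ndarray  # (n_bundles, nx, ny, nz, 3) unit tangents (0 outside)
    wm_mask: Volume
    gwmi_mask: Volume
    roi_labels: LabelVolume

    def orientations_at(self, idx) -> list:
        """[(unit vector, fraction), ...] for one voxel index."""
        i, j, k = idx
        out = []
        for b in range(len(self.bundle_names)):
            f = float(self.fractions[b, i, j, k])
            if f > 0:
                out.append((self.orientations[b, i, j, k].copy(), f))
        return out


def default_gradient_table(n_dirs: int = 64, b: float = 1000.0, n_b0: int = 2) -> GradientTable:
    """Single-shell scheme: ``n_b0`` b=0 volumes then ``n_dirs`` directions."""
    i = np.arange(n_dirs)
    z = (i + 0.5) / n_dirs
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def make_u_bundle_spec(
    grid_shape: Sequence[int] = (30, 30, 30),
    seed: int = 0,
    voxel_size: float = 2.0,
    noise_sigma: float = 2.0,
    n_sessions: int = 2,
    include_u_bundle: bool = True,
) -> PhantomSpec:
    """Default phantom: U-bundle between ROI-A and ROI-B plus a crossing distractor.

    The U-bundle is a semicircular arc (radius 15 mm, hence ~47 mm of arc)
    with short straight extensions toward the grey-matter patches, so its
    total centerline length (~53 mm) is close to the ~47 mm mean length
    reported for the tract it emulates.  ``include_u_bundle=False`` builds
    the negative-control phantom (distractor and ROIs only).

    A small per-seed rigid jitter (< 1.5 mm) displaces the whole assembly to
    emulate between-subject anatomical variability.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if any(s < 20 for s in grid_shape):
        raise ConfigurationError("grid_shape must be >= 20 voxels per axis")
    grid = ImageGrid.isotropic(grid_shape, voxel_size)
    extent = (np.array(grid_shape) - 1) * voxel_size
    center = extent / 2.0

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-1.5, 1.5, size=3)

    R = 15.0
    tube = 3.0
    cU = center + np.array([0.0, 0.0, -11.0]) + jitter

    # fit check: bounding box of arc + tubes + grey patches
    half_span = R + tube + 1.0
    lo = cU - np.array([half_span, half_span, 19.0 + 5.0])
    hi = cU + np.array([half_span, half_span, R + tube + 1.0])
    if np.any(lo < -voxel_size) and np.any(hi > extent + voxel_size):
        raise ConfigurationError("grid too small to contain the bundle geometry")

    bundles = []
    if include_u_bundle:
        phi = np.linspace(0.0, np.pi, 73)
        arc = cU + np.column_stack(
            [R * np.cos(phi), np.zeros_like(phi), R * np.sin(phi)]
        )
        ext_a = cU + np.array([[R, 0, -1.5], [R, 0, -3.0]])
        ext_b = cU + np.array([[-R, 0, -1.5], [-R, 0, -3.0]])
        centerline = np.vstack([ext_a[::-1], arc, ext_b])
        bundles.append(BundleGeometry("u_bundle", centerline, radius=tube))

    apex_z = cU[2] + R
    y0, y1 = cU[1] - 24.0, cU[1] + 24.0
    straight = np.column_stack(
        [
            np.full(49, cU[0]),
            np.linspace(y0, y1, 49),
            np.full(49, apex_z),
        ]
    )
    bundles.append(BundleGeometry("distractor", straight, radius=tube))

    roi_centers = {
        "superior_parietal_like": (cU + np.array([R, 0.0, -8.0]), 5.0),
        "supramarginal_like": (cU + np.array([-R, 0.0, -8.0]), 5.0),
        "distractor_a": (np.array([cU[0], y0 - 2.0, apex_z]), 5.0),
        "distractor_b": (np.array([cU[0], y1 + 2.0, apex_z]), 5.0),
    }

    return PhantomSpec(
        grid=grid,
        bundles=bundles,
        gtab=default_gradient_table(),
        noise_sigma=noise_sigma,
        n_sessions=n_sessions,
        seed=seed,
        roi_centers=roi_centers,
        jitter_mm=tuple(jitter),
    )


_ROI_LABELS = {
    "superior_parietal_like": 1,
    "supramarginal_like": 2,
    "distractor_a": 3,
    "distractor_b": 4,
}


def _tube_occupancy(grid: ImageGrid, bundle: BundleGeometry) -> np.ndarray:
    """Fraction of 27 within-voxel subsamples inside the bundle tube."""
    dense = bundle.dense()
    tree = cKDTree(dense)
    vs = grid.voxel_size
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    centers = np.atleast_2d(grid.voxel_to_mm(idx))

    # cheap prefilter: only voxels whose center is within radius + half-diagonal
    half_diag = float(np.linalg.norm(vs)) / 2.0
    d_center, _ = tree.query(centers, workers=-1)
    cand = np.flatnonzero(d_center <= bundle.radius + half_diag)

    occ = np.zeros(len(centers))
    if len(cand):
        offsets = np.array(
            np.meshgrid(*[[-1 / 3, 0, 1 / 3]] * 3, indexing="ij")
        ).reshape(3, -1).T * vs
        sub = centers[cand][:, None, :] + offsets[None, :, :]
        d, _ = tree.query(sub.reshape(-1, 3), workers=-1)
        inside = (d.reshape(len(cand), 27) <= bundle.radius)
        occ[cand] = inside.mean(axis=1)
    return occ.reshape(grid.shape)


def _tangent_field(grid: ImageGrid, bundle: BundleGeometry, mask: np.ndarray) -> np.ndarray:
    dense = bundle.dense()
    tang = np.gradient(dense, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    tree = cKDTree(dense)
    field = np.zeros(grid.shape + (3,))
    vox = np.argwhere(mask)
    if len(vox):
        centers = grid.voxel_centers(vox)
        _, nearest = tree.query(centers, workers=-1)
        field[tuple(vox.T)] = tang[nearest]
    return field


def _build_truth(spec: PhantomSpec) -> PhantomTruth:
    grid = spec.grid
    nb = len(spec.bundles)
    fractions = np.zeros((nb,) + grid.shape)
    orientations = np.zeros((nb,) + grid.shape + (3,))
    for b, bundle in enumerate(spec.bundles):
        occ = _tube_occupancy(grid, bundle) * bundle.volume_fraction
        fractions[b] = occ
        orientations[b] = _tangent_field(grid, bundle, occ > 0)

    total = fractions.sum(axis=0)
    over = total > 1.0
    if np.any(over):
        fractions[:, over] /= total[over]

    wm = total > 0

    # grey-matter ROI patches; white matter wins where the ball overlaps the tube
    labels = np.zeros(grid.shape, dtype=int)
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = np.atleast_2d(grid.voxel_to_mm(idx.astype(float)))
    for name, (c, r) in spec.roi_centers.items():
        inside = np.linalg.norm(centers - c, axis=1) <= r
        ball = inside.reshape(grid.shape) & ~wm
        labels[ball] = _ROI_LABELS[name]
    grey = labels > 0

    # GWMI seed mask: white-matter voxels 6-adjacent to any grey voxel
    gwmi = np.zeros_like(wm)
    for ax in range(3):
        for sh in (1, -1):
            gwmi |= wm & np.roll(grey, sh, axis=ax)
    # roll wraps around the grid edge; drop any wrapped faces
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        gwmi[tuple(sl)] &= wm[tuple(sl)]

    names = {v: k for k, v in _ROI_LABELS.items() if v in np.unique(labels)}
    return PhantomTruth(
        grid=grid,
        bundle_names=[b.name for b in spec.bundles],
        fractions=fractions,
        orientations=orientations,
        wm_mask=Volume(grid, wm),
        gwmi_mask=Volume(grid, gwmi),
        roi_labels=LabelVolume(grid, labels, names),
    )


def noiseless_signal(spec: PhantomSpec, truth: PhantomTruth) -> np.ndarray:
    """Noise-free 4-D signal array (nx, ny, nz, n_meas)."""
    gtab = spec.gtab
    b = gtab.bvals
    G = gtab.bvecs
    n_meas = len(gtab)
    shape = spec.grid.shape

    iso = np.exp(-b * spec.d_iso)  # (n_meas,)
    f_sum = truth.fractions.sum(axis=0)
    signal = (1.0 - f_sum)[..., None] * iso[None, None, None, :]

    for bi in range(len(spec.bundles)):
        mask = truth.fractions[bi] > 0
        if not np.any(mask):
            continue
        t = truth.orientations[bi][mask]  # (n, 3)
        f = truth.fractions[bi][mask]  # (n,)
        ct2 = (G @ t.T) ** 2  # (n_meas, n)
        att = np.exp(-b[:, None] * (spec.d_radial + (spec.d_axial - spec.d_radial) * ct2))
        signal[mask] += f[:, None] * att.T
    return spec.s0 * signal


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MR noise: two independent Gaussian channels added in quadrature."""
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def generate_phantom(spec: PhantomSpec):
    """Synthesize one 4-D volume per session plus the shared ground truth."""
    if spec.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    truth = _build_truth(spec)
    clean = noiseless_signal(spec, truth)
    rng = np.random.default_rng(spec.seed)
    sessions = []
    for _ in range(spec.n_sessions):
        noisy = add_rician_noise(clean, spec.noise_sigma, rng)
        sessions.append(Volume(spec.grid, noisy))
    return sessions, truth
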