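"""Probabilistic streamline tractography on FOD volumes.

Streamlines grow bidirectionally from uniformly sampled points inside
randomly selected seed voxels.  At every step the next direction is drawn
categorically from the FOD amplitudes (trilinearly interpolated SH
coefficients) over a fixed antipodally symmetric sphere sample, restricted
to the cone of ``angular_threshold`` degrees around the incoming direction;
the first step at a seed draws from the full sphere.  A half terminates
when the proposed point leaves the white-matter mask (the exiting point is
kept, so endpoints reach toward grey matter), when no candidate direction
reaches the FOD amplitude stopping criterion, or at the length cap.
Streamlines shorter than the minimum length are discarded.

The stepping loop is compiled with numba; identical seeds give bit-identical
streamlines.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from functools import lru_cache
import warnings

import numba
import numpy as np

from .core import ImageGrid, Tractogram
from .harmonics import sphere_basis, unit_sphere
from .local_model import FODVolume, PeakVolume

__all__ = ["TrackingParams", "track", "generate_ensemble", "DEFAULT_ANGULAR_THRESHOLDS"]

# the four curvature settings of the ensemble
DEFAULT_ANGULAR_THRESHOLDS = (5.7, 11.5, 23.1, 47.2)


@dataclass
class TrackingParams:
    step_size: float = 0.2  # mm
    angular_threshold: float = 47.2  # degrees per step
    stop_amplitude: float = 0.1  # FOD amplitude stopping criterion
    min_length: float = 10.0  # mm
    max_length: float = 200.0  # mm
    n_streamlines: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0 < self.angular_threshold <= 90:
            raise ValueError("angular_threshold must be in (0, 90] degrees")
        if not self.min_length < self.max_length:
            raise ValueError("min_length must be < max_length")


@lru_cache(maxsize=16)
def _cone_table(cos_thresh_key: float):
    """Flat candidate-index table: cone of sphere dirs around each sphere dir."""
    dirs = np.asarray(unit_sphere())
    dot = dirs @ dirs.T
    offsets = [0]
    idx = []
    for i in range(len(dirs)):
        members = np.flatnonzero(dot[i] >= cos_thresh_key)
        idx.extend(members.tolist())
        offsets.append(len(idx))
    return np.asarray(idx, dtype=np.int32), np.asarray(offsets, dtype=np.int64)


@numba.njit(cache=True)
def _interp_coeffs(coeffs, x, y, z, out):
    nx, ny, nz, nc = coeffs.shape
    i0 = int(np.floor(x))
    j0 = int(np.floor(y))
    k0 = int(np.floor(z))
    fx = x - i0
    fy = y - j0
    fz = z - k0
    for c in range(nc):
        out[c] = 0.0
    for di in range(2):
        wi = fx if di else 1.0 - fx
        ii = i0 + di
        if ii < 0 or ii >= nx or wi == 0.0:
            continue
        for dj in range(2):
            wj = fy if dj else 1.0 - fy
            jj = j0 + dj
            if jj < 0 or jj >= ny or wj == 0.0:
                continue
            for dk in range(2):
                wk = fz if dk else 1.0 - fz
                kk = k0 + dk
                if kk < 0 or kk >= nz or wk == 0.0:
                    continue
                w = wi * wj * wk
                for c in range(nc):
                    out[c] += w * coeffs[ii, jj, kk, c]


@numba.njit(cache=True)
def _sample_direction(coeffs, B, cone_idx, cone_off, cur_dir, vx, vy, vz, stop_amp, fbuf):
    """Draw a direction index from FOD amplitudes within the cone of cur_dir.

    cur_dir == -1 means the full sphere (first step).  Returns -1 when no
    candidate reaches stop_amp.
    """
    _interp_coeffs(coeffs, vx, vy, vz, fbuf)
    if cur_dir < 0:
        lo, hi = 0, B.shape[0]
    else:
        lo = cone_off[cur_dir]
        hi = cone_off[cur_dir + 1]
    n = hi - lo
    amps = np.empty(n, dtype=np.float64)
    total = 0.0
    for q in range(n):
        d = cone_idx[q + lo] if cur_dir >= 0 else q
        a = 0.0
        for c in range(B.shape[1]):
            a += B[d, c] * fbuf[c]
        if a < stop_amp:
            a = 0.0
        amps[q] = a
        total += a
    if total <= 0.0:
        return -1
    r = np.random.random() * total
    acc = 0.0
    for q in range(n):
        acc += amps[q]
        if r <= acc:
            return cone_idx[q + lo] if cur_dir >= 0 else q
    # numerical fallthrough: last positive candidate
    for q in range(n - 1, -1, -1):
        if amps[q] > 0:
            return cone_idx[q + lo] if cur_dir >= 0 else q
    return -1


@numba.njit(cache=True)
def _track_kernel(
    coeffs,
    B,
    dirs,
    cone_idx,
    cone_off,
    wm,
    inv3,
    invt,
    seeds,
    step,
    stop_amp,
    max_steps_half,
    rng_seed,
    points,
    n_back,
    n_fwd,
):
    np.random.seed(rng_seed)
    n_seeds = seeds.shape[0]
    nc = coeffs.shape[3]
    nd = dirs.shape[0]
    nh = nd // 2
    fbuf = np.empty(nc, dtype=np.float32)
    mid = max_steps_half  # seed point slot
    for s in range(n_seeds):
        px, py, pz = seeds[s, 0], seeds[s, 1], seeds[s, 2]
        vx = inv3[0, 0] * px + inv3[0, 1] * py + inv3[0, 2] * pz + invt[0]
        vy = inv3[1, 0] * px + inv3[1, 1] * py + inv3[1, 2] * pz + invt[1]
        vz = inv3[2, 0] * px + inv3[2, 1] * py + inv3[2, 2] * pz + invt[2]
        d0 = _sample_direction(coeffs, B, cone_idx, cone_off, -1, vx, vy, vz, stop_amp, fbuf)
        points[s, mid, 0] = px
        points[s, mid, 1] = py
        points[s, mid, 2] = pz
        n_back[s] = 0
        n_fwd[s] = 0
        if d0 < 0:
            continue
        for half in range(2):
            if half == 0:
                cur_dir = d0
                sign = 1
            else:
                cur_dir = (d0 + nh) % nd
                sign = -1
            cx, cy, cz = px, py, pz
            count = 0
            for _ in range(max_steps_half):
                nxp = cx + step * dirs[cur_dir, 0]
                nyp = cy + step * dirs[cur_dir, 1]
                nzp = cz + step * dirs[cur_dir, 2]
                vx = inv3[0, 0] * nxp + inv3[0, 1] * nyp + inv3[0, 2] * nzp + invt[0]
                vy = inv3[1, 0] * nxp + inv3[1, 1] * nyp + inv3[1, 2] * nzp + invt[1]
                vz = inv3[2, 0] * nxp + inv3[2, 1] * nyp + inv3[2, 2] * nzp + invt[2]
                ii = int(np.floor(vx + 0.5))
                jj = int(np.floor(vy + 0.5))
                kk = int(np.floor(vz + 0.5))
                outside = (
                    ii < 0
                    or jj < 0
                    or kk < 0
                    or ii >= wm.shape[0]
                    or jj >= wm.shape[1]
                    or kk >= wm.shape[2]
                    or wm[ii, jj, kk] == 0
                )
                count += 1
                slot = mid + sign * count
                points[s, slot, 0] = nxp
                points[s, slot, 1] = nyp
                points[s, slot, 2] = nzp
                if outside:
                    break
                nd_next = _sample_direction(
                    coeffs, B, cone_idx, cone_off, cur_dir, vx, vy, vz, stop_amp, fbuf
                )
                if nd_next < 0:
                    break
                cur_dir = nd_next
                cx, cy, cz = nxp, nyp, nzp
            if half == 0:
                n_fwd[s] = count
            else:
                n_back[s] = count


def _sample_seed_points(grid: ImageGrid, seed_mask: np.ndarray, n: int, rng) -> np.ndarray:
    vox = np.argwhere(seed_mask)
    if len(vox) == 0:
        raise ValueError("empty seed mask")
    pick = vox[rng.integers(0, len(vox), size=n)]
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
    return np.atleast_2d(grid.voxel_to_mm(pick + jitter))


def track(fod, seed_mask: np.ndarray, wm_mask: np.ndarray, params: TrackingParams) -> Tractogram:
    """Generate a probabilistic tractogram from an FOD (or peak) volume."""
    if isinstance(fod, PeakVolume):
        return _track_peaks(fod, seed_mask, wm_mask, params)
    if not isinstance(fod, FODVolume):
        raise TypeError("track expects an FODVolume or PeakVolume")

    grid = fod.grid
    rng = np.random.default_rng(params.seed)
    seeds = _sample_seed_points(grid, np.asarray(seed_mask, dtype=bool), params.n_streamlines, rng)

    dirs = np.asarray(unit_sphere(), dtype=np.float32)
    B = np.asarray(sphere_basis(fod.lmax), dtype=np.float32)
    cos_t = float(np.cos(np.deg2rad(params.angular_threshold)))
    cone_idx, cone_off = _cone_table(round(cos_t, 12))

    coeffs = np.ascontiguousarray(fod.coeffs, dtype=np.float32)
    wm = np.ascontiguousarray(np.asarray(wm_mask, dtype=np.uint8))
    inv = grid.inverse_affine
    inv3 = np.ascontiguousarray(inv[:3, :3], dtype=np.float64)
    invt = np.ascontiguousarray(inv[:3, 3], dtype=np.float64)

    max_steps_half = int(np.floor(params.max_length / params.step_size / 2.0))
    streamlines = []
    chunk = 1024
    min_pts = int(np.ceil(params.min_length / params.step_size)) + 1
    for c0 in range(0, len(seeds), chunk):
        sub = np.ascontiguousarray(seeds[c0 : c0 + chunk], dtype=np.float64)
        n = len(sub)
        pts = np.empty((n, 2 * max_steps_half + 1, 3), dtype=np.float64)
        n_back = np.zeros(n, dtype=np.int64)
        n_fwd = np.zeros(n, dtype=np.int64)
        kseed = int((params.seed * 9973 + c0) % (2**31 - 1)) + 1
        _track_kernel(
            coeffs,
            B,
            dirs,
            cone_idx,
            cone_off,
            wm,
            inv3,
            invt,
            sub,
            params.step_size,
            params.stop_amplitude,
            max_steps_half,
            kseed,
            pts,
            n_back,
            n_fwd,
        )
        mid = max_steps_half
        for s in range(n):
            npts = n_back[s] + n_fwd[s] + 1
            if npts < max(min_pts, 2):
                continue
            streamlines.append(pts[s, mid - n_back[s] : mid + n_fwd[s] + 1].copy())

    if not streamlines:
        warnings.warn("no streamlines survived the length filter", stacklevel=2)
    prov = asdict(params)
    prov["n_seeded"] = int(params.n_streamlines)
    prov["n_surviving"] = len(streamlines)
    return Tractogram(streamlines=streamlines, provenance=prov)


def _track_peaks(peaks: PeakVolume, seed_mask, wm_mask, params: TrackingParams) -> Tractogram:
    """Reference-path tracking on discrete per-voxel peaks (nearest voxel lookup)."""
    grid = peaks.grid
    rng = np.random.default_rng(params.seed)
    seeds = _sample_seed_points(grid, np.asarray(seed_mask, dtype=bool), params.n_streamlines, rng)
    wm = np.asarray(wm_mask, dtype=bool)
    cos_t = np.cos(np.deg2rad(params.angular_threshold))
    max_steps_half = int(np.floor(params.max_length / params.step_size / 2.0))
    min_pts = int(np.ceil(params.min_length / params.step_size)) + 1

    def candidates(point, incoming):
        idx = grid.nearest_voxel(point)[0]
        if not grid.contains(idx[None])[0]:
            return None, None
        d, a = peaks.peaks_at(tuple(idx))
        if len(a) == 0:
            return np.empty((0, 3)), np.empty(0)
        both = np.vstack([d, -d])
        amps = np.concatenate([a, a])
        if incoming is not None:
            keep = both @ incoming >= cos_t
            both, amps = both[keep], amps[keep]
        keep = amps >= params.stop_amplitude
        return both[keep], amps[keep]

    def grow(start, direction):
        pts = []
        cur = start.copy()
        d = direction
        for _ in range(max_steps_half):
            nxt = cur + params.step_size * d
            idx = grid.nearest_voxel(nxt)[0]
            inside = grid.contains(idx[None])[0] and wm[tuple(idx)]
            pts.append(nxt)
            if not inside:
                break
            cand, amps = candidates(nxt, d)
            if cand is None or len(cand) == 0:
                break
            d = cand[rng.choice(len(cand), p=amps / amps.sum())]
            cur = nxt
        return pts

    streamlines = []
    for seed in seeds:
        cand, amps = candidates(seed, None)
        if cand is None or len(cand) == 0:
            continue
        d0 = cand[rng.choice(len(cand), p=amps / amps.sum())]
        fwd = grow(seed, d0)
        back = grow(seed, -d0)
        pts = back[::-1] + [seed] + fwd
        if len(pts) >= max(min_pts, 2):
            streamlines.append(np.asarray(pts))
    prov = asdict(params)
    prov["n_surviving"] = len(streamlines)
    return Tractogram(streamlines=streamlines, provenance=prov)


def generate_ensemble(
    fod,
    seed_mask,
    wm_mask,
    base_params: TrackingParams,
    angular_thresholds=DEFAULT_ANGULAR_THRESHOLDS,
    n_per_setting: int | None = None,
) -> list:
    """One tractogram per angular-threshold setting, distinct RNG substreams."""
    if len(angular_thresholds) == 0:
        raise ValueError("angular_thresholds must be non-empty")
    out = []
    for i, ang in enumerate(angular_thresholds):
        p = TrackingParams(
            step_size=base_params.step_size,
            angular_threshold=float(ang),
            stop_amplitude=base_params.stop_amplitude,
            min_length=base_params.min_length,
            max_length=base_params.max_length,
            n_streamlines=n_per_setting or base_params.n_streamlines,
            seed=int((base_params.seed + 7919 * (i + 1)) % (2**31 - 1)),
        )
        out.append(track(fod, seed_mask, wm_mask, p))
    return out
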