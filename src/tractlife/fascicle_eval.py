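"""Linear fascicle evaluation (LiFE) and the virtual-lesion statistic.

The connectome model predicts the *demeaned* diffusion attenuation in every
white-matter voxel a candidate streamline traverses as a non-negative
linear combination of per-streamline stick predictions:

    y  ~  M w,   w >= 0

where, for a streamline segment with unit tangent t in voxel v, the
predicted attenuation for direction theta at b-value b is
exp(-b d_axial (theta . t)^2); a streamline's contribution to v is the
mean over its segments in v, demeaned across v's diffusion-weighted
directions.  The measured vector y is the voxel's attenuation
(signal / mean b=0 signal) demeaned the same way.  Streamlines with zero
optimised weight do not contribute to the model and are pruned.

Model accuracy against a held-out repeat session is summarised per voxel
by R_rmse, the ratio of the model-prediction RMSE (against session 2) to
the session-1 vs session-2 test-retest RMSE; R_rmse = 1 means the model
predicts the repeat data exactly as well as the data replicate.  A virtual
lesion removes a candidate tract, refits the remaining path-neighbourhood
streamlines in the tract's voxels, and summarises the loss of accuracy by
the strength of evidence S: the difference of mean R_rmse between lesioned
and unlesioned models divided by their pooled standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core import GradientTable, ImageGrid, Tractogram, Volume

__all__ = [
    "LifeModel",
    "RrmseDistribution",
    "VirtualLesionResult",
    "build_life_model",
    "optimize_weights",
    "nnls_projected_gradient",
    "prune",
    "build_etc",
    "r_rmse",
    "rrmse_per_voxel",
    "virtual_lesion",
    "demeaned_attenuations",
]

DENOM_EPS = 1e-12


@dataclass
class LifeModel:
    tractogram: Tractogram
    gtab: GradientTable
    grid: ImageGrid
    voxels: np.ndarray  # (n_vox, 3) integer indices, traversal union
    y: np.ndarray  # demeaned session-1 attenuations, (n_vox * n_dw,)
    M: sparse.csc_matrix  # (n_vox * n_dw, n_streamlines)
    d_axial: float
    weights: np.ndarray | None = None
    objective_history: np.ndarray | None = None
    zero_columns: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_dw(self) -> int:
        return int(self.gtab.dwi_mask.sum())

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def voxel_rows(self, voxel_ids: np.ndarray) -> np.ndarray:
        """Flat row indices of the direction blocks of the given voxel ids."""
        voxel_ids = np.asarray(voxel_ids, dtype=int)
        n = self.n_dw
        return (voxel_ids[:, None] * n + np.arange(n)[None, :]).ravel()

    def predict(self, weights: np.ndarray | None = None) -> np.ndarray:
        w = self.weights if weights is None else weights
        if w is None:
            raise ValueError("model has no weights; call optimize_weights first")
        return self.M @ w

    def objective(self, weights: np.ndarray | None = None) -> float:
        return float(np.sum((self.y - self.predict(weights)) ** 2))


@dataclass
class RrmseDistribution:
    values: np.ndarray  # per-voxel R_rmse, included voxels only
    voxel_ids: np.ndarray  # into the parent model's voxel list
    n_excluded: int = 0  # voxels dropped for degenerate test-retest denominator


@dataclass
class VirtualLesionResult:
    unlesioned: RrmseDistribution
    lesioned: RrmseDistribution
    S: float
    n_voxels: int
    degenerate: bool = False  # all-zero-weight bundle or no usable voxels


# ---------------------------------------------------------------------------
# model construction


def demeaned_attenuations(data: np.ndarray, gtab: GradientTable, voxels: np.ndarray) -> np.ndarray:
    """Demeaned b>0 attenuations for the listed voxels, flattened per block."""
    vox = tuple(np.asarray(voxels, dtype=int).T)
    sig = np.asarray(data, dtype=float)[vox]  # (n_vox, n_meas)
    s0 = np.maximum(sig[:, gtab.b0_mask].mean(axis=1), DENOM_EPS)
    att = sig[:, gtab.dwi_mask] / s0[:, None]
    att -= att.mean(axis=1, keepdims=True)
    return att.ravel()


def _streamline_voxel_tangents(points: np.ndarray, grid: ImageGrid):
    """(voxel index array, per-segment voxel assignment, unit tangents)."""
    mids = 0.5 * (points[1:] + points[:-1])
    tangents = np.diff(points, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    keep = norms[:, 0] > 0
    tangents = tangents[keep] / norms[keep]
    vox = grid.nearest_voxel(mids[keep])
    return vox, tangents


def build_life_model(
    tractogram: Tractogram,
    dwi_session1: Volume,
    gtab: GradientTable,
    wm_mask: np.ndarray,
    d_axial: float = 1.7e-3,
) -> LifeModel:
    """Assemble the sparse streamline -> demeaned-signal design matrix."""
    if len(tractogram) == 0:
        raise ValueError("tractogram is empty")
    grid = dwi_session1.grid
    wm = np.asarray(wm_mask, dtype=bool)
    b = gtab.bvals[gtab.dwi_mask]
    G = gtab.bvecs[gtab.dwi_mask]  # (n_dw, 3)
    n_dw = len(b)

    # pass 1: per-streamline per-voxel mean stick attenuation
    per_sl = []  # list of (voxel_keys, contributions (n_vox_i, n_dw))
    voxel_set = {}
    for sl in tractogram:
        vox, tang = _streamline_voxel_tangents(np.asarray(sl), grid)
        if len(vox) == 0:
            per_sl.append((np.empty((0,), dtype=np.int64), np.empty((0, n_dw))))
            continue
        inside = grid.contains(vox)
        inwm = np.zeros(len(vox), dtype=bool)
        inwm[inside] = wm[tuple(vox[inside].T)]
        vox, tang = vox[inwm], tang[inwm]
        if len(vox) == 0:
            per_sl.append((np.empty((0,), dtype=np.int64), np.empty((0, n_dw))))
            continue
        keys = np.ravel_multi_index(tuple(vox.T), grid.shape)
        order = np.argsort(keys, kind="stable")
        keys, tang = keys[order], tang[order]
        uniq, start = np.unique(keys, return_index=True)
        att = np.exp(-b[None, :] * d_axial * (tang @ G.T) ** 2)  # (n_seg, n_dw)
        sums = np.add.reduceat(att, start, axis=0)
        counts = np.diff(np.append(start, len(keys)))
        contrib = sums / counts[:, None]
        contrib -= contrib.mean(axis=1, keepdims=True)  # demean per direction block
        per_sl.append((uniq, contrib))
        for k in uniq:
            voxel_set.setdefault(int(k), len(voxel_set))

    if not voxel_set:
        raise ValueError("no streamline traverses the white-matter mask")
    keys_sorted = np.array(sorted(voxel_set), dtype=np.int64)
    key_to_id = {int(k): i for i, k in enumerate(keys_sorted)}
    voxels = np.column_stack(np.unravel_index(keys_sorted, grid.shape))

    rows, cols, vals = [], [], []
    zero_cols = []
    for j, (uniq, contrib) in enumerate(per_sl):
        if len(uniq) == 0:
            zero_cols.append(j)
            continue
        vids = np.array([key_to_id[int(k)] for k in uniq])
        r = (vids[:, None] * n_dw + np.arange(n_dw)[None, :]).ravel()
        rows.append(r)
        cols.append(np.full(len(r), j, dtype=np.int64))
        vals.append(contrib.ravel())
    if zero_cols:
        warnings.warn(
            f"{len(zero_cols)} streamlines lie entirely outside the white-matter mask "
            "(all-zero columns kept)",
            stacklevel=2,
        )
    M = sparse.csc_matrix(
        (
            np.concatenate(vals) if vals else np.empty(0),
            (
                np.concatenate(rows) if rows else np.empty(0, dtype=np.int64),
                np.concatenate(cols) if cols else np.empty(0, dtype=np.int64),
            ),
        ),
        shape=(len(voxels) * n_dw, len(tractogram)),
    )
    y = demeaned_attenuations(dwi_session1.data, gtab, voxels)
    return LifeModel(
        tractogram=tractogram,
        gtab=gtab,
        grid=grid,
        voxels=voxels,
        y=y,
        M=M,
        d_axial=d_axial,
        zero_columns=np.asarray(zero_cols, dtype=int),
    )


# ---------------------------------------------------------------------------
# non-negative least squares


def _spectral_norm_sq(M: sparse.spmatrix, n_iter: int = 30) -> float:
    """lambda_max(M^T M) by power iteration (fixed internal seed)."""
    rng = np.random.default_rng(12345)
    v = rng.standard_normal(M.shape[1])
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        u = M.T @ (M @ v)
        lam = float(np.linalg.norm(u))
        if lam == 0:
            return 1.0
        v = u / lam
    return lam


def nnls_projected_gradient(
    M,
    y: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-6,
    w0: np.ndarray | None = None,
):
    """Accelerated projected-gradient NNLS with a monotone-descent safeguard.

    Minimises ||y - M w||^2 over w >= 0.  Accelerated (FISTA-style) steps
    are accepted only when they do not increase the objective; otherwise a
    plain projected-gradient step from the current iterate is taken, which
    descends for step 1/L.  Returns (w, objective_history, converged).
    """
    M = sparse.csc_matrix(M) if not sparse.issparse(M) else M
    L = max(_spectral_norm_sq(M), DENOM_EPS)
    step = 1.0 / L

    def f(w):
        r = M @ w - y
        return float(r @ r)

    w = np.zeros(M.shape[1]) if w0 is None else np.maximum(np.asarray(w0, dtype=float), 0.0)
    z = w.copy()
    t = 1.0
    fw = f(w)
    history = [fw]
    converged = False
    for _ in range(max_iter):
        grad_z = M.T @ (M @ z - y)
        w_new = np.maximum(z - step * grad_z, 0.0)
        f_new = f(w_new)
        if f_new > fw:  # safeguard: plain PG step from w
            grad_w = M.T @ (M @ w - y)
            w_new = np.maximum(w - step * grad_w, 0.0)
            f_new = f(w_new)
            t = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = w_new + ((t - 1.0) / t_new) * (w_new - w)
        t = t_new
        rel = (fw - f_new) / max(fw, DENOM_EPS)
        w, fw = w_new, f_new
        history.append(fw)
        if 0.0 <= rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("NNLS did not converge within max_iter; best iterate returned", stacklevel=2)
    return w, np.asarray(history), converged


def optimize_weights(model: LifeModel, max_iter: int = 1000, tol: float = 1e-6) -> np.ndarray:
    """Fit non-negative streamline weights; stores them on the model."""
    w, hist, _ = nnls_projected_gradient(model.M, model.y, max_iter=max_iter, tol=tol)
    model.weights = w
    model.objective_history = hist
    return w


def prune(model: LifeModel, k: int | None = None) -> Tractogram:
    """Streamlines with positive weight (optionally the top-k by weight)."""
    if model.weights is None:
        raise ValueError("optimize_weights must run before pruning")
    nz = np.flatnonzero(model.weights > 0)
    if len(nz) == 0:
        warnings.warn("all weights are zero; empty tractogram", stacklevel=2)
        return model.tractogram.subset([], pruned=True)
    if k is not None and k < len(nz):
        order = np.argsort(model.weights[nz])[::-1][:k]
        nz = np.sort(nz[order])
    return model.tractogram.subset(
        nz, pruned=True, weights=model.weights[nz].tolist()
    )


def build_etc(single_param_models: list, k_per_model: int) -> Tractogram:
    """Ensemble tractography connectome: union of per-model top-k pruned sets.

    The returned candidate tractogram is meant to be re-optimised with
    :func:`build_life_model` + :func:`optimize_weights`.
    """
    if len(single_param_models) < 2:
        raise ValueError("ETC needs >= 2 optimised single-parameter models")
    streamlines = []
    source_params = []
    source_of = []
    for m in single_param_models:
        sub = prune(m, k=k_per_model)
        streamlines.extend(sub.streamlines)
        ang = m.tractogram.provenance.get("angular_threshold")
        source_params.append({"angular_threshold": ang, "n_selected": len(sub)})
        source_of.extend([ang] * len(sub))
    return Tractogram(
        streamlines=streamlines,
        provenance={
            "etc": True,
            "k_per_model": int(k_per_model),
            "sources": source_params,
            "source_setting": source_of,
        },
    )


# ---------------------------------------------------------------------------
# cross-validated accuracy


def rrmse_per_voxel(
    pred: np.ndarray, att1: np.ndarray, att2: np.ndarray, n_dw: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel R_rmse of flattened direction-block vectors.

    Returns (values, included_mask); voxels whose test-retest RMSE is below
    1e-12 are excluded.
    """
    p = pred.reshape(-1, n_dw)
    a1 = att1.reshape(-1, n_dw)
    a2 = att2.reshape(-1, n_dw)
    num = np.sqrt(np.mean((p - a2) ** 2, axis=1))
    den = np.sqrt(np.mean((a1 - a2) ** 2, axis=1))
    included = den >= DENOM_EPS
    values = np.zeros(len(num))
    values[included] = num[included] / den[included]
    return values, included


def r_rmse(
    model: LifeModel,
    dwi_session1: Volume,
    dwi_session2: Volume,
    voxel_ids: np.ndarray,
    prediction: np.ndarray | None = None,
) -> RrmseDistribution:
    """Cross-validated ratio-of-RMSE over the given model voxel ids.

    The numerator is the RMSE between the model prediction (fitted on
    session 1) and the session-2 demeaned attenuation; the denominator is
    the session-1 vs session-2 test-retest RMSE in the same voxel.
    ``prediction`` overrides the model's fitted prediction (full y-length
    vector), which supports definitional checks and lesioned models.
    """
    voxel_ids = np.asarray(voxel_ids, dtype=int)
    if len(voxel_ids) == 0:
        raise ValueError("empty voxel set")
    rows = model.voxel_rows(voxel_ids)
    pred = model.predict() if prediction is None else np.asarray(prediction)
    vox = model.voxels[voxel_ids]
    att1 = demeaned_attenuations(dwi_session1.data, model.gtab, vox)
    att2 = demeaned_attenuations(dwi_session2.data, model.gtab, vox)
    values, included = rrmse_per_voxel(pred[rows], att1, att2, model.n_dw)
    return RrmseDistribution(
        values=values[included],
        voxel_ids=voxel_ids[included],
        n_excluded=int((~included).sum()),
    )


# ---------------------------------------------------------------------------
# virtual lesion


def _columns_touching_rows(M: sparse.csc_matrix, rows: np.ndarray) -> np.ndarray:
    mask = np.zeros(M.shape[0], dtype=bool)
    mask[rows] = True
    touched = np.zeros(M.shape[1], dtype=bool)
    indptr, indices = M.indptr, M.indices
    for j in range(M.shape[1]):
        sl = indices[indptr[j] : indptr[j + 1]]
        if sl.size and mask[sl].any():
            touched[j] = True
    return touched


def strength_of_evidence(unlesioned: np.ndarray, lesioned: np.ndarray) -> float:
    """Difference of mean R_rmse over the pooled standard deviation."""
    if len(unlesioned) == 0 or len(lesioned) == 0:
        return 0.0
    var_u = float(np.var(unlesioned, ddof=1)) if len(unlesioned) > 1 else 0.0
    var_l = float(np.var(lesioned, ddof=1)) if len(lesioned) > 1 else 0.0
    pooled = np.sqrt(0.5 * (var_u + var_l))
    if pooled < DENOM_EPS:
        return 0.0
    return float((np.mean(lesioned) - np.mean(unlesioned)) / pooled)


def virtual_lesion(
    model: LifeModel,
    bundle_column_indices: np.ndarray,
    dwi_session1: Volume,
    dwi_session2: Volume,
    refit_max_iter: int = 500,
    refit_tol: float = 1e-6,
) -> VirtualLesionResult:
    """Lesion a candidate bundle and measure the loss of prediction accuracy.

    The comparison voxel set is the set of model voxels traversed by the
    bundle.  The path neighbourhood is every positively weighted streamline
    traversing any of those voxels.  The lesioned model removes the bundle
    columns and re-optimises the remaining path-neighbourhood weights on
    the voxel set only; both models are then scored with R_rmse against the
    held-out session and compared via the strength of evidence S.
    """
    if model.weights is None:
        raise ValueError("optimize_weights must run before virtual_lesion")
    bundle = np.unique(np.asarray(bundle_column_indices, dtype=int))
    w = model.weights

    # voxels traversed by the bundle
    sub = model.M[:, bundle]
    touched_rows = np.unique(sparse.csc_matrix(sub).indices)
    voxel_ids = np.unique(touched_rows // model.n_dw)

    if len(voxel_ids) == 0 or not np.any(w[bundle] > 0):
        dist = (
            r_rmse(model, dwi_session1, dwi_session2, voxel_ids)
            if len(voxel_ids)
            else RrmseDistribution(np.empty(0), np.empty(0, dtype=int))
        )
        return VirtualLesionResult(
            unlesioned=dist, lesioned=dist, S=0.0, n_voxels=len(voxel_ids), degenerate=True
        )

    rows = model.voxel_rows(voxel_ids)
    neighbourhood = np.flatnonzero(_columns_touching_rows(model.M, rows) & (w > 0))
    survivors = np.setdiff1d(neighbourhood, bundle)

    unlesioned = r_rmse(model, dwi_session1, dwi_session2, voxel_ids)

    # lesioned refit restricted to path-neighbourhood columns and voxel rows
    pred_lesioned = np.zeros_like(model.y)
    if len(survivors):
        M_sub = sparse.csc_matrix(model.M[rows][:, survivors])
        y_sub = model.y[rows]
        w_sub, _, _ = nnls_projected_gradient(
            M_sub, y_sub, max_iter=refit_max_iter, tol=refit_tol, w0=w[survivors]
        )
        pred_lesioned[rows] = M_sub @ w_sub
    lesioned = r_rmse(
        model, dwi_session1, dwi_session2, voxel_ids, prediction=pred_lesioned
    )

    # compare over the identical (included) voxel set
    common = np.intersect1d(unlesioned.voxel_ids, lesioned.voxel_ids)
    u_vals = unlesioned.values[np.isin(unlesioned.voxel_ids, common)]
    l_vals = lesioned.values[np.isin(lesioned.voxel_ids, common)]
    S = strength_of_evidence(u_vals, l_vals)
    return VirtualLesionResult(
        unlesioned=RrmseDistribution(u_vals, common, unlesioned.n_excluded),
        lesioned=RrmseDistribution(l_vals, common, lesioned.n_excluded),
        S=S,
        n_voxels=len(common),
        degenerate=len(common) == 0,
    )
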