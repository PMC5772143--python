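"""LiFE model construction, NNLS optimisation, R_rmse and virtual lesions."""

import itertools

import numpy as np
import pytest
from scipy import sparse

from tractlife.bundle_ops import segment_by_endpoints
from tractlife.core import GradientTable, ImageGrid, Tractogram, Volume
from tractlife.fascicle_eval import (
    build_etc,
    build_life_model,
    demeaned_attenuations,
    nnls_projected_gradient,
    optimize_weights,
    prune,
    r_rmse,
    rrmse_per_voxel,
    strength_of_evidence,
    virtual_lesion,
)
from tractlife.phantom import generate_phantom, make_u_bundle_spec
from tractlife.tracking import TrackingParams, track


def brute_force_nnls(A, y):
    """Exhaustive active-set oracle: best feasible restricted LS over all supports."""
    n = A.shape[1]
    best = float(y @ y)
    for r in range(1, n + 1):
        for S in itertools.combinations(range(n), r):
            ws, *_ = np.linalg.lstsq(A[:, S], y, rcond=None)
            if np.all(ws >= -1e-12):
                w = np.zeros(n)
                w[list(S)] = np.maximum(ws, 0.0)
                best = min(best, float(np.sum((y - A @ w) ** 2)))
    return best


@pytest.fixture(scope="module")
def fitted_model(phantom):
    """Single-setting connectome model optimised on the default phantom."""
    spec, sessions, truth = phantom
    from tractlife.local_model import deconvolve_fod, estimate_response, fit_tensor

    wm = truth.wm_mask.data.astype(bool)
    tensor = fit_tensor(sessions[0], spec.gtab, wm)
    resp = estimate_response(sessions[0], spec.gtab, tensor)
    fod = deconvolve_fod(sessions[0], spec.gtab, resp, mask=wm)
    p = TrackingParams(angular_threshold=47.2, n_streamlines=1500, seed=13)
    tg = track(fod, truth.gwmi_mask.data.astype(bool), wm, p)
    model = build_life_model(tg, sessions[0], spec.gtab, wm)
    optimize_weights(model, max_iter=500)
    return spec, sessions, truth, model


class TestModelConstruction:
    def test_single_streamline_explains_aligned_stick_voxel(self, gtab):
        # stick signal with zero radial diffusivity is exactly proportional,
        # after demeaning, to the LiFE column of an aligned streamline
        grid = ImageGrid.isotropic((3, 3, 3), 2.0)
        t = np.array([1.0, 0, 0])
        b, G = gtab.bvals, gtab.bvecs
        sig = 100 * np.exp(-b * 1.7e-3 * (G @ t) ** 2)
        data = np.broadcast_to(sig, (3, 3, 3, 66)).copy()
        wm = np.zeros((3, 3, 3), dtype=bool)
        wm[1, 1, 1] = True
        sl = np.array([[1.0, 2, 2], [2, 2, 2], [3, 2, 2]])
        model = build_life_model(Tractogram([sl]), Volume(grid, data), gtab, wm)
        w, *_ = nnls_projected_gradient(model.M, model.y, max_iter=5000, tol=1e-14)
        resid = np.linalg.norm(model.y - model.M @ w)
        assert resid < 0.01 * np.linalg.norm(model.y)

    def test_columns_demeaned_per_voxel_block(self, fitted_model):
        _, _, _, model = fitted_model
        M = model.M.tocsc()
        n_dw = model.n_dw
        for j in range(0, min(50, M.shape[1])):
            col = M[:, j]
            rows = col.indices
            vals = col.data
            for block in np.unique(rows // n_dw):
                sel = rows // n_dw == block
                assert abs(vals[sel].sum()) < 1e-9

    def test_identical_streamlines_give_identical_columns(self, gtab):
        grid = ImageGrid.isotropic((3, 3, 3), 2.0)
        data = np.full((3, 3, 3, 66), 50.0)
        wm = np.ones((3, 3, 3), dtype=bool)
        sl = np.array([[0.0, 2, 2], [2, 2, 2], [4, 2, 2]])
        model = build_life_model(Tractogram([sl, sl.copy()]), Volume(grid, data), gtab, wm)
        M = model.M.toarray()
        assert np.array_equal(M[:, 0], M[:, 1])

    def test_streamline_outside_mask_kept_as_zero_column(self, gtab):
        grid = ImageGrid.isotropic((4, 4, 4), 2.0)
        data = np.full((4, 4, 4, 66), 50.0)
        wm = np.zeros((4, 4, 4), dtype=bool)
        wm[1, 1, 1] = True
        inside = np.array([[1.0, 2, 2], [2, 2, 2], [3, 2, 2]])
        outside = np.array([[5.0, 6, 6], [6, 6, 6], [7, 6, 6]])
        with pytest.warns(UserWarning):
            model = build_life_model(
                Tractogram([inside, outside]), Volume(grid, data), gtab, wm
            )
        assert model.M.shape[1] == 2
        assert model.M[:, 1].nnz == 0
        assert list(model.zero_columns) == [1]

    def test_empty_tractogram_rejected(self, gtab):
        grid = ImageGrid.isotropic((3, 3, 3), 2.0)
        with pytest.raises(ValueError):
            build_life_model(
                Tractogram([]), Volume(grid, np.ones((3, 3, 3, 66))), gtab,
                np.ones((3, 3, 3), dtype=bool),
            )


class TestNNLS:
    def test_orthogonal_columns_exact_solution(self):
        A = np.zeros((6, 3))
        A[0, 0] = A[1, 1] = A[2, 2] = 1.0
        y = 2.0 * A[:, 0]
        w, hist, conv = nnls_projected_gradient(sparse.csc_matrix(A), y, max_iter=2000, tol=1e-14)
        assert np.allclose(w, [2.0, 0.0, 0.0], atol=1e-8)

    def test_matches_brute_force_active_set_oracle(self, rng):
        for _ in range(5):
            A = rng.standard_normal((30, 10))
            y = rng.standard_normal(30)
            w, *_ = nnls_projected_gradient(sparse.csc_matrix(A), y, max_iter=20000, tol=1e-14)
            ours = float(np.sum((y - A @ w) ** 2))
            assert abs(ours - brute_force_nnls(A, y)) < 1e-6

    def test_orthogonal_target_gives_zero_weights(self, rng):
        A = np.zeros((4, 2))
        A[:2, 0] = [1, 0]
        A[:2, 1] = [0, 1]
        y = np.array([0.0, 0, 1, 1])  # orthogonal to both columns
        w, *_ = nnls_projected_gradient(sparse.csc_matrix(A), y, max_iter=100, tol=1e-12)
        assert np.allclose(w, 0.0)

    def test_objective_monotone_descent(self, rng):
        A = rng.standard_normal((40, 15))
        y = rng.standard_normal(40)
        _, hist, _ = nnls_projected_gradient(sparse.csc_matrix(A), y, max_iter=500, tol=0.0)
        assert np.all(np.diff(hist) <= 1e-12)


class TestPruneAndEtc:
    def _toy_model(self, weights):
        m = type("M", (), {})()  # minimal stand-in with the attributes prune uses
        m.weights = np.asarray(weights, dtype=float)
        m.tractogram = Tractogram(
            [np.array([[i, 0, 0], [i, 1, 0]], dtype=float) for i in range(len(weights))]
        )
        return m

    def test_prune_keeps_positive_weights(self):
        tg = prune(self._toy_model([0.5, 0.0, 0.2]))
        assert len(tg) == 2
        assert tg.provenance["parent_indices"] == [0, 2]

    def test_prune_top_k(self):
        tg = prune(self._toy_model([0.5, 0.0, 0.2]), k=1)
        assert len(tg) == 1
        assert tg.provenance["parent_indices"] == [0]

    def test_prune_k_larger_than_nonzero_count(self):
        tg = prune(self._toy_model([0.5, 0.0, 0.2]), k=10)
        assert len(tg) == 2

    def test_prune_all_zero_warns_empty(self):
        with pytest.warns(UserWarning):
            tg = prune(self._toy_model([0.0, 0.0]))
        assert len(tg) == 0

    def test_etc_candidate_arithmetic(self):
        models = [self._toy_model(np.linspace(1, 0.1, 150)) for _ in range(4)]
        etc = build_etc(models, k_per_model=100)
        assert len(etc) == 400  # 4 x 100, the desk-scale analog of 4 x 150k
        assert etc.provenance["k_per_model"] == 100

    def test_etc_needs_two_models(self):
        with pytest.raises(ValueError):
            build_etc([self._toy_model([1.0])], k_per_model=1)

    def test_pruned_refit_reproduces_objective(self, fitted_model):
        spec, sessions, truth, model = fitted_model
        pruned_tg = prune(model)
        wm = truth.wm_mask.data.astype(bool)
        m2 = build_life_model(pruned_tg, sessions[0], spec.gtab, wm)
        w2, *_ = nnls_projected_gradient(m2.M, m2.y, max_iter=2000, tol=1e-12,
                                         w0=model.weights[model.weights > 0])
        # evaluate both on the pruned model's rows: objectives agree closely
        f_full = model.objective()
        f_pruned = float(np.sum((m2.y - m2.M @ w2) ** 2))
        extra = f_full - float(
            np.sum(np.asarray(model.y) ** 2)
            - np.sum(np.asarray(m2.y) ** 2)
        )  # residual mass on rows absent from the pruned model is pure ||y||^2
        assert f_pruned <= extra + 1e-6

    def test_etc_refit_at_least_as_good_as_embedded_singles(self, phantom):
        spec, sessions, truth = phantom
        from tractlife.local_model import deconvolve_fod, estimate_response, fit_tensor

        wm = truth.wm_mask.data.astype(bool)
        tensor = fit_tensor(sessions[0], spec.gtab, wm)
        resp = estimate_response(sessions[0], spec.gtab, tensor)
        fod = deconvolve_fod(sessions[0], spec.gtab, resp, mask=wm)
        models = []
        for i, ang in enumerate((11.5, 47.2)):
            p = TrackingParams(angular_threshold=ang, n_streamlines=400, seed=31 + i)
            tg = track(fod, truth.gwmi_mask.data.astype(bool), wm, p)
            m = build_life_model(tg, sessions[0], spec.gtab, wm)
            optimize_weights(m, max_iter=400)
            models.append(m)
        etc_tg = build_etc(models, k_per_model=10**9)  # keep every contributing streamline
        etc = build_life_model(etc_tg, sessions[0], spec.gtab, wm)
        optimize_weights(etc, max_iter=1500)
        f_etc = etc.objective()
        # superset-of-columns argument: embedding each single model's weights
        # into the ETC columns cannot do better than the re-optimised ETC
        offset = 0
        for m in models:
            w_embed = np.zeros(etc.M.shape[1])
            nz = np.flatnonzero(m.weights > 0)
            w_embed[offset : offset + len(nz)] = m.weights[nz]
            offset += len(nz)
            f_embed = float(np.sum((etc.y - etc.M @ w_embed) ** 2))
            assert f_etc <= f_embed + 1e-6


class TestRrmse:
    def test_definitional_unity(self, fitted_model):
        # prediction constructed to equal the session-1 demeaned signal makes
        # the ratio exactly 1 in every voxel
        spec, sessions, truth, model = fitted_model
        vox_ids = np.arange(model.n_voxels)
        att1 = demeaned_attenuations(sessions[0].data, spec.gtab, model.voxels)
        dist = r_rmse(model, sessions[0], sessions[1], vox_ids, prediction=att1)
        assert dist.n_excluded == 0
        assert np.allclose(dist.values, 1.0, atol=1e-9)

    def test_session2_prediction_gives_zero(self, fitted_model):
        spec, sessions, truth, model = fitted_model
        vox_ids = np.arange(model.n_voxels)
        att2 = demeaned_attenuations(sessions[1].data, spec.gtab, model.voxels)
        dist = r_rmse(model, sessions[0], sessions[1], vox_ids, prediction=att2)
        assert np.allclose(dist.values, 0.0, atol=1e-12)

    def test_zero_model_median_above_one(self, fitted_model):
        # predicting zero (the demeaned mean) is worse than test-retest noise
        spec, sessions, truth, model = fitted_model
        vox_ids = np.arange(model.n_voxels)
        dist = r_rmse(model, sessions[0], sessions[1], vox_ids,
                      prediction=np.zeros_like(model.y))
        assert np.median(dist.values) > 1.0

    def test_invariant_to_global_scaling_of_both_sessions(self, fitted_model):
        spec, sessions, truth, model = fitted_model
        vox_ids = np.arange(min(40, model.n_voxels))
        a = r_rmse(model, sessions[0], sessions[1], vox_ids)
        s1 = Volume(sessions[0].grid, sessions[0].data * 3.7)
        s2 = Volume(sessions[1].grid, sessions[1].data * 3.7)
        b = r_rmse(model, s1, s2, vox_ids)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_empty_voxel_set_rejected(self, fitted_model):
        spec, sessions, truth, model = fitted_model
        with pytest.raises(ValueError):
            r_rmse(model, sessions[0], sessions[1], np.array([], dtype=int))

    def test_degenerate_denominator_excluded(self):
        pred = np.zeros(8)
        att = np.arange(8.0)
        vals, inc = rrmse_per_voxel(pred, att, att, 4)  # identical sessions
        assert not inc.any()


class TestVirtualLesion:
    def test_zero_weight_lesion_gives_identical_distributions(self, fitted_model):
        spec, sessions, truth, model = fitted_model
        zero_cols = np.flatnonzero(model.weights == 0)[:20]
        assert len(zero_cols)
        res = virtual_lesion(model, zero_cols, sessions[0], sessions[1])
        assert res.degenerate
        assert res.S == 0.0
        assert np.array_equal(res.unlesioned.values, res.lesioned.values)

    def test_essential_bundle_has_positive_evidence(self, fitted_model):
        spec, sessions, truth, model = fitted_model
        pruned = prune(model)
        parent = np.asarray(pruned.provenance["parent_indices"])
        roi_a = truth.roi_labels.centers("superior_parietal_like")
        roi_b = truth.roi_labels.centers("supramarginal_like")
        bundle = segment_by_endpoints(pruned, roi_a, roi_b)
        assert len(bundle) > 0
        res = virtual_lesion(model, parent[bundle.indices], sessions[0], sessions[1])
        assert not res.degenerate
        assert res.S > 0

    def test_bundle_evidence_exceeds_random_distractor_subsets(self, fitted_model):
        spec, sessions, truth, model = fitted_model
        pruned = prune(model)
        parent = np.asarray(pruned.provenance["parent_indices"])
        roi_a = truth.roi_labels.centers("superior_parietal_like")
        roi_b = truth.roi_labels.centers("supramarginal_like")
        bundle = segment_by_endpoints(pruned, roi_a, roi_b)
        s_bundle = virtual_lesion(model, parent[bundle.indices], sessions[0], sessions[1]).S
        da = truth.roi_labels.centers("distractor_a")
        db = truth.roi_labels.centers("distractor_b")
        distr = segment_by_endpoints(pruned, da, db, dist_mm=4.5)
        rng = np.random.default_rng(5)
        cand = parent[distr.indices]
        for _ in range(3):
            take = rng.choice(cand, size=min(len(bundle), len(cand)), replace=False)
            s_rand = virtual_lesion(model, take, sessions[0], sessions[1]).S
            assert s_bundle > s_rand

    def test_duplicated_bundle_is_redundant(self, fitted_model):
        # duplicating every bundle streamline before fitting makes each copy
        # individually dispensable: lesioning one copy leaves S ~ 0
        spec, sessions, truth, model = fitted_model
        pruned = prune(model)
        roi_a = truth.roi_labels.centers("superior_parietal_like")
        roi_b = truth.roi_labels.centers("supramarginal_like")
        bundle = segment_by_endpoints(pruned, roi_a, roi_b)
        dup_streamlines = list(pruned.streamlines) + [
            s.copy() for s in bundle.streamlines
        ]
        wm = truth.wm_mask.data.astype(bool)
        dup_model = build_life_model(
            Tractogram(dup_streamlines), sessions[0], spec.gtab, wm
        )
        optimize_weights(dup_model, max_iter=600)
        copy_cols = np.arange(len(pruned), len(dup_streamlines))
        res = virtual_lesion(dup_model, copy_cols, sessions[0], sessions[1])
        assert abs(res.S) < 2.0


def test_strength_of_evidence_pooled_sd():
    u = np.array([1.0, 1.1, 0.9])
    l = np.array([2.0, 2.1, 1.9])
    pooled = np.sqrt(0.5 * (np.var(u, ddof=1) + np.var(l, ddof=1)))
    assert np.isclose(strength_of_evidence(u, l), 1.0 / pooled)
    assert strength_of_evidence(u, u) == 0.0
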