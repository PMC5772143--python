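"""End-to-end orchestration of the phantom cohort analysis.

Per subject: phantom synthesis -> tensor fit and single-fiber response ->
CSD -> ensemble tractography over four angular-threshold settings ->
per-setting LiFE optimisation and preselection -> ensemble tractography
connectome (ETC) re-optimisation -> endpoint-ROI segmentation with outlier
removal -> virtual lesion -> endpoint density and ROI proximity ->
visitation map.  The cohort run aggregates per-subject rows and builds the
percentage-overlap atlas on a common template grid using each subject's
known rigid jitter as the subject-to-template affine.

Each "subject" is an independent phantom instance (independent geometry
jitter and noise); two phantom instances stand in for the two hemispheres
of a real analysis.  All randomness derives from a single master seed via
a documented counter scheme, so cohort runs are fully reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .atlas import OverlapAtlas, VisitationMap, normalise_map, percentage_overlap, visitation_map
from .bundle_ops import endpoint_density, remove_outliers, roi_proximity, segment_by_endpoints
from .core import ImageGrid, Tractogram
from .fascicle_eval import build_etc, build_life_model, optimize_weights, prune, virtual_lesion
from .local_model import deconvolve_fod, estimate_response, fit_tensor
from .phantom import generate_phantom, make_u_bundle_spec
from .tracking import DEFAULT_ANGULAR_THRESHOLDS, TrackingParams, generate_ensemble

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SubjectResult", "CohortResult", "run_subject", "run_cohort", "subject_seed"]


@dataclass
class RunConfig:
    """All stage parameters in one place (defaults follow the reference analysis
    protocol where it states values; counts are desk-scale)."""

    # phantom
    grid_shape: tuple = (30, 30, 30)
    voxel_size: float = 2.0
    noise_sigma: float = 2.0
    n_sessions: int = 2
    include_u_bundle: bool = True
    # local model
    lmax: int = 8
    fa_threshold: float = 0.7
    # tracking
    step_size: float = 0.2
    stop_amplitude: float = 0.1
    min_length: float = 10.0
    max_length: float = 200.0
    angular_thresholds: tuple = DEFAULT_ANGULAR_THRESHOLDS
    n_per_setting: int = 5000
    # LiFE / ETC
    k_per_model: int = 1250
    prefit_max_iter: int = 300
    etc_max_iter: int = 600
    nnls_tol: float = 1e-6
    d_axial: float = 1.7e-3
    # segmentation
    endpoint_dist_mm: float = 3.0
    outlier_len_sd: float = 3.0
    outlier_min_len_mm: float = 15.0
    outlier_pos_sd: float = 3.0
    # reports
    proximity_thresholds: tuple = (3.0, 4.5)
    atlas_threshold_pct: float = 25.0
    # cohort
    n_subjects: int = 6
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=list))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        for k in ("grid_shape", "angular_thresholds", "proximity_thresholds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SubjectResult:
    subject_id: str
    report: dict
    bundle: "object"
    etc_model: "object"
    lesion: "object"
    vmap: VisitationMap
    affine_to_template: np.ndarray
    proximity: "object"
    density: "object"
    degenerate: bool = False


@dataclass
class CohortResult:
    report: pd.DataFrame
    atlas: OverlapAtlas
    subjects: list
    failures: list = field(default_factory=list)


def subject_seed(master_seed: int, index: int) -> int:
    """Counter-scheme per-subject seed derived from the master seed."""
    return int((master_seed * 100003 + 7919 * (index + 1)) % (2**31 - 1))


def run_subject(config: RunConfig, seed: int, subject_id: str = "S1", out_dir=None) -> SubjectResult:
    """Execute every stage for one phantom subject; deterministic given seed."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    spec = make_u_bundle_spec(
        grid_shape=config.grid_shape,
        seed=seed,
        voxel_size=config.voxel_size,
        noise_sigma=config.noise_sigma,
        n_sessions=config.n_sessions,
        include_u_bundle=config.include_u_bundle,
    )
    sessions, truth = generate_phantom(spec)
    sess1, sess2 = sessions[0], sessions[1 % len(sessions)]
    wm = truth.wm_mask.data.astype(bool)
    gwmi = truth.gwmi_mask.data.astype(bool)

    tensor = fit_tensor(sess1, spec.gtab, wm)
    response = estimate_response(sess1, spec.gtab, tensor, fa_threshold=config.fa_threshold,
                                 lmax=config.lmax)
    fod = deconvolve_fod(sess1, spec.gtab, response, lmax=config.lmax, mask=wm)

    base = TrackingParams(
        step_size=config.step_size,
        stop_amplitude=config.stop_amplitude,
        min_length=config.min_length,
        max_length=config.max_length,
        n_streamlines=config.n_per_setting,
        seed=seed,
    )
    ensemble = generate_ensemble(
        fod, gwmi, wm, base, angular_thresholds=config.angular_thresholds
    )

    models = []
    for tg in ensemble:
        if len(tg) == 0:
            continue
        m = build_life_model(tg, sess1, spec.gtab, wm, d_axial=config.d_axial)
        optimize_weights(m, max_iter=config.prefit_max_iter, tol=config.nnls_tol)
        models.append(m)
    if len(models) < 2:
        raise RuntimeError("fewer than two non-empty single-parameter connectomes")

    etc_candidates = build_etc(models, k_per_model=config.k_per_model)
    etc_model = build_life_model(etc_candidates, sess1, spec.gtab, wm, d_axial=config.d_axial)
    optimize_weights(etc_model, max_iter=config.etc_max_iter, tol=config.nnls_tol)
    optimised = prune(etc_model)  # positive-weight streamlines only
    opt_parent = np.asarray(optimised.provenance["parent_indices"], dtype=int)

    roi_a_centers = truth.roi_labels.centers("superior_parietal_like")
    roi_b_centers = truth.roi_labels.centers("supramarginal_like")
    bundle = segment_by_endpoints(
        optimised, roi_a_centers, roi_b_centers,
        dist_mm=config.endpoint_dist_mm, name="u_bundle",
    )
    if len(bundle):
        bundle = remove_outliers(
            bundle,
            len_sd=config.outlier_len_sd,
            min_len_mm=config.outlier_min_len_mm,
            pos_sd=config.outlier_pos_sd,
            anchor=roi_a_centers.mean(axis=0),
        )

    lesion = None
    S = float("nan")
    degenerate = False
    if len(bundle):
        bundle_cols = opt_parent[bundle.indices]
        lesion = virtual_lesion(etc_model, bundle_cols, sess1, sess2)
        S = lesion.S
        degenerate = lesion.degenerate
    else:
        degenerate = True

    rois = {
        "superior_parietal_like": roi_a_centers,
        "supramarginal_like": roi_b_centers,
    }
    proximity = roi_proximity(bundle, rois, thresholds_mm=config.proximity_thresholds)
    density = endpoint_density(bundle, truth.roi_labels, dist_mm=config.endpoint_dist_mm)
    vmap = visitation_map(bundle, spec.grid, subject_id=subject_id)

    # known subject-to-template rigid transform: undo the phantom jitter
    affine = np.eye(4)
    affine[:3, 3] = -np.asarray(spec.jitter_mm)

    report = {
        "subject": subject_id,
        "seed": seed,
        "n_candidates": int(sum(len(t) for t in ensemble)),
        "n_etc_candidates": len(etc_candidates),
        "n_etc_optimised": len(optimised),
        "n_bundle": len(bundle),
        "mean_bundle_length_cm": float(bundle.streamlines.lengths().mean() / 10.0)
        if len(bundle)
        else float("nan"),
        "S": S,
        "n_lesion_voxels": lesion.n_voxels if lesion is not None else 0,
        "degenerate": bool(degenerate),
    }
    for (roi, thr), p in proximity.proportions.items():
        report[f"prox_{roi}_{thr:g}mm"] = p

    if out is not None:
        _persist_subject(out, subject_id, spec, truth, bundle, etc_model, lesion, vmap, affine, report)

    return SubjectResult(
        subject_id=subject_id,
        report=report,
        bundle=bundle,
        etc_model=etc_model,
        lesion=lesion,
        vmap=vmap,
        affine_to_template=affine,
        proximity=proximity,
        density=density,
        degenerate=degenerate,
    )


def _persist_subject(out, sid, spec, truth, bundle, etc_model, lesion, vmap, affine, report):
    sub = out / sid
    sub.mkdir(parents=True, exist_ok=True)
    tio.write_volume(vmap.volume, sub / "visitation.nii.gz")
    tio.write_label_volume(truth.roi_labels, sub / "roi_labels.nii.gz")
    tio.write_affine(affine, sub / "to_template.txt")
    if len(bundle):
        tio.write_tractogram(bundle.streamlines, sub / "bundle.tck")
    if etc_model.weights is not None:
        pd.DataFrame(
            {"streamline": np.arange(len(etc_model.weights)), "weight": etc_model.weights}
        ).to_csv(sub / "weights.tsv", sep="\t", index=False)
    if lesion is not None:
        (sub / "lesion.json").write_text(
            json.dumps(
                {
                    "n_voxels": lesion.n_voxels,
                    "mean_unlesioned": float(np.mean(lesion.unlesioned.values))
                    if len(lesion.unlesioned.values)
                    else None,
                    "mean_lesioned": float(np.mean(lesion.lesioned.values))
                    if len(lesion.lesioned.values)
                    else None,
                    "sd_unlesioned": float(np.std(lesion.unlesioned.values, ddof=1))
                    if len(lesion.unlesioned.values) > 1
                    else None,
                    "sd_lesioned": float(np.std(lesion.lesioned.values, ddof=1))
                    if len(lesion.lesioned.values) > 1
                    else None,
                    "S": lesion.S,
                    "degenerate": lesion.degenerate,
                },
                indent=1,
            )
        )
    (sub / "report.json").write_text(json.dumps(report, indent=1))


def run_cohort(config: RunConfig, out_dir=None) -> CohortResult:
    """Run every subject, aggregate the cohort report, and build the atlas."""
    out = Path(out_dir) if out_dir is not None else None
    subjects = []
    failures = []
    rows = []
    template_grid = ImageGrid.isotropic(config.grid_shape, config.voxel_size)
    maps = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1}"
        seed = subject_seed(config.master_seed, i)
        try:
            res = run_subject(config, seed, subject_id=sid,
                              out_dir=(out / "subjects") if out else None)
        except Exception as exc:  # pragma: no cover - defensive cohort continuation
            logger.error("subject %s failed: %s", sid, exc)
            failures.append({"subject": sid, "seed": seed, "error": repr(exc)})
            continue
        subjects.append(res)
        rows.append(res.report)
        maps.append(normalise_map(res.vmap, res.affine_to_template, template_grid))
    if not subjects:
        raise RuntimeError("all subjects failed")

    report = pd.DataFrame(rows)
    atlas = percentage_overlap(maps, threshold_pct=config.atlas_threshold_pct)

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "cohort_report.tsv", sep="\t", index=False)
        tio.write_volume(atlas.volume, out / "atlas_overlap_pct.nii.gz")
        tio.write_volume(atlas.thresholded(), out / "atlas_overlap_thresholded.nii.gz")
        config.to_json(out / "run_config.json")
        summary = {
            "n_subjects": len(subjects),
            "mean_S": float(np.nanmean(report["S"])),
            "sd_S": float(np.nanstd(report["S"], ddof=1)) if len(report) > 1 else None,
            "mean_bundle_length_cm": float(np.nanmean(report["mean_bundle_length_cm"])),
            "failures": failures,
        }
        (out / "cohort_summary.json").write_text(json.dumps(summary, indent=1))

    return CohortResult(report=report, atlas=atlas, subjects=subjects, failures=failures)
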