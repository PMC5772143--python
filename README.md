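# tractlife

Ensemble probabilistic tractography, linear fascicle evaluation (LiFE) and
virtual-lesion statistics, implemented and validated end-to-end on synthetic
diffusion-MRI phantoms.

## What this package is for

Identifying a short, curved white-matter tract (a U-fibre system wrapping
around a sulcus, such as the stratum proprium of the interparietal sulcus,
SIPS) with diffusion tractography is delicate: the tract crosses major
fasciculi, and a single tracking-parameter setting either misses its sharp
curvature or floods the result with spurious streamlines.  The analysis
chain implemented here addresses that with:

1. **Ensemble tractography** — CSD-based probabilistic tracking repeated
   under four per-step angular thresholds (5.7°, 11.5°, 23.1°, 47.2°; step
   0.2 mm, FOD amplitude stopping criterion 0.1, lengths 10–200 mm),
   seeded from the grey/white-matter interface.
2. **LiFE** — each single-setting connectome predicts the demeaned
   diffusion attenuation `y ≈ M w` with non-negative streamline weights
   `w`; per-streamline columns of `M` are mean stick attenuations
   `exp(−b d∥ (θ·t)²)` over the voxels each streamline traverses.  The top
   contributing streamlines of each setting are merged into the **ensemble
   tractography connectome (ETC)** and re-optimised jointly.
3. **Tract segmentation** — streamlines whose two *terminal* points end
   within 3 mm of the two grey-matter ROIs (pass-throughs excluded),
   refined by three outlier rules (≥3 SD over-length, <15 mm, ≥3 SD
   positional deviation from the mean tract).
4. **Virtual lesion** — remove the tract, re-optimise the remaining
   path-neighbourhood streamlines in its voxels, and compare per-voxel
   cross-validated accuracy `R_rmse` (model-vs-session-2 RMSE over
   session-1-vs-session-2 test–retest RMSE) with and without the tract.
   The strength of evidence is
   `S = (mean R_rmse^lesioned − mean R_rmse^unlesioned) / pooled SD`.
5. **Probabilistic atlas** — per-subject binary visitation maps,
   affine-normalised to a template grid, averaged into a percentage-overlap
   atlas (displayed above a strict 25% threshold).

Because the original human datasets are not redistributable, the package
ships a first-class **phantom module**: a curved U-bundle terminating under
two cortical ROI patches, a straight distractor crossing its apex at ~90°,
a two-session single-shell acquisition (64 directions, b = 1000 s/mm²,
two b = 0 volumes, 2-mm voxels) and Rician noise.  Every stage is tested
against this ground truth.

## Worked example

The numbered scripts under `analysis/` run the chain step by step on one
phantom and write their tables under `results/`:

```bash
python analysis/01_make_phantom.py
python analysis/02_fit_local_models.py
python analysis/03_track_ensemble.py
python analysis/04_optimize_connectome.py
python analysis/05_segment_and_endpoints.py
python analysis/06_virtual_lesion.py
python analysis/07_cohort_atlas.py
```

Representative output (seed 1):

```
 angular_threshold_deg  n_seeded  n_surviving  mean_length_mm
                   5.7      2000         1021       20.499510
                  11.5      2000         1389       38.679194
                  23.1      2000         1550       47.741161
                  47.2      2000         1565       51.570479

           setting  n_candidates  n_contributing  objective
candidates_ang11.5          1389             571  29.040463
...
ETC (re-optimised)          1834             804  20.018715

  segmented 190 streamlines, 190 after outlier removal
  mean length 6.11 cm (SD 0.39)

  mean_R_rmse_unlesioned: 0.8341
  mean_R_rmse_lesioned: 1.017
  S: 0.7554
```

Reading this: tighter angular thresholds lose the curved bundle (shorter
surviving streamlines at 5.7°), the jointly re-optimised ETC explains the
signal better than any single setting (lowest objective), the segmented
bundle tracks the ~5.3 cm ground-truth centerline, and lesioning it
degrades held-out prediction accuracy in its voxels (`R_rmse` rises from
0.83 to 1.02, S > 0).  The phantom's S is positive but far smaller than
values reported for in-vivo tracts, as expected at desk scale: a
30³-voxel phantom with thousands (not millions) of candidate streamlines
leaves more redundancy in the path neighbourhood relative to the lesioned
evidence.

The cohort driver (`07`) additionally prints per-subject rows and the
atlas overlap lattice (e.g. `{0, 33.3, 66.7, 100}` for three subjects).

## Layout

```
src/tractlife/
  core.py           spatial types: grids, volumes, labels, tractograms
  io.py             NIfTI, bvals/bvecs, TCK/TRK, affine text files
  harmonics.py      real even-order spherical harmonics, sphere samples
  phantom.py        synthetic two-session phantom with ground truth
  local_model.py    tensor fit, single-fiber response, CSD, peaks
  tracking.py       probabilistic tracking (numba kernel), ensembles
  fascicle_eval.py  LiFE model, NNLS, ETC, R_rmse, virtual lesion
  bundle_ops.py     endpoint segmentation, outliers, density, proximity
  atlas.py          visitation maps, normalisation, percentage overlap
  pipeline.py       per-subject and cohort orchestration
analysis/           numbered narrative drivers (write under results/)
docs/methods.md     model and design notes
```
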