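# Methods

This note documents the models, parameter choices and numerical decisions
behind `tractlife`, in the spirit of the methods sections of the
simulation and statistics packages this one resembles.

## The phantom and what it does (and does not) emulate

The synthetic subject is a 30³ grid of 2-mm isotropic voxels containing:

* a **U-bundle**: a semicircular arc of radius 15 mm (plus 3-mm straight
  extensions toward grey matter, total centerline ≈ 53 mm — within 20% of
  the ~47 mm mean length of the short parietal tract the geometry
  emulates), tube radius 3 mm, terminating beneath two spherical
  grey-matter ROI patches ("superior-parietal-like" and
  "supramarginal-like", radius 5 mm);
* a **straight distractor bundle** of the same tube radius crossing the
  U-bundle's apex at ~90°, with its own pair of distractor ROIs;
* isotropic background everywhere else.

Per-voxel ground truth holds each bundle's unit tangent (tangent of the
nearest centerline point) and a volume fraction equal to the fraction of
27 regular within-voxel subsamples falling inside the tube (normalised to
sum ≤ 1 where tubes overlap).  The forward signal is the standard
multi-compartment stick/tensor model

S(θ, b) = s0 [ f_iso e^(−b d_iso) + Σ_k f_k e^(−b (d_r + (d_a − d_r)(θ·t_k)²)) ]

with defaults d_a = 1.7e−3, d_r = 0.2e−3, d_iso = 3.0e−3 mm²/s and
s0 = 100 — typical white-matter/CSF literature values; the source protocol
states none.  The acquisition is two repeats of 64 directions at
b = 1000 s/mm² plus two b = 0 volumes (Fibonacci-hemisphere directions).
Rician noise (two Gaussian channels in quadrature) is applied per session;
the default σ = 2 (2% of s0, SNR ≈ 50 at b = 0) was chosen once as a
realistic single value since no noise level is stated anywhere for the
emulated acquisitions; tests sweep σ ∈ {0.5, 1, 2}.  Each cohort
"subject" draws an independent ±1.5 mm rigid jitter of the whole assembly
plus independent noise; the inverse jitter is the subject-to-template
affine used by the atlas stage, standing in for b=0-to-template
registration (registration *estimation* is out of scope).

What the phantom deliberately does not emulate: cortical folding,
susceptibility/eddy artefacts, multi-shell acquisitions, and realistic
crossing-fibre density outside the single planned crossing.  Passing
tests therefore demonstrate correctness of the *computational chain* and
its behaviour under known truth, not in-vivo effect sizes — the
strength-of-evidence values on the phantom are positive but much smaller
than published in-vivo values, because at desk scale the optimised
connectome retains proportionally more redundant evidence in each voxel.

## Local models

**Tensor.** Log-linear least squares on log-attenuations (signals clamped
at 1e−6·s0), eigen-decomposition per voxel, FA by the standard
normalised-variance formula.  Scale invariance follows from using
attenuations relative to mean b = 0.

**Single-fiber response.** Voxels with FA ≥ 0.7 are rotated so their PDD
aligns with +z and their attenuation is projected onto the zonal even SH
basis; the response is the mean over voxels.  With fewer than 20
candidate voxels the analytic stick response (Gauss–Legendre projection
of the stick attenuation) is used with a warning.  Any scheme satisfying
the recovery oracles would do; this one is simple and deterministic.

**CSD.** Real, even-order, orthonormal SH basis with (l, m) ordering
l = 0,2,…,lmax; m = −l…l (lmax = 8 → 45 coefficients).  Forward
convolution by Funk–Hecke factors √(4π/(2l+1)) r_l.  Non-negativity via
iterated constrained least squares: rows of a 724-point antipodally
symmetric Fibonacci sphere whose current FOD amplitude falls below
τ = 0.1 × (mean initial amplitude) are penalised with weight λ = 1;
iteration ends when the constraint set is stable or after 50 rounds
(non-converged voxels are flagged and kept).  Bit-compatibility with any
external CSD implementation is a non-goal; the oracles are angular:
single-fiber recovery < 2°, 90° crossing < 10°, isotropic suppression.

**Peaks.** Local maxima over the 724-point sphere (16° neighbourhood)
refined by hierarchical cap-grid ascent (8° → 0.125°), antipodally
canonicalised (first nonzero component ≥ 0), merged below 25° separation
keeping the larger, thresholded at 10% of the largest peak.

## Tracking

Bidirectional probabilistic tracking on the FOD.  The first direction at
a seed is drawn from the full sphere; subsequent directions are drawn
categorically, probability ∝ FOD amplitude (trilinearly interpolated SH
coefficients evaluated on the fixed sphere sample), restricted to the
cone of the per-step angular threshold and to amplitudes ≥ the stopping
criterion (0.1).  A half terminates on leaving the white-matter mask
(nearest-voxel lookup; the exiting point is kept so endpoints reach
toward grey matter), on amplitude failure, or at the length cap; each
half is capped at ⌊(max_length/step)/2⌋ steps so the assembled streamline
respects the total 200-mm maximum.  Streamlines shorter than 10 mm are
discarded.  The stepping loop is a numba kernel; a given seed yields
bit-identical output, and ensemble settings use distinct derived seeds.
Candidate counts are configuration: the protocol's 2,000,000 per setting
is represented by a desk-scale default of 5,000.

## LiFE, R_rmse, virtual lesion

Design-matrix columns use the stick attenuation e^(−b d∥ (θ·t)²) with
d∥ = 1.7e−3 mm²/s (configurable), averaged over a streamline's segments
per voxel and **demeaned across each voxel's diffusion-weighted
directions**; the data vector is the attenuation (signal over mean b = 0)
demeaned identically.  Whether demeaning should operate on raw signals or
attenuations is not specified by the protocol this follows; attenuations
make the model scale-free and are adopted throughout.

The NNLS solver is an accelerated projected-gradient method with step
1/λ_max(MᵀM) (power iteration) and a monotone safeguard: an accelerated
step that would increase the objective is replaced by a plain projected
gradient step, so the recorded objective history never increases.
Convergence: relative objective decrease < 1e−6 or the iteration budget
(300 for single-setting prefits, 600 for the ETC refit at the default
desk scale).  Correctness is checked against exhaustive active-set
enumeration on random 30×10 problems.

"Contributed meaningfully" for ETC preselection is implemented as top-k
by weight among positive weights (default k = 1250 per setting, the
desk-scale analog of 150,000 of 2,000,000); the ETC is the concatenation
of the four pruned sets, re-optimised jointly.

R_rmse per voxel = RMSE(model prediction, session-2 demeaned attenuation)
/ RMSE(session-1, session-2 demeaned attenuations); the model is fitted
on session 1 only.  Voxels with test–retest RMSE < 1e−12 are excluded and
counted (with zero noise every voxel is excluded and the subject is
reported degenerate rather than crashing).  The virtual lesion removes
the bundle's columns, re-optimises only the remaining path-neighbourhood
columns on the bundle-voxel rows (a full-connectome refit is neither
described by the protocol nor tractable), and
S = (mean lesioned − mean unlesioned) / √((var_l + var_u)/2) —
"joint standard deviation" is read as the pooled SD (sample variances,
ddof = 1); a bundle whose weights are all zero returns S = 0 with a flag.

## Segmentation and outliers

Endpoint rule: only *terminal* points are tested, within 3 mm (Euclidean,
mm, to voxel centers) of each of the two ROIs; the source description's
"within two/three voxels" parenthetical is treated as commentary — the
3-mm figure governs.  The three outlier criteria are applied in the order
min-length (15 mm) → over-length (> mean + 3 SD) → position, each on the
statistics of the set entering that step (the order is not prescribed;
removing degenerate fragments first keeps the SD statistics meaningful).
Boundary cases sit exactly at the 3-SD cut and are kept (strict
inequality), which makes the zero-variance bundle a no-op as expected.
The position rule resamples each streamline to 100 equidistant nodes
(the along-tract convention of the fiber-quantification toolchain),
orients them by an anchor point (the ROI-A centroid in the pipeline; the
first streamline's orientation otherwise), and removes streamlines whose
mean node distance to the mean streamline exceeds the mean of those
distances by 3 SD.  Re-applying the rules can cascade (statistics shrink);
idempotence is deliberately not claimed — instead the final set is
verified clean under rules (1) and (2).

## Atlas

Visitation maps resample streamlines to ≤ half-voxel steps before
nearest-voxel marking, guaranteeing 26-connected paths.  Normalisation to
the template grid is nearest-neighbour (pull-style, via the inverse
affine) to preserve binarity; interpolation is not specified by the
protocol and partial-volume averaging was rejected because the overlap
atlas is defined on binary maps.  Percentage overlap is the per-voxel
mean × 100, so values lie on the lattice {0, 100/n, …, 100} and satisfy
mass conservation; the display threshold zeroes values ≤ 25% (strict
"greater than").

## Pipeline scale and seeds

Per-subject seeds derive from the master seed by
`(master·100003 + 7919·(i+1)) mod (2³¹−1)`; every stochastic stage
records its seed in provenance, and identical seeds reproduce identical
outputs byte-for-byte.  The default cohort (6 subjects — mirroring the
six-volunteer cohort structure of the emulated study — at 5,000
streamlines per setting, k = 1250) runs in roughly 8 minutes on one CPU;
the analysis drivers use 2,000/setting and 3 subjects to stay in the
couple-of-minutes range.  These sizes are the package's desk-scale study
conditions, chosen once; all protocol-stated parameters (step size,
angular thresholds, stopping criterion, length limits, 3-mm endpoint
rule, outlier thresholds, proximity thresholds 3/4.5 mm, atlas
threshold 25%) keep their stated values as defaults.

## Known limitations

* Single-shell only; multi-shell/multi-tissue CSD is out of scope.
* The CSD response is rotationally symmetric by construction; no
  per-bundle response heterogeneity.
* Tracking interpolates SH coefficients trilinearly and looks up masks at
  the nearest voxel; sub-voxel mask geometry is not honoured.
* The lesioned-model refit is restricted to the path neighbourhood and
  lesion voxels; S values are therefore comparable within a configuration
  but not across refit policies.
* Phantom S values are one to two orders of magnitude below published
  in-vivo values; only sign and ordering properties are asserted.
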