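# Methods

This note documents the models, calibrations and numerical conventions behind
`phrenicmap`, and what its synthetic-data results do and do not demonstrate.

## The measurement being reproduced

The clinical analysis pairs each endocardial pace-mapping site with the
shortest 3D distance to the CT-delineated right phrenic nerve, after rigidly
merging the electroanatomical map with CT. Sites carry a five-level ordinal
capture-threshold category (≤10, >10–≤20, >20–≤30, >30–≤50 mA at 2 ms, or
non-capture at 50 mA). The statistics of interest are the per-category
distance summaries, the Spearman correlation between category and distance,
and the ROC / sensitivity–specificity panel for predicting distance > 10 mm
(a lesion with ~6 mm radius cannot plausibly reach a nerve beyond 10 mm).

Because the clinical raw data are not deposited, the package reproduces this
analysis on two kinds of synthetic data, each a first-class, tested module.

## Distance convention

All distances are measured to the nerve **centerline** polyline, in
millimetres. The alternative — distance to the surface of the
pericardiophrenic bundle — would be systematically smaller by the bundle
radius; the source analysis does not state which it used. Centerline is the
default throughout; mesh-surface distance is available via
`point_to_mesh_distance` for anyone wanting the other convention. Polyline
distance ties between segments break to the lowest segment index, making all
outputs deterministic.

## Map–CT fusion

The clinical merge used an unpublished custom program. Here the merge is
defined as paired-landmark Kabsch initialization (the four PV-ostium centers
plus the chamber centroid as fiducials) followed by point-to-point ICP with
nearest-neighbour correspondence. There is no scale term: both frames are
metric. On synthetic clouds related by a true rigid motion of ≤10° / ≤5 mm,
ICP recovers the motion to within 0.5° / 0.5 mm (verified in the test suite).
No registration accuracy figure exists for the clinical merge, so instead of
claiming one, `perturb_transform` supports a sensitivity study: the pipeline
reports how site-to-nerve distances move under controlled rotation/translation
perturbations. A pure translation of k mm can change any point-to-set
distance by at most k mm (the distance map is 1-Lipschitz), which the
geometric scenario asserts numerically.

## Volume encoding of the nerve

The nerve path is written into the attenuation volume as a curved tube at
900 HU with diameter = 5 voxels × mean spacing, mimicking the clinical trick
of overwriting CT with a bright marker to make segmentation trivial. The
"5 pixel" width is interpreted as a 3D isotropic tube diameter (the in-plane
vs 3D question is undefined in the source; the parameter is exposed).
Conventions: axis-aligned grids only, voxel index = voxel center,
world = origin + index × spacing; NIfTI-1 I/O. A voxel is marked iff its
center lies within the tube radius of the centerline, so the marked set is a
discrete capsule (cylinder plus hemispherical end caps).

Segmentation is a plain ≥850 HU threshold — midway between bone-range
background and the 900 HU marker; the synthetic background (soft-tissue
ellipsoid at ~40 HU in −1000 HU air) makes the separation exact, so
segmentation∘rasterization recovers the written voxel set identically.

Centerline extraction orders voxel centers by projection on the first
principal axis, averages them in one-voxel bins (local centroid smoothing
over about a tube diameter), chains bin centroids by greedy nearest
neighbour, and finally trims one estimated tube radius
(r̂ = √(voxel volume / π·length)) from each end to remove the capsule
end-cap overshoot. Accuracy, verified by round-trip tests: Hausdorff error ≤
one voxel diagonal for gently curved paths (curvature radius ≥ 20 mm), and
propagated site-distance error ≤ one voxel diagonal per site, decreasing with
voxel size over 2 → 0.25 mm. The greedy chaining assumes the path is roughly
monotone along its first principal axis — true for phrenic-like, gently
curved courses, not for loops or hairpins.

## Capture model

True threshold at distance d (mm) and pulse width pw (ms):

    T(d, pw) = (I_rh + k·d²) · (1 + τ_ch / pw)

the Weiss–Lapicque strength–duration law times a quadratic strength–distance
term (far-field point-source approximation). Chronaxie τ_ch defaults to
1.5 ms, the reported phrenic value, so pacing at 2 ms sits near the rheobase
plateau. Observed thresholds are T times lognormal noise exp(σ·Z) —
multiplicative because thresholds are positive and dispersion grows with
magnitude — then binned by the protocol with inclusive upper edges (a
threshold of exactly 10 mA is "≤10 mA").

The source analysis fits no such model; this one exists so the geometric
scenario produces a threshold–distance relationship with realistic overlap.
`calibrate_capture_params` fits (I_rh, k, σ) by Nelder–Mead with common
random numbers so that simulated category-wise mean distances match the five
published means (equal category weights). Fitted on the geometric scenario's
distance field this lands all five means within 1.5 mm of the published
7.5 / 8.6 / 11.5 / 16.5 / 19.2 mm. The package defaults
(I_rh = 3.5 mA, k = 0.11 mA/mm², σ = 0.80) are one such calibrated fit,
frozen; the large σ is what the near-identical ≤10 mA and ≤20 mA category
means demand. The published overlap plausibly also reflects non-spherical
virtual-electrode geometry, perinervous fat and merge error, all of which the
iid noise term absorbs without distinguishing.

## Synthetic anatomy

The endocardial shell is an icosphere scaled to semi-axes 30 × 25 × 25 mm
(left-atrium scale); four PV ostium landmarks sit on the right (+x, septal)
and left (−x) aspects with short tube stubs carried separately so the shell
stays watertight for inside/outside tests. The nerve follows a jittered
meridian on the septal aspect, offset outward along the surface normal by a
smooth clearance profile dipping to 1.2 mm near the right-superior-PV level
and growing to ~32 mm at both ends — reproducing the reported clearance span
of ~1 mm to beyond 3 cm. Pacing sites are sampled area-uniformly on the
septal patch facing the nerve course, so site distances span that same range.
Everything is deterministic per seed.

## Calibrated cohort generator

The statistical scenario needs per-category distance distributions matching
the published summaries: n = 74/319/135/197/308 sites with mean ± SD
(minimum) of 7.5±3.0 (1), 8.6±4.5 (2), 11.5±3.7 (4.1), 16.5±4.5 (5.7),
19.2±6.5 (9.4) mm. Each category is modelled as a normal truncated below at
the printed minimum, with the parent (μ, σ) solved from the truncated-moment
equations so the *post-truncation* mean and SD equal the printed values
(residuals < 1e-6; Monte-Carlo verified at 10⁶ draws). Truncation is not a
nicety: untruncated normals would place non-capture sites at 2–5 mm, which
the printed minima exclude, and would understate the high-output cutoffs'
specificities. Region labels follow the published 872/161 LA vs SVC/RA split
independently of category, and sites scatter over 45 synthetic patients
(mean 23 sites/patient); all statistics pool sites, mirroring the site-level
source analysis. The printed SDs are treated as site-level.

Under this generator, 200 replicate cohorts of 1033 sites give replicate
means of AUC ≈ 0.861, Se/Sp at the four cutoffs within ≈1–2 points of the
published panel, ρ ≈ 0.696 and a ≤10 mA category mean of ≈ 7.51 mm — i.e.
the published diagnostics are consistent with exactly their printed
per-category distance summaries plus truncated normality, with no further
tuning. That is also precisely what passing tests show, and no more: the
generator encodes the published *marginal* distance structure, not real
anatomy, operator behaviour, intra-patient correlation, or CT delineation
error.

## Statistics

- Percentages print to 1 decimal, proportions to 3, matching report
  precision. (Recomputing the category shares from the printed counts gives
  7.2 / 30.9 / 13.1 / 19.1 / 29.8%; the 319-site row is printed elsewhere as
  30.1%, which is not 319/1033 — the package reports the arithmetic value.)
- Spearman ρ uses mid-rank ties (the predictor has only five levels).
- Group comparisons are Welch two-sided t-tests on sites; no
  multiple-testing correction is applied (none was in the source analysis).
- AUC is the tie-corrected Mann–Whitney estimator with the ordinal category
  as predictor (non-capture ranked highest); it equals the concordance
  double loop exactly. The CI is a nonparametric bootstrap percentile
  interval over sites (2000 resamples by default); the source bracket's
  method is unstated, so only the point estimate is compared.
- Sensitivity at cutoff c is P(category above c | distance > 10 mm),
  specificity P(category at/below c | distance ≤ 10 mm); the four cutoffs
  are nested, so Se is non-increasing and Sp non-decreasing across them.
- Degenerate inputs: single-record categories report SD 0 with a flag;
  constant inputs to Spearman are flagged invalid; zero-variance t-tests and
  single-class ROC raise.

## Problem sizes and seeds

Default replicate count is 200 cohorts (Monte-Carlo error ≈ 0.001 on AUC,
well under the reporting precision). The geometric scenario defaults to
1 mm voxels and a few hundred sites; the test suite uses 1–1.5 mm voxels
with 100–500 sites and a 0.25 mm grid only on a short tube for the
convergence check. Seeds are split per stage/replicate with
`numpy.random.SeedSequence`, so every stage is independently reproducible
and two runs with the same seed produce identical tables.

## Known limitations

- Quadratic strength–distance with iid lognormal noise is a phenomenological
  stand-in, not a biophysical nerve model (no cable equation, no dog-bone
  virtual-electrode shape, no anisotropic fat shielding).
- The anatomy is an ellipsoid with stub ostia, adequate for distance and
  registration geometry, not for morphological realism; there is no
  inter-patient variability beyond seed jitter of the nerve course.
- Only the four-level differential protocol is simulated; operators
  sometimes refined thresholds further, a behaviour with unknown frequency.
- The calibrated generator draws region and patient labels independently of
  distance, so it cannot support region-specific or clustered inference.
- ICP here is point-to-point on clean clouds; real map/CT fusion contends
  with partial overlap and deformation that this registration does not model.
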