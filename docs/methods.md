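# Methods

`cortexratio` implements an intracortical T1w/T2w ratio analysis for
staged cohorts (healthy controls, two premanifest and two manifest
disease groups) together with a synthetic phantom-cohort generator that
supplies every input the analysis needs, plus ground truth for scoring
each stage.

## The measurement model

A structural MRI voxel intensity is modelled as

    I_c(x) = s_c · B_r(x) · B_t,c(x) · μ_c(tissue(x)) + ε_c(x)

for contrast `c ∈ {T1w, T2w}`: a global scanner/site scale `s_c`, a
smooth multiplicative receive field `B_r` *shared* by both contrasts, a
smooth transmit-related field `B_t,c` *specific* to each contrast, the
clean tissue intensity `μ_c`, and measurement noise. The voxelwise
ratio `T1w/T2w` cancels `B_r` exactly and amplifies myelin-related
contrast (myelin raises T1w and lowers T2w signal). The pipeline's
quantity of interest is the ratio sampled at mid-cortical depth,
averaged per ROI, and compared across disease groups with age and site
as covariates.

## Pipeline stages

1. **Rigid registration** of the T2w image onto the T1w grid:
   normalized cross-correlation over the fixed-image foreground,
   optimized with a derivative-free Powell search over three resolution
   levels (downsampling factors 4/2/1), rotation centered at the
   foreground's center of mass. Adequate for the small within-session
   offsets simulated (≤ a few mm / degrees); phantom recovery is ≲0.1 mm
   and ≲0.3° at 2 % noise.

2. **Local intensity normalization** of T1w for segmentation only: the
   image is divided by a smoothed local-maximum field (3³ maximum
   filter, 10 mm FWHM Gaussian). The smoothing is confined to the
   bright-reference support (max-filter values above an Otsu split),
   with renormalized weights: the field then tracks the local
   white-matter brightness envelope — exactly what multiplicative B1
   bias modulates — without being dragged down by CSF and background,
   which would otherwise compress GM/WM contrast near boundaries. The
   normalized image never enters the ratio; a dataflow test asserts
   that scaling T1w rescales the final ratio proportionally.

3. **Cerebrum mask**: histogram threshold (deepest valley between the
   darkest mode and the next one, Otsu fallback when no adequate valley
   exists), then a fixed morphological recipe at doubled resolution:
   unsharp sharpening, threshold, removal of small components, one
   erosion and one dilation with a 6-connected cross. The downsampling
   back to the original grid is inclusive (overlap > 0.25) and the same
   threshold is re-applied so that the *threshold*, not interpolation
   round-off, sets the final boundary; the dominant connected component
   is kept. The dura shell, disconnected from the brain by
   sub-threshold CSF, is removed by the component logic.

4. **Tissue classification**: two-class fuzzy c-means (m = 2) on the
   masked normalized image with a neighbourhood membership-smoothness
   penalty (6-neighbour stencil; weight `spatial_beta`, scaled by the
   intensity variance so it is unit-invariant). Centroids initialize
   from the 25th/75th intensity percentiles, convergence at centroid
   shift < 1e-4, cap 200 iterations. With `spatial_beta = 0` the
   update is the classical alternating minimization and its objective
   decreases monotonically (asserted in tests); with the spatial
   penalty the membership update treats neighbours as fixed (ICM
   style), so only overall improvement is guaranteed.

5. **Cortical depth**: Laplace's equation relaxed over the GM ribbon
   with Dirichlet data on the boundary tissue (WM = 0, CSF/background
   = 1), red-black Gauss–Seidel, tolerance 1e-5 on the largest update,
   cap 5000 sweeps. Boundary arms use a Shortley–Weller stencil whose
   interface location is found sub-voxel as the half-level crossing of
   a lightly smoothed (σ = 1 voxel) tissue indicator; this anti-aliases
   the voxelized surface and roughly halves the depth error against the
   spherical-shell closed form `(1/a − 1/r)/(1/a − 1/b)` (max ≈ 0.02 vs
   ≈ 0.04 with face-midpoint arms at the sizes used here). An optional
   equivolume reparameterization maps depth to the local cumulative
   volume fraction using boundary-area proxies from the depth
   gradient (flux conservation: area ∝ 1/|∇u| at the boundary); it is
   off by default — the mid-depth band uses the equidistant 0.5 level —
   and for a spherical shell its fraction-0.5 surface sits at
   `((a³+b³)/2)^{1/3}`, *outward* of the equidistant midpoint.

6. **Mid-depth shell**: ribbon voxels with |depth − 0.5| ≤ 0.1 (the
   half-width guarantees ≥ 1 voxel thickness for a 3 mm ribbon at 1 mm
   spacing). ROI identifiers are copied voxelwise from the phantom's
   ground-truth parcellation — the phantom stand-in for surface-based
   inter-subject registration, which is out of scope.

7. **Bias field and ratio**: the residual field is estimated as
   `sqrt(T1w·T2w)` inside the cerebrum mask (inverted tissue contrast
   cancels to first order, leaving the smooth shared bias), normalized
   to unit mean, then smoothed within the mask with a Gaussian of
   σ = 5 mm (this kernel is specified as a standard deviation; the
   10 mm normalization and 6 mm shell kernels are FWHM). Normalization
   precedes smoothing, and the unit mean is re-enforced afterwards.
   Both contrasts are divided by the field and the ratio is T1w/T2w
   with a denominator floor at the 1st percentile of T2w in the mask;
   floored voxels carry NaN and never enter ROI means. Because the
   same field divides both contrasts, this step cannot disturb the
   ratio — receive-bias cancellation in the ratio is an algebraic
   identity that the acceptance suite verifies end to end at 1e-10.

8. **On-shell smoothing**: Gaussian weights (FWHM 6 mm) in 3D distance
   between shell voxels, truncated at 3σ, renormalized over in-shell
   neighbours — constants pass unchanged and no signal leaks across
   CSF or WM. The sparse kernel is built once per anatomy and reused
   across subjects.

9. **Group statistics**: per subject×ROI means and within-ROI SDs of
   the smoothed shell signal; subjects whose whole-cortex mean ratio
   lies outside the cohort mean ± 1.5 SD are excluded once ("gain
   difference" rule). Each ROI is fit with weighted least squares,
   `Signal ~ Age + Site + Group` (treatment coding, Control reference),
   two-sided p-values per group level; Holm–Bonferroni across ROIs,
   separately within each group level, at α = 0.05.

### Regression weights

The weighting rationale is that subjects with more image artifacts
should count less. Three schemes are implemented:

* `per_subject` (default): one weight per subject — the inverse of the
  median, across ROIs, of that subject's within-ROI voxel SDs. The
  artifact severity being a property of the scan, pooling across the
  82 ROIs gives nearly noise-free weights.
* `per_subject_roi`: the literal per-cell reading, `1/sd` of each
  (subject, ROI) entry. Each weight is then estimated from only a few
  dozen voxels; on null phantom cohorts this weight noise measurably
  misestimates the WLS standard errors and inflates the family-wise
  error above its nominal level, which is why it is not the default.
* `per_roi`: one weight per ROI (inverse across-subject SD), identical
  to OLS coefficients.

All weights are floored at the cohort 5th percentile of within-ROI SDs
to bound the largest weight.

## The phantom cohort

Geometry is a nested-ellipsoid head: WM core, 3 mm GM ribbon, 2 mm CSF
gap, 1 mm dura shell, with a sinusoidal angular perturbation (3 % of
radius, 3 cycles) so the cortex has nonzero curvature. The GM ribbon is
parcellated into R = 82 contiguous angular sectors (equal-area rings ×
azimuthal bins). The "standard" test subject scales the radii to ~2/3
of the field of view, mirroring the real-data regime in which the 10 mm
and 5 mm kernels are small relative to the head.

Per-subject corruption, in order: site-specific global intensity scales
(lognormal, log-SD 0.05 per contrast); an age trend on the clean GM
ratio (−0.001 per year, realized through T2w); group effects — the
clean ratio in each targeted ROI is raised by exactly (1+δ) by dividing
T2w, so truth bookkeeping is exact; bias fields as exponentials of
random degree-2 polynomials (receive amplitude 0.15 shared across
contrasts; transmit amplitude 0.0075 per contrast, independent between
them, leaving a ~1.5–2 % residual ratio bias after the sqrt-product
correction, in line with what that correction leaves on real data).
Each field is the product of a site-level component drawn once per site
and shared by its subjects — the scanner character the Site regressor
absorbs — and a per-subject component, each carrying half the
log-variance; additive Gaussian noise (σ = 2 % of the mean GM T1w intensity; Rician
available); an optional small rigid T2w misalignment. A per-subject
lognormal artifact factor (log-SD 0.4) jointly scales the noise level
and the transmit amplitudes — subjects genuinely differ in scan
quality, which is the variance structure the 1/SD regression weights
are designed to exploit.

Cohort defaults: five groups × two sites, group sizes per site
{Control 10, PreHD-A 5, PreHD-B 5, HD1 6, HD2 4} in the acceptance
studies (≈ the staging proportions of the real multi-site cohort at
n = 60), ages drawn per group with the published group means/SDs.

### What the phantom does not emulate

No gyrification or realistic folding (ROI contiguity and curvature are
exercised, deep sulci are not); no sequence signal equations, k-space
or motion artifacts; clean volumes are piecewise constant (no partial
volume or intra-tissue texture); all subjects share one anatomy, so
inter-subject registration is trivially exact by construction. Passing
tests therefore demonstrate correctness of the algorithms under the
stated measurement model, not performance on real folded cortex.

## Replicate-study design and problem sizes

Cohort-scale studies (20 replicate effect cohorts with δ = 0.05 in six
ROIs for the two manifest groups, and 20 replicate null cohorts) run at
48³ × 1 mm with ground-truth masks and alignment, sharing the geometry
stage across subjects and replicates; this keeps a 40-cohort study in a
few minutes on one CPU. Registration and segmentation estimation are
validated separately on single 64³ subjects, including a full-chain
run (normalize → strip → segment → depth → bias → ratio) for the
bias-cancellation identity. The choice isolates each stage's error
rather than re-estimating identical anatomy 2400 times.

## Numerical choices and degenerate inputs

* Kernel conventions: 10 mm (normalization) and 6 mm (shell smoothing)
  are FWHM; 5 mm (bias field) is a standard deviation.
* Division guards: normalization flags voxels where the smoothed
  reference support is negligible; the bias field has a positivity
  floor; the ratio uses a quantile denominator floor and NaN markers.
* The histogram threshold requires a valley dipping below 75 % of both
  flanking modes, otherwise Otsu is used and flagged.
* FCM requires at least two distinct intensities; ties in centroid
  initialization fall back to the data range.
* The Laplace solver refuses ribbon voxels with no path to both
  boundaries (topology error listing offenders).
* QC with zero cohort SD excludes nobody and warns; `k = inf` is a
  no-op.
* Degenerate equivolume area proxies fall back to the unadjusted depth
  with a warning.

## Known limitations

* The volumetric mid-depth band replaces the triangulated mid-depth
  surface and mesh registration of surface-based pipelines; ROI
  transfer relies on phantom truth.
* NCC registration is validated for small same-subject offsets only;
  no deformable or cross-modality registration.
* The spatial FCM penalty is ICM-style; no convergence proof, only the
  empirical descent checked in tests.
* Transmit-field differences between contrasts do not cancel in the
  ratio — this residual is simulated and absorbed into the error term,
  not corrected, matching the method's real limitation.
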