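# Methods

This note documents the models and algorithms behind `t1morph`, the
parameter choices that matter, what the phantom generator does and does
not emulate, and the known limitations.  All quantitative statements here
are computed by the test suite or `scripts/acceptance.py`; none are taken
on faith.

## The phantom generator

Every stage is validated against synthetic brains with exact ground
truth.  A phantom is a star-shaped "cortex": a white-matter core whose
radius is `R(θ, φ) = wm_radius + fold_amplitude · sin(f·θ) · sin(f·φ)`, a
gray-matter shell containing all points within `gm_thickness` (Euclidean
distance) of the core — hence constant *normal* thickness even where the
surface folds — and a CSF shell of `csf_thickness` (default 3 mm) beyond
that.  Tissue fractions are computed by 3×3×3 supersampling of every
voxel (quantization error ≤ 1/27 per fraction); for folded cores, the
distance to the core is an exact Euclidean distance transform on the
supersampled mask with a half-sample flat-interface correction.

The image is the fraction-weighted mixture of the class means (defaults
40/80/120 for CSF/GM/WM, the T1-weighted ordering), multiplied by a bias
field and corrupted with seeded Gaussian noise.  Conventions:

* **Noise** — `noise_percent` is the Gaussian sigma as a percentage of
  the WM mean, matching the convention of simulated-MRI ground-truth
  resources.  Gaussian (not Rician) noise: at the simulated SNRs the
  difference is negligible and the sigma oracle stays exact.
* **Bias** — the lowest-order separable polynomial, a linear ramp along
  the first axis, scaled to `bias_percent` peak-to-peak across the grid.
* **Determinism** — a phantom is a pure function of its spec; identical
  specs produce bit-identical volumes.

Geometry defaults (10 mm core, 4 mm ribbon, 48³ grid at 1 mm) keep a full
segmentation + surface run under ~5 s so that sweeps over noise levels,
resolutions and cohorts stay cheap; they are one order of magnitude
smaller than a human head but preserve the ratios that matter (ribbon
thickness of 3–4 voxels, folds comparable to sulcal widths).

What the phantom does *not* emulate: skull and scalp (no skull-stripping
stage is needed or provided), Rician noise floors, motion ghosting,
multi-coil inhomogeneity patterns, and the topological complexity of a
real cortex (handles, fused gyri).  Passing tests therefore demonstrate
algorithmic correctness under controlled conditions, not clinical
robustness.

Cohorts plant a known group effect: group B's `gm_thickness` is reduced
by `atrophy_percent`, and every subject receives seeded 2% jitter on
`wm_radius` and the intensity means, emulating anatomical and scanner
variability.  A random diffeomorphism generator (Gaussian-filtered random
velocity, exponentiated by scaling-and-squaring) supplies registration
ground truth with a guaranteed positive Jacobian.

## Noise estimation and non-local-means denoising

Local noise is estimated from Laplacian pseudo-residuals
`(I − mean of 6 neighbours)/√(1 + 1/6)`, whose variance equals the noise
variance under i.i.d. additive noise.  The local sigma map is the median
absolute residual over a sliding 7³ window (×1.4826), robust to the
structural outliers at tissue interfaces; the scalar summary is the
*mode* of the local-sigma distribution inside the mask, because on
thin-shelled geometries a median would still be contaminated by
interface-straddling windows.  The filter itself is classical blockwise
non-local means — 3³ patches compared over a 7³ search window — with the
similarity bandwidth `2·β·σ²(x)` tied to the local noise map (β = 1 by
default).  The output is a convex combination of input intensities and
therefore range-bounded.  Rician bias correction is omitted; on real
low-SNR magnitude images the filter would leave the noise floor in place.

## Adaptive MAP segmentation with partial-volume estimation

Classification is atlas-free.  A deterministic 3-class k-means
(quantile-seeded, mode-refined so reported class means land on
pure-tissue peaks rather than partial-volume-shifted cluster means)
initializes an EM/ICM loop:

* **E-step** — posterior ∝ Gaussian likelihood under the local class
  means × Potts prior `exp(β · #same-label 6-neighbours)` of the current
  hard labeling (β default 0.1).
* **M-step** — the three class means share a single multiplicative bias
  field: normalized intensities of *eroded pure-tissue* voxels are
  Gaussian-smoothed (24 mm FWHM) into the field, and global means and
  variances are re-estimated from the bias-corrected pure voxels.

Two design points deserve emphasis.  First, restricting the M-step to
eroded pure voxels is essential: posterior-weighted estimation lets
partial-volume mixtures inflate the CSF variance and drag the local means
near boundaries, which measurably *hurts* accuracy.  Second, sharing one
multiplicative field across classes (rather than estimating three
independent mean fields) keeps the means ordered by construction and
makes the adaptation a proper bias-field model; with the field estimation
disabled the classifier reduces exactly to per-voxel maximum likelihood
(plus the MRF prior).  On phantoms with a 10% bias field, the adaptive
variant beats the non-adaptive one in paired κ comparisons.

The convergence rule is a fixed schedule: at most 12 iterations, stopping
early when fewer than 0.1% of labels change.

Partial-volume estimation reassigns voxels among five classes
{CSF, CSF/GM, GM, GM/WM, WM}: the mixed fraction of the brighter tissue
is `(I − m_low)/(m_high − m_low)` with the local means, clipped to
[0, 1]; mixed classes are only allowed where the 6-neighbourhood contains
both parent tissues, otherwise the voxel snaps to the nearer pure class.
The continuous label lives on the 1–3 scale (1 = CSF, 2 = GM, 3 = WM), so
`gm_fraction = 1 − |label − 2|` is closed-form.

Head masking is Otsu-based (threshold 0.35×Otsu, closing, hole filling,
largest component).  Because mask-boundary voxels are partly background,
volume summaries weight each voxel by an intracranial fraction — 1 in the
interior, `clip(I/m_CSF, 0, 1)` on boundary voxels — which brings TIV
within ~2% of the generator's definition (voxel count with >50% head
content).  Probabilities inside the mask still sum to 1; the head
fraction is bookkeeping for volumes only.  The fraction-sum-to-one
invariant of the *generator* likewise holds for voxels fully inside the
head; boundary voxels carry an explicit background fraction.

Accuracy is quantified as Cohen's κ of the binary tissue-vs-rest maps;
κ is undefined (and raised as an error) when both maps are constant.

## Diffeomorphic registration and modulation

The registration is a stationary-velocity demons scheme: a symmetric
gradient force capped at half a voxel, fluid-regularized by a Gaussian
(6 mm FWHM) before being added to the velocity, which is then
diffusion-regularized (1 mm FWHM) and exponentiated by
scaling-and-squaring (step count chosen so each squaring step moves less
than 0.4 voxel).  Three pyramid levels by default; a moments-based affine
pre-alignment (center of mass + isotropic scale from the intensity
spread; rotation omitted — the principal axes of near-spherical phantoms
are ill-conditioned) brings the images into a common frame first.  The
fixed image at every level is sampled through the same world-coordinate
path as the moving image, so self-registration yields an exactly zero
field.  The Jacobian determinant is computed from central finite
differences of the total world-frame mapping and asserted positive after
every registration.

Modulation multiplies a warped tissue map by this Jacobian so template-
space integrals equal native-space tissue volumes (conservation holds
within 1% on phantoms).  Templates are built by iterative registration to
the running mean; the mean gradient magnitude (sharpness) is
non-decreasing over iterations on phantom cohorts.

This scheme trades the large-deformation machinery of geodesic-shooting
registration for a transparent, dependency-free optimizer that preserves
the two contracts downstream analysis needs: diffeomorphism and volume
conservation under modulation.

## Projection-based thickness and surfaces

Boundary distances are Euclidean distances from gray-matter voxel centers
to the white-matter and CSF/background boundaries, each placed where the
respective tissue fraction crosses 0.5.  The fraction map is linearly
upsampled 3× (an odd factor, so a fine sample lands on every native voxel
center — necessary to detect half-voxel CSF gaps), a distance transform
runs on the fine grid, and a sub-voxel correction
`(F_nearest − 0.5)/|∇F|` accounts for the surface sitting beyond the
nearest inside sample.  Residual errors are ≈ 0.05 mm mean, < 0.25 mm
worst-case on spherical shells at 1 mm voxels.

Thickness candidates `wmd + csfd` start on the outer gray-matter boundary
and are max-propagated inward over 26-neighbour sweeps along
non-increasing `wmd`; a propagated value is only accepted where it does
not exceed the local `wmd + csfd` bound.  Non-increasing (rather than
strictly decreasing) propagation lets values travel along distance level
sets, which is what lets sulcal banks whose own `csfd` overshoots through
a blurred sulcus inherit the thickness measured where the sulcus *is*
detected.  A half-voxel CSF gap — invisible to any hard labeling — is
recovered exactly because of the sub-voxel boundary placement.

The central surface is the zero level set of `wmd − T/2`, extracted by
marching cubes, cleaned (largest component, hole filling) and reported
with its Euler characteristic and genus; spherical-harmonic topology
repair is out of scope, so non-zero genus is reported rather than
repaired.  White and pial meshes are offsets of the central vertices by
±T/2 along the level-set gradient, and the refined thickness is the
symmetric closest-surface metric
`T(v) = ½[d(white_v → pial) + d(pial_v → white)]` with exact
point-to-triangle distances (a KD-tree over triangle centroids prunes
candidates without approximation).

Depth sampling along the surface normal supports two rules: equidistant
(`r_white + α·T`) and equi-volume, which uses the local spherical
approximation with radius `1/H` (signed mean curvature) and places the
sample at `r(α) = ((1−α)·r_in³ + α·r_out³)^{1/3}` — the depth at which
the cortical volume fractions above and below are preserved under
curvature.  For `|H|·T < 10⁻⁶` the equidistant rule is used verbatim, and
the two rules agree to machine precision on flat sheets.

Vertex scalars are smoothed by explicit heat diffusion with the clamped
cotangent Laplacian and lumped vertex-area mass; total diffusion time
follows the 2-D heat-kernel identity `σ² = 2t` with
`σ = FWHM/√(8 ln 2)`, and the symmetric zero-row-sum Laplacian preserves
the area-weighted mean exactly.  The impulse response attains the
requested geodesic FWHM within ~15% on sphere meshes.

## Folding metrics

* **Gyrification** — |H| from the cotangent Laplace–Beltrami
  mean-curvature normal (`Δx = −2Hn`, barycentric vertex areas),
  area-averaged over a 3 mm Euclidean neighbourhood to suppress
  discretization noise.  Sphere check: |H| = 1/r within 2%.
* **Sulcal depth** — exact point-to-surface distance to the convex hull;
  an optional square-root transform is off by default.
* **Spherical map** — vertices are projected radially from the centroid,
  which is bijective and adds no distortion for star-shaped surfaces (and
  is the identity for a sphere); only if the projection flips spherical
  triangles does an iterative uniform-Laplacian inflation with
  reprojection take over.  Flipped triangles raise an error; per-vertex
  area distortion is reported.
* **Fractal dimension** — vertex coordinates are expanded in real
  spherical harmonics over the sphere map (area-weighted least squares;
  the band limit is reduced automatically if the mesh has fewer than
  twice as many vertices as coefficients), surfaces are reconstructed at
  degrees l = 2, 4, …, 32, and `FD = 2 + slope(log area vs log l)` over
  l ∈ [8, 32].  A smooth sphere gives FD = 2.00 ± 0.05; FD grows with
  fold amplitude and is scale-invariant.
* **Surface ratio** — mesh area inside a Euclidean ball (default 20 mm,
  configurable; tests use radii suited to the phantom scale) over
  `πr²`, with boundary triangles clipped by uniform 4³-fold subdivision
  and centroid-inside counting (all sub-triangles have equal area, so the
  inside fraction is the clipped area fraction).

All four metrics are deterministic and invariant under rigid motion and
vertex reindexing.

## Statistics

The GLM is ordinary least squares per element with
`t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`; rank-deficient designs are rejected with
the collinear columns named.  Global scaling multiplies each subject's
data by `mean(TIV)/TIV` — the head-size correction appropriate when TIV
is correlated with the effect of interest.

TFCE integrates `e(h)^E · h^H · dh` over thresholds, with cluster extent
from the configured voxel connectivity (grids) or edge-connected vertex
area (meshes).  Defaults E = 0.5, H = 2 for volumes and E = 1, H = 2 for
surfaces are the published recommendations for 3-D and 2-D sheet data;
n_steps = 100.  The step height is `max(stat)/n_steps` by default; note
that this adaptive step makes the enhancement monotone in the input only
up to discretization — a fixed `dh` makes it exactly monotone, and the
property suite verifies that.

Family-wise error control uses the max-TFCE permutation distribution with
Freedman–Lane nuisance handling: data are residualized against the
design columns the contrast ignores, residual rows are permuted within
exchangeability blocks, the reduced-model fit is added back, and the full
model is refit.  `p = (1 + #{null max ≥ observed})/(n_perm + 1)`, so the
attainable floor is `1/(n_perm+1)`.  When the number of distinct
within-block permutations is at most the requested count, they are
enumerated exhaustively (exact test) and a note is logged.  One-tailed
tests (the positive contrast direction) are the default, matching the
directional hypotheses of atrophy studies; two-sided designs enhance both
signs and take the per-element maximum.  Calibration: over 200 null
two-group simulations (8 vs 8, 10³-voxel smoothed Gaussian maps, 99
permutations — sizes chosen to keep the simulation around a minute) the
empirical FWER is 0.045, inside the binomial 95% interval around 0.05.

FDR for region tables is Benjamini–Hochberg step-up, cross-checked in the
tests against an exhaustive threshold search and statsmodels.

## Quality control

Three measures, each mapped linearly onto a 0.5 (best) – 10.5 (worst)
rating between configurable anchors:

| measure | definition | anchors (0.5 → 10.5) |
|---|---|---|
| `ncr` | pseudo-residual sigma over eroded pure WM / GM–WM contrast | 0 → 0.5 |
| `icr` | sigma of the 20 mm-smoothed WM intensity field / contrast | 0 → 0.5 |
| `res` | RMS voxel size (mm) | 0.5 → 3.0 |

The overall rating is the weighted mean with weights (2, 1, 1) — noise
dominates segmentation error, so it counts double.  Letter grades A–F
partition the scale in unit bins with +/− thirds.  The anchors are
design choices guarded by monotonicity tests (each rating rises with its
degradation parameter), not by absolute targets.

Cohort homogeneity: each subject's registered GM map is correlated with
the leave-one-out mean; `z` standardizes `1 − r` across the cohort and
|z| > 2 flags outliers.  This captures anatomical deviation and gross
processing failure in one score; it does not separate the two causes.

## Pipeline orchestration

`run_subject` executes denoise → segment → QC → surfaces → metrics with
per-stage toggles, returning a JSON-serializable report (class means,
TIV, QC, mean thickness, per-stage runtimes); any stage error aborts with
the stage name.  `run_study` adds template construction,
warp + modulate + 6 mm smoothing for the voxel stream, TFCE permutation
statistics, regional tables with FDR, and a surface stream in which each
subject's thickness is resampled onto a common icosphere via the
spherical parameterization (nearest mapped vertex) — a minimal stand-in
for spherical surface registration that works because the phantom cohort
shares topology and orientation, then smoothed at 12 mm.  Defaults (6 mm
volume / 12 mm surface smoothing, one-tailed contrasts, global scaling
for the volume stream only) mirror common atrophy-study practice.
A `--longitudinal` flag is reserved and errors: the longitudinal pipelines
are deliberately not implemented.

## Known limitations

* Phantoms are skull-free; the head mask is intensity-based and would not
  strip a real head.
* Gaussian noise only; no Rician correction in the denoiser.
* The demons registration is desk-scale: adequate for phantom-sized
  deformations (< ~5 mm), not for full inter-subject human registration.
* Topology defects are reported (genus), not repaired.
* The common-sphere surface resampling in `run_study` assumes consistent
  orientation across subjects; it is not a folding-based registration.
* QC anchors and the MRF/kernel defaults are package choices; only their
  monotone behaviour, not their absolute values, is validated.
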