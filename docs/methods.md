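# Methods

This note documents the models, parameter choices and numerical decisions
behind `ratpet`, and what validation on the digital phantom does and does
not establish about real scanner data.

## Coordinate conventions

Volumes are stored in Paxinos axis order: axis 0 is left–right x (negative
reported x = left of the midline), axis 1 dorso-ventral y (positive =
ventral), axis 2 rostro-caudal z (positive = toward the olfactory bulb,
negative = toward the cerebellum). The template set's origin voxel sits at
the dorsal third ventricle (D3V); reported z is conventionally
bregma-referenced, so `PaxinosAxes.z_bregma_offset` (mm, default 0) is
added when converting voxel indices to coordinates. The offset is exposed
as configuration because the D3V-to-bregma distance depends on the
template; we deliberately do not guess it.

Grids follow a half-open convention: a `GridSpec` with box [lower, upper)
and voxel size v has exactly (upper−lower)/v voxels, and voxel i sits at
lower + i·v. This is what makes the standard normalization box
[−150 −180 −126; 150 60 72] mm at [1 1 1.8] mm an exact 300×240×110 matrix
with an integer origin index — a closed convention would give 301×241×111.

Analyze 7.5 files carry no portable origin; on read the grid centre is
used and the limitation is documented at the I/O layer. NIfTI round-trips
the origin through the sform affine. Intensities are promoted to floating
point on read regardless of the on-disk type, since all downstream math is
continuous.

## Registration

Both registration stages minimize the same objective, the mean squared
intensity difference after a closed-form global intensity factor α
(PET units are arbitrary; only the spatial pattern carries information),
normalized by the target's mean square so regularization weights are
scale-free:

J(θ) = mean_x [α·s(φ_θ(x)) − g(x)]² / mean_x g(x)² + λ·E_membrane(u)

* **Affine stage** — 12 parameters (translations mm, rotations rad,
  log-zooms, shears), optimized by L-BFGS with an analytic gradient
  (chain rule through the sampled image gradient; the optimality of α
  makes the gradient exact by the envelope theorem). A Gaussian
  multi-resolution schedule of (6 mm FWHM, step 3), (3 mm, step 2),
  (0 mm, full resolution) provides the capture range. The
  "average sized template" regularization is a quadratic penalty
  (weight 0.01) on log-zooms and shears: the template is assumed to have
  the cohort-average size, so scale is only adjusted when the data demand
  it. On phantoms, seeded affines with ≤5 mm translations, ≤0.1 rad
  rotations and zooms 0.9–1.1 are recovered to ~0.01 voxel.
* **Nonlinear stage** — per-axis displacements on a truncated 3-D DCT-II
  cosine basis (default cutoff 4 functions per axis), with membrane-energy
  regularization that is diagonal in coefficient space (the derivative of
  a cosine basis is an orthogonal sine basis): w_m = Σ_axis (π·m_axis /
  (N_axis·h_axis))². Default λ = 1. Optimization is L-BFGS with the
  analytic gradient; the warp starts at zero, so monotone descent
  guarantees the final objective never exceeds the affine-only objective
  (a zero warp is returned in the numerically pathological case). λ→∞
  provably drives the coefficients to zero. The basis cutoff bounds the
  finest recoverable deformation wavelength; the default resolves the
  smooth inter-individual variability the phantom generates but not
  focal distortions.
* Estimation is fully deterministic (no stochastic optimizer): repeated
  runs are bit-identical.

Transforms map target mm coordinates to source mm coordinates (the
pull-back direction used by resampling) and serialize to JSON (affine
matrix and parameters, warp coefficients, cutoff, λ, estimation grid).

## Template construction

The register–average loop always re-registers the *original* scans to the
current target rather than compounding previously warped copies, avoiding
progressive interpolation blur. Two statistics are logged per round for
old/new targets f, g: the mean squared residual d = (1/n)Σ(fᵢ−gᵢ)² and the
scale-invariant rel = Σ(fᵢ−gᵢ)²/Σfᵢ². The 5% stopping rule is applied to
rel, the only unitless reading under which "less than 5%" is meaningful
across intensity scales; both are recorded so either convention can be
audited. The initial target is a caller-chosen cohort scan (default index
0) — the average is insensitive to the choice once converged, but the
choice is recorded in the run manifest.

## Intracranial extraction

One global Otsu threshold is computed from the pooled nonzero in-box
voxels (256 histogram bins). Ties in between-class variance — which arise
systematically when an empty histogram gap separates the modes — resolve
to the lowest candidate threshold, retaining more tissue; the mask is
refined by registration downstream anyway. Eye boxes are applied
volumetrically by default (per-slice boxes are supported). Re-running
extraction on an already-extracted volume recomputes the threshold from
the remaining sample, so exact idempotence holds only when that threshold
stays below the brain minimum; the API documents this rather than
special-casing it. No morphological post-processing (hole filling,
surface stripping) is applied.

## Atlas-driven synthetic target

Fine atlas labels are merged to six structures (1 olfactory bulb,
2 cortex, 3 hippocampi, 4 mesencephalon, 5 thalamus, 6 cerebellum), each
painted with its mean reference-PET intensity and smoothed with a
2×2×4 mm FWHM Gaussian (σ_axis = FWHM/(voxel·√(8 ln 2))). The kernel is
anisotropic in mm; the per-axis values are implemented as stated.
Smoothing zero-pads: background in masked PET genuinely is zero signal,
at the price of shrunk intensities within about one FWHM of the field
edge (intensity is conserved to <0.1% for interior-supported inputs).

## Spatial normalization

Header scaling (×4), registration to the template (affine + warp),
resampling onto the standard grid, masking, then the shear to a fixed
120×80×98 window positioned so the intracranial mask's bounding box is
centered — the spec of the window's placement is otherwise free, and
centering is deterministic and content-preserving; the offset goes into
the result so Paxinos coordinates are unchanged by the crop. Masking
happens after resampling onto the standard grid, where the mask lives.
Already-masked inputs should be normalized against the canonical
(brain-only) target: registering a stripped brain to the with-scalp
template dilates it toward the scalp ring (the `target` parameter
selects this).

## Statistics

Smoothing (2×2×4 mm) → proportional scaling (each scan's in-mask mean set
to 50; no ANCOVA) → voxel-wise pooled-variance two-sample t with
df = nA+nB−2; zero-variance voxels are excluded from the search volume.
t→z conversion goes through log tail probabilities
(z = −Φ⁻¹(exp(log sf_t)) with sign restored), clamped at |z| = 38 where
the double-precision normal tail underflows.

Residual smoothness is estimated from variance-normalized residuals: the
mean squared first difference per axis estimates the derivative variance
λ of a unit-variance field, and FWHM = √(4 ln 2/λ) voxels (exact for a
Gaussian autocorrelation; pure white noise therefore reads ≈1.18 voxels,
the intrinsic lattice width). Resel counts R0–R3 come from the mask's
cubical-complex counts (vertices/edges/faces/cubes), which reduce to the
closed cuboid values (1, a+b+c, ab+ac+bc, abc in FWHM units) and are
verified against that closed form in the tests.

The FWE height threshold solves E[EC](u) = α using the T-field
Euler-characteristic densities, capped at the Bonferroni threshold — at
low df or low smoothness the EC bound can exceed Bonferroni, and the
sharper of two valid bounds is the standard choice. **Known limitation:**
for t fields at small df (≈15) with smoothness around 2–4 voxels the EC
approach is conservative — the lattice only samples the continuous field
at voxel centres, and high excursions of low-df t fields cluster, so
E[EC] exceeds P(max > u) by a factor of roughly 2–5 in tail probability
at the settings above. We validated the implementation itself by direct
simulation of the Euler characteristic (Gaussian fields at 6-voxel FWHM
match the predicted E[EC] within Monte-Carlo error); the residual
conservatism is a property of the method, not of the code. FWE control
is therefore never anti-conservative. For small-animal designs at these
df we recommend the exact max-t permutation option
(`method="permutation"`), which the calibration tests show holds the
nominal 5% level; RFT remains the default for lineage compatibility, and
the two agree within ~15% once fields are smooth at ≥3 voxels FWHM per
axis.

Clusters are 18-connected components above threshold (configurable 6/26),
filtered at 50 voxels, numbered by descending extent; up to three local
maxima at least 8 mm apart are reported per cluster with corrected peak
p = min(1, E[EC](t_peak)), Max_T, Max_Z and Paxinos mm coordinates.

## Overlap metrics

JS, RV, FP, FN as defined in the README. FP and FN are normalized by the
union V(R∪S) — the only denominator under which JS + FP + FN = 100 holds
identically, which the published per-animal agreement tables satisfy row
by row; RV is normalized by the reference volume (the standard "relative
error on volume"). Non-binary inputs are rejected rather than silently
thresholded; the CLI offers `--binarize 0.5` to opt in.

## The phantom: what it emulates, and what it does not

The phantom provides six ellipsoidal structures (split into 12 left/right
sub-labels so label merging is exercised), a scalp shell at 30% of
cortical intensity, and eye blobs — on a 64×48×40 grid at [1 1 1.8] mm,
i.e. template-scale dimensions. Structure intensities (cortex 100,
thalamus 98, cerebellum 96, hippocampi 95, mesencephalon 92, olfactory
bulb 90, arbitrary units) follow the qualitative FDG ranking of
gray-matter-rich structures. Subjects are generated by a seeded random
affine (|translation| ≤ 2 mm, |rotation| ≤ 0.05 rad, zooms 0.95–1.05,
shears ≤ 0.02) plus a smooth random cosine warp (≈1 voxel RMS), scanner
PSF blur of 1.5 mm FWHM, and additive Gaussian noise with σ = 5% of the
brain mean. Everything is bit-reproducible from (spec, seed).

Cohorts fed to the statistics stage use `PhantomSpec.normalized()`:
residual subvoxel misregistration (≈0.5 voxel translations, 0.3-voxel
warp) rather than raw anatomical variability, because the GLM only ever
sees spatially normalized scans — feeding raw-variability cohorts to
voxel statistics would test a pipeline no one runs and produces low-rank
anatomy-difference residuals that violate any FWE model.

Not emulated: PET physics (Poisson counting in projection space, scatter,
randoms, attenuation — noise is additive Gaussian on the blurred image),
reconstruction correlations, anatomically faithful Paxinos geometry, and
inter-scanner resolution differences. Passing phantom tests therefore
establishes the correctness of the geometry, registration, extraction and
statistical machinery under a known ground truth; it does not certify
registration accuracy on real scanner data, where contrast and noise
structure differ.

## Problem sizes used in validation

Registration-heavy validation (transform recovery, template convergence,
calibration, power) runs on reduced grids — 48×36×30 or 40×32×26 voxels —
chosen so the full suite runs on a laptop-class single core; the
geometry of the anatomy is proportional to the default phantom. The FWE
calibration uses 200 seeded 9-versus-8 null cohorts (permutation option,
200 relabellings each) and the power check 50 seeded effect cohorts. The
published-configuration checks (300×240×110 grid, 120×80×98 shear) run at
full size, since they are pure geometry.
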