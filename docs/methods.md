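# Methods

This note records the models, conventions and numerical choices behind
`dirval`, and what the synthetic validation can and cannot say about real
patient data.

## Geometry and field conventions

World coordinates are millimetres on fixed axis-aligned axes; arrays are
indexed `[i, j, k]` along (x, y, z) with the centre of voxel (0,0,0) at the
grid origin, and the world↔index map is the exact affine
`world = origin + index * spacing`.  Displacements are always stored in
world mm, never voxel units, so anisotropic clinical grids (1 × 1 × 3 mm)
need no special handling.  Every field carries an explicit direction tag:

- **pull** — the field lives on the *target* grid and `out(x) =
  moving(x + u(x))`; this is the only direction `warp_image` and
  `propagate_mask` accept;
- **push** — the field maps source points forward; it must be inverted
  first.

Operations check and propagate the tag rather than guessing; the tag is not
recorded by NIfTI/MetaImage, so the reader requires it from the caller.
Oblique grids and 4-D volumes are out of scope.  Contours are integer label
volumes (voxel centre inside the analytic shape), not DICOM-RT structures.

## DVF inversion and inverse consistency

`invert_dvf` solves `v(x) = -u(x + v(x))` by fixed-point iteration from
`v₀ = -u(x)`, stopping when the largest update drops below `tol`
(default 1e-3 mm, 50 iterations; the ground-truth pipeline uses 1e-4 mm).
The iteration is contractive when `max |∇u| < 1`, which the generator's
deformations respect by construction.  The inverse-consistency error is
defined per voxel of the forward field's grid,

    ice(x) = || inv(x + u(x)) + u(x) ||,

with linear interpolation of the inverse field; voxels whose composed sample
point leaves the grid are excluded from statistics and counted, because edge
extrapolation would poison the mean.  ICE statistics are full-volume means
over each structure (whether the original tool used surface or volume
statistics is unrecorded; volume means are documented here and the QC
thresholds — 0.2 mm per contour, 0.5 mm per case — are applied to them).

## Contour metrics

DSC is voxel-count overlap.  MDA is the *symmetric* mean surface distance:
surfaces are six-connected boundary voxel centres (the grid edge counts as
background), nearest-neighbour distances are computed in world mm with a
k-d tree, and the two directed means are averaged.  Conventions for
degenerate inputs: DSC(∅,∅)=1, DSC(∅,A)=0 with a warning, MDA on an empty
mask is an error.  The k-d-tree MDA equals the all-pairs brute force
exactly; the test suite verifies both metrics against naive oracles on
random masks.

Propagated contours binarize the linearly interpolated warped indicator at
0.5.  A consequence worth knowing: boundary motion below about half a voxel
is invisible to the thresholded mask.  Volume-change analyses of small
shrinkages therefore use the fractional (partial-volume) sum of the warped
indicator (`warped_mask_volume_cc`), which tracks sub-voxel surface motion;
the thresholded mask remains the propagation convention for DSC/MDA.

## The registration engine

The deformable engine is a stand-in written to the published description of
the validated algorithm — patch-wise normalized cross-correlation optimized
iteratively over the whole domain in a multiresolution coarse-to-fine
scheme with a smoothing regularizer after each iteration — not a clone of
any vendor implementation; agreement with any vendor's published tables is
a plausibility check, never a claim.

*Patch NCC by local normalization.*  Each level subtracts the local mean
and divides by the local standard deviation over a `(2r+1)³` window
(`patch_radius` r = 2).  The squared difference of the two normalized
images is algebraically `2(1 - NCC)` per patch, so demons-style forces on
the normalized images ascend patch NCC and are invariant to affine
intensity rescaling — the property that lets one engine serve both kV–kV
and kV–MV registration.  Patches with standard deviation below 2% of the
image SD normalize to ~0 and exert no force (they carry no alignment
information); their count is reported.

*Iteration.*  Per iteration: symmetric-gradient demons force
`-d·∇/(|∇|² + d²)` on the normalized images; normalization of the force
field so a typical informative voxel (95th percentile) moves
`step_size_mm` (default 1 mm), with amplification capped at 4× and
individual voxels at 2× the step; Gaussian smoothing of the accumulated
field (`reg_sigma_mm`, default 2.5 mm); re-warp.  Voxels whose sample point
falls outside the moving volume (truncated scan coverage, common at the
inferior edge of HN scans) exert no force and are excluded from the
objective — the regularizer carries the field into those regions from
informed neighbours.  The engine keeps the best state seen under its
objective (the aggregate patch NCC) and stops a level after `patience`
(15) iterations without a relative improvement of `stop_tol` (1e-6), or at
`max_iter_per_level` (300; hard ceiling 500).  Up to 4 pyramid levels
(default 3) with downsampling factor 2 per level; the moving image is
smoothed to each level's band, and the finest level keeps a light 0.5-voxel
blur on both images because linear interpolation's position-dependent blur
otherwise biases sub-voxel optima toward zero displacement.  The published
trace is the objective's improvement path, non-decreasing within each level
by construction.

*Rigid stage.*  6-DOF (three Euler angles about the volume centre, three
translations) maximizing global NCC: a phase-correlation translation seed,
then Powell refinement per pyramid level with cubic-B-spline image sampling
(coefficients prefiltered once per level — the spline kernel's symmetric
response removes linear interpolation's sub-voxel bias, which matters at
the 0.1 mm marker tolerance).  `finest_factor=2` stops the pyramid at half
resolution for pre-alignment use, where the deformable stage follows
anyway.  Deformable registration always starts from the rigid transform.

Engine defaults were set by the synthetic recovery suite (translation,
rotation and full-case recovery); the vendor algorithm's actual patch size,
regularizer and schedule are unpublished.

## Synthetic phantoms

`build_hn_phantom` rasterizes eleven masks for nine named structures
(both parotids and submandibulars) as ellipsoids and z-cylinders laid out in
disjoint anatomical bands inside a neck-to-head body whose in-plane radii
widen superiorly; semi-axes solve `4/3·π·abc = V` for the published mean
volumes (realized within 5% at the default 1 × 1 × 3 mm, 256 × 256 × 60
grid; `PhantomSpec.desk()` gives 128 × 128 × 40 at 1.5 × 1.5 × 3 mm).  HU
assignments: air −1000, body 20, bone (mandible, an unnamed cervical
vertebral column) 800, soft-tissue structures 30–80.  A seeded smooth random
texture (Gaussian-filtered white noise, σ 4 mm, amplitude 50 HU) inside the
body makes NCC patches informative.  Same seed, same bytes.

`build_gt_dvf` composes push fields, innermost first: uniform in-plane
contraction toward the body axis with per-axis scale `√(1-f)` (so a target
volume-loss fraction f is exact — the default 10.6% matches the average
reported for the anatomy class being emulated, range 4–20%); per-organ
uniform shrinkage inside the structure (exact volume prediction) with a
Gaussian falloff outside; progressive spine flexion (rotation about x whose
angle grows linearly above a pivot, default 0.3°/cm); and an axial head
rotation (default 3°) blended in by a smooth sigmoid weight above the neck.
Shoulder and hyoid components of the clinical inventory are collapsed into
the contraction and flexion terms.  The composite's Jacobian determinant is
checked positive (> 0.1) on the body; the default composition peaks near
10 mm displacement inside the body (somewhat more in the air corners).
`apply_gt` inverts the push field numerically, warps the image and masks
with the pull field, and returns both directions plus the ICE map, so every
case is born with its own QC evidence; default cases come in around 0.01 mm
mean ICE, far below the 0.2 mm acceptance bar.

The marker phantom is three 2-mm spheres (not coplanar with the grid
centre) rasterized with an erf edge profile of 0.5 mm — wide enough to be
band-limited at 1 mm sampling, so intensity centroids sit on the analytic
centres to ~0.002 mm — and the moving volume is generated analytically at
shifted centres (no resampling step, hence no aliasing).

*What the generator does not emulate:* patient-realistic anatomy and
texture, CT physics (beam hardening, scatter, rings), breathing or
swallowing motion, contouring variability.  Passing the synthetic suite
demonstrates that the pipeline's machinery — field algebra, metrics,
statistics, and the engine's capture range at ~10 mm deformations with
informative texture — is correct; it does not certify accuracy on any
particular clinical dataset.

## MVCT quality transform and NPS

The kVCT→MVCT transform is (a) in-plane Gaussian pre-smoothing (default
0.7 px; no kernel is published, this is configurable), (b) a monotone
piecewise-linear HU remap clamped at its endpoints (default identity), and
(c) per-slice noise injection.  Noise synthesis follows the
split-and-shape procedure: draw a Gaussian white-noise image mask with
σ = `sigma_frac` × `ref_scale_hu` (default 4% of 1000 HU → 40 HU); split
into positive and negative definite parts; DFT each; multiply by the
amplitude filter `H(f) = √NPS(|f|)` normalized to unit RMS over the
frequency plane (power spectra multiply as |H|², and unit-RMS keeps total
power — a flat NPS gives the identity filter, so `sigma_frac` keeps its
meaning); inverse DFT; recombine positive minus negative; blur the noise
pattern with a 0.5-px Gaussian to soften the salt-and-pepper look.  For a
linear filter the split-and-recombine is algebraically identical to
filtering the signed mask (a test asserts this); it is retained as the
documented procedure.  The blur is applied to the noise pattern, not the
sum, preserving anatomic edge resolution.  Each CT slice gets a fresh
pattern; realization r of `n_realizations` (default 3) derives its slice
seeds from `seed + r`, so realizations share the deterministic component
exactly.  The 4% σ is referenced to a configurable scale because the
original reference point is unstated; the resulting noise SD (≈29 HU with
the default study NPS) is an outcome, not a calibration target.

`estimate_nps` uses the paired-scan difference method: `d = (s₁ - s₂)/√2`
cancels the deterministic anatomy; mean-subtracted square ROIs give
periodograms `NPS = Δx·Δy/(Nx·Ny)·|DFT(d)|²`, averaged over ROIs and
slices and radially binned to Nyquist.  With this scaling the integral of
the NPS over the 2-D frequency plane equals the noise variance (Parseval;
units HU²·mm²).  The DC sample is excluded — mean subtraction forces it to
zero — and empty bins are dropped.  The loop closes: measuring the NPS of
synthesized noise on a uniform cylinder recovers the target shape times the
known blur MTF² to within ~10% relative RMS at 50 slices of 128², and the
noise SD is exactly linear in `sigma_frac` at fixed seed (the pipeline is
positively homogeneous).  `default_study_nps` is a synthetic MVCT-like
spectrum (ramp × Gaussian roll-off, fc = 0.25 mm⁻¹, small floor) standing
in for a measured uniformity-phantom spectrum.

## Study orchestration and statistics

`run_case`: build phantom → ground-truth deformation (per-case magnitudes
sampled from the stated ranges with seeds derived from the study seed) →
QC filter → rigid registration (half-resolution finish) → RR propagation →
deformable registration → DR propagation → DSC/MDA/TRE against ground
truth; the kV-MV mode repeats registration per MVCT realization and
averages the *metrics*, not the fields.  Stage failures mark the case and
the batch continues.  Reports are byte-deterministic (fixed float format,
sorted JSON keys).

The kV-kV vs kV-MV comparison uses the paired two-sided Wilcoxon
signed-rank test, paired per contour per case: zeros dropped, average ranks
for ties, exact null distribution by dynamic programming over doubled ranks
for n ≤ 25, tie-corrected normal approximation with continuity correction
above.  No multiple-testing correction is applied across the nine
structures (noted in the report).  Pearson correlation is the direct
product-moment formula; on multi-case runs the DSC–MDA correlation over DR
records is negative, as overlap and surface congruence measure the same
misalignment from opposite sides.

## Problem sizes

Defaults were chosen so a full desk-scale case (128 × 128 × 40) runs in a
few minutes on one CPU: the test suite exercises the pipeline at
64 × 64 × 24 (3 × 3 × 5 mm) and the acceptance checks at the full desk
grid; the phantom generator itself scales to 256 × 256 × 60 at 1 × 1 × 3 mm.

## Known limitations

- The engine is description-faithful, not vendor-identical; absolute
  per-structure agreement with any published vendor table is not claimable.
- MDA uses voxel-centre surfaces; mesh-based tools will differ in the third
  decimal.
- Masks binarized at 0.5 cannot express sub-half-voxel boundary motion
  (use the fractional volumes for that).
- The phantom's geometric primitives make registration easier than real
  anatomy in some respects (smooth organ boundaries) and harder in others
  (low soft-tissue contrast between organs sharing similar HU).
- Uniform in-plane body contraction moves skin and deep tissue alike; real
  weight loss is surface-weighted.
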