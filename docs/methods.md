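# Methods

This note records the models, conventions and design choices behind
`rotqa`, in the order the pipeline runs them.

## Geometry and conventions

A patient-like right-handed frame is used throughout: axis 0 (x) is
left–right, axis 1 (y) anterior–posterior, axis 2 (z)
superior–inferior.  The three rotational error directions are labelled
**UP** (upward pitch, about x), **RO** (roll, about y) and **CW**
(clockwise yaw viewed from above, about z with negative mathematical
sign).  The combined rotation is `R = Rz(yaw) · Ry(roll) · Rx(pitch)`.
The mapping is configurable via `rotqa.types.DIRECTION_AXES` /
`DIRECTION_SIGNS`; nothing downstream depends on the sign choices
because only error magnitudes enter the analyses.

Rotation is applied to the dose volume with the detector plane held
fixed — equivalent to rotating a phantom under a fixed detector — by
inverse-mapping trilinear resampling about the isocenter.  Voxels
mapped from outside the field are zero.  Trilinear interpolation of a
smooth field has relative error of order `h²/(8σ²)` (grid step `h`,
feature scale `σ`); at the default 2 mm grid and ≥ 4 mm lobes this is
below 1 %, and the round-trip and symmetry tests assert against this
bound rather than machine precision.

## The synthetic plan generator

The generator emulates the *planar measurement phenomenology* of
clinical SBRT plans, not any specific treatment planning system.  A
plan is a superposition of anisotropic Gaussian lobes rescaled so the
global maximum equals the peak dose; the target mask is the
prescription isodose region (default 80 % of the peak).

Parameter choices, with units and rationale:

| parameter | default | rationale |
|---|---|---|
| grid | 48³ voxels at 2 mm | covers the 77 mm detector with margin; desk-scale |
| lobes per plan | 4–5 | clinical planar dose distributions are multi-lobed / extended |
| lobe arrangement | smooth arc around the isocenter, span 150–330°, radius 15–30 mm | large irregular or annular targets (e.g. spine-like geometries); the high-dose structure spans azimuth continuously so every rotation axis engages a comparable share of it |
| lateral sigma | U(4, 10) mm per lobe | steep SBRT penumbra |
| longitudinal sigma | U(7, 10) mm, one draw per plan | the longitudinal falloff is a plan-level property of beam arrangement and is typically shallower than the lateral penumbra |
| lobe z-offset | ±(0.9–1.1) σ_z | the detector plane cuts the longitudinal flank of the dose, as non-coplanar delivery makes generic; keeps the plane maximum (which anchors the 70 % threshold) stable under tilts |
| peak dose | U(40, 70) Gy | typical SBRT prescriptions |
| beam-modulation ripple | 5 % amplitude, 2.5 mm correlation length | beamlet-interference texture seen in measured planes; rotates rigidly with the plan |
| detector | 77 × 77 mm, 45 × 45 samples, plane through the isocenter | matches the planar-array geometry the pipeline standardizes to |
| measurement noise | Gaussian, SD = 1 % of plane max, clipped at 0 | diode-array repeatability is at the percent level |

The two-stage cohort protocol: per plan one noise-bearing 0° reference;
stage 1 one measurement per (magnitude × single direction) on the grid
{1.5, 2.25, 3.0, 3.75, 4.5}° × {UP, RO, CW}; stage 2 one measurement
with continuous U(1.5, 4.5)° angles in 2–3 randomly chosen axes.  Every
quantity is a pure function of (spec, seed); per-plan randomness
derives from a per-plan seed so feature extraction can regenerate the
identical plans independently of the measurement stream.

A companion phantom-image volume (smoothed high-intensity target over a
textured background, CT-like scale) carries the plan geometry into the
radiomic feature set.

**What the generator does not emulate.**  Real beam models (no
TPS-computed dose), detector spatial calibration and angular response,
couch kinematics, anatomy-driven heterogeneity of rotational
susceptibility, and the diode layout of a physical array (a regular
grid is sampled instead; the downstream 45 × 45 standardization makes
the stages equivalent).  Passing tests therefore demonstrate the
*method's* behaviour under controlled rotational perturbations, not
calibration against any clinical dataset.  In particular, plan-to-plan
variation in rotational susceptibility here stems from geometry draws
and field realizations; with real patients it also carries anatomy
information that planning features can predict.  This limits how much
of the held-out SSIM variance a features-only model can explain on
synthetic cohorts (see Modeling).

## Plane standardization

Fixed order: bilinear resampling to 45 × 45 over the same physical
extent (corner-aligned, so a bilinear field is reproduced exactly) →
zeroing of entries *strictly below* 70 % of the plane's own maximum
(ties kept; a pair-shared reference maximum is available) → optional
normalization to relative dose.  The pipeline is idempotent at fixed
settings.  Thresholding after interpolation follows the order the
measurement workflow implies; the order is configurable.

## SSIM

Default: 7 × 7 uniform sliding window, sample covariance, K1 = 0.01,
K2 = 0.03, dynamic range L = max of the two planes, exponents
α = β = γ = 1, scalar = mean of the local map.  These are the common
image-library conventions, and the implementation is cross-checked
bit-for-bit against scikit-image in the tests.  A global single-window
mode (`window=0`) exists for closed-form checks.  The contrast term
uses C2 in numerator and denominator (with C3 = C2/2 the component
product collapses algebraically to the combined closed form).  The
implementation computes variances and covariance through the same
expressions, so identical inputs give exactly 1.0 in floating point.

## Gamma index and DD pass rates

Per scored reference point (the entries surviving the 70 % threshold),
γ is the minimum over evaluated positions within 3 × DTA of
`sqrt(distance²/DTA² + ΔD²/dd²)`; the evaluated plane is upsampled ×10
by corner-aligned bilinear interpolation, so original nodes are
reproduced exactly and the DD pass set is provably a subset of the
gamma pass set at the same criterion.  Dose differences are normalized
to the reference-plane maximum (global) by default; local normalization
is a flag.  Relative-dose (RD) mode rescales each plane to its own
maximum before comparison; absolute-dose (AD) mode compares in Gy.
Because scaling a criterion scales γ inversely and enlarges the search
disc, pass rates are exactly monotone across 1 %/1 mm → 1.5 %/1.5 mm →
2 %/2 mm.  The search-radius cap cannot change pass/fail decisions
(a passing point's spatial term alone must be ≤ DTA < radius).

## Feature extraction

Feature definitions follow the IBSI-aligned standard set.  Volumes are
resampled to isotropic spacing and discretized with a fixed bin width
(`level = floor((v − min)/w) + 1` anchored at the masked minimum):
25 intensity units for images, 1 Gy for dose.  Texture matrices use the
13 unique 3D directions at distance 1; GLCM (symmetric) and GLRLM are
computed per direction and feature values averaged; GLSZM zones and
GLDM dependences use 26-connectivity with tolerance 0; NGTDM uses the
26-neighborhood mean.  Degenerate cases take documented conventional
values (correlation of a single-level field is 1, coarseness is capped
at 10⁶, …) so all features are finite on any valid input.

Censuses: radiomics = 18 first-order + 14 shape = 32 (original image
only); dosiomics = 18 first-order + 75 texture on the original volume
plus 93 on each of the 8 single-level wavelet bands (coif1,
periodization mode, each band reconstructed to input shape;
orthogonality gives exact energy partition) = 837.  Shape features are
not re-extracted from dose.  The dosiomic mask defaults to the whole
field (dose > 0).

Shape features come from a marching-cubes mesh of the mask after mild
Gaussian smoothing (σ = 1 voxel), which places the iso-surface at
sub-voxel accuracy and removes the ~9 % staircase bias in surface area
that binary marching cubes incurs; a digitized 10 mm ball recovers
sphericity within 2 % of 1.  Axis lengths use 4·sqrt(eigenvalue) of the
physical voxel-coordinate covariance; maximum diameters use convex-hull
vertices of the mesh.

Features are extracted once per plan from the planned (reference) dose
volume and the phantom image — they are planning-time quantities paired
with the rotation-angle labels of each measurement, mirroring a
workflow in which the rotated 3D dose is never measured.

## Modeling and statistics

Records are split 70/30 at the *plan* level (train count =
round(0.7·n)); no plan contributes to both sides, which the code
asserts on every run.  Features are min–max scaled with train-fitted
ranges (constant columns map to 0; test rows may leave [0, 1]).

Selection is two-stage: each feature group (radiomics, dosiomics) is
ranked by mean |TreeSHAP attribution| of a gradient-boosted regression
fit (XGBoost's native `pred_contribs`, which is exact additive
tree-path attribution), the top k = 17 per group are merged, a fresh
model re-ranks the merged set, and features holding at least 1 % of the
total attribution mass are retained.  The 1 % floor operationalizes
"significant global contribution"; it and k are configurable.

Model search replaces genetic-programming AutoML with a fixed, seeded
candidate family — ridge regression (α ∈ {10⁻⁸, 0.1, 1}), a
200-tree random forest, and two gradient-boosted configurations —
selected by grouped 10-fold cross-validated R² on the training plans
and refit on all training rows; reports give held-out R², MAE, RMSE and
MedAE.  The decision surface (CV R²) matches the original approach
while being deterministic under a fixed seed.

The three comparison scenarios share one split and one selection
(fitted on training rows only): *full* = selected features + the three
angle columns, *rotation-only* = angles, *features-only* = selected
features.  On synthetic cohorts the full model dominates both
single-source models every seed tested; the features-only model is
bounded by the feature-predictable share of plan-level susceptibility,
which is intrinsically small here (see the generator caveats above), so
rotation-only typically places second rather than third.

Direction-resolved statistics report, per group (UP, RO, CW, and the
mixed-direction stage-2 group), the Pearson r and two-sided p of each
metric against total rotation angle (and against direction count for
the mixed group), plus the proportion of records whose 2 %/2 mm gamma
pass rate exceeds 95 %.  No multiple-testing correction is applied; raw
p-values are reported.  Groups with fewer than 3 records are skipped.

## Problem sizes

Default desk-scale sizes, chosen so a full cohort analysis runs on a
laptop: cohorts of 40 plans (640 records) with 48³/2 mm volumes;
cohort-scale feature extraction at native 2 mm spacing; the
1 mm-isotropic extraction default is exercised on single 64³ volumes.
Stochastic cohort-level properties are verified on a handful of seeds
in the test suite; the correlation structure reported above was
characterized over 10 seeds during development.

## Known limitations

* Susceptibility to rotation is realization-driven; anatomy-linked
  predictability of real cohorts is out of reach of the generator.
* The mixed-direction (stage-2) group has one record per plan; with 40
  plans its correlation test is underpowered relative to the
  single-direction groups.
* 3D gamma, film dosimetry, DICOM import and TPS dose calculation are
  out of scope.
* Texture features on near-degenerate wavelet bands (high-pass bands of
  very smooth fields discretized at 1 Gy) collapse to their
  single-level conventional values; they remain finite and
  deterministic but carry little information in that regime.
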