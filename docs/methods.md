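# Methods

This note documents the models, conventions and numerical choices behind
`myoarch`, and what validation against the synthetic phantom does and does
not establish.

## Coordinate and data conventions

Arrays are indexed `(z, y, x)`, slice-first; physical coordinates are
`index × spacing` with spacing in µm. Vector fields store components in
the same `(z, y, x)` order; cross products are evaluated in the proper
right-handed (x, y, z) basis. Masks use labels {0: background,
1: myocardium, 2: cavity}. NIfTI I/O converts between the internal order
and NIfTI's x-fastest layout and carries spacing in the header (micron
unit code); TIFF stacks require a sidecar JSON `{"spacing_um": [z, y, x]}`
because TIFF has no reliable 3D spacing convention. Orientation estimation
requires isotropic spacing and refuses anisotropic volumes.

## Global geometry

Volumes are voxel counts × voxel volume (1 ml = 10¹² µm³). Mass is
myocardial volume × density with density 1.05 g/ml by default — the
standard myocardial tissue density, which also makes a 0.58 ml myocardium
weigh 0.61 g at two decimals.

Wall thickness per voxel is `d_endo + d_epi − 1 voxel`, where the two
terms are Euclidean distance transforms (µm) to the cavity and to the
epicardial background. The subtracted voxel corrects the EDT's
centre-to-centre convention (each surface is overshot by about half a
voxel); on a digital annulus this centres the estimate on the true `r₂ −
r₁`. Normalized wall depth is `d_endo / (d_endo + d_epi)` unchanged — the
half-voxel offsets largely cancel in the ratio.

On a truncated ventricle the open basal cut is background but is *not*
epicardium. When the cardiac frame is available, background at or beyond
the basal end of the myocardium is excluded from the epicardial distance;
without this the depth error near the base was an order of magnitude
larger than mid-wall (RMSE 0.116 vs 0.009 on the default phantom) and
basal transmural fits were strongly flattened.

## Cardiac frame and segment model

The apex→base axis is the principal axis of the myocardial voxel cloud; a
mask whose principal variance does not exceed the second by at least 10%
has no meaningful long axis and is rejected. The base is detected as the
end where the cavity is open (the cavity reaches the myocardial extreme).
Local frames: ℓ = axis, r = unit in-plane radius vector, c = ℓ × r;
on-axis voxels (undefined r) are flagged invalid.

Segments are 5 equal-length axial levels × 9 equal angular sectors
(configurable; 45 by default), with sector 1 starting at a configurable
reference angle. Categories: peri-MI is the 8-neighborhood of MI cells in
the level×sector grid (sectors wrap, levels clip); contralateral is, per
MI segment, the sector(s) at the same level nearest its sector centre
+180° — with 9 sectors the opposite angle falls between two sectors and
both are included. Precedence MI > peri-MI > contralateral > remaining.

## Orientation estimation

Gradients are central differences after Gaussian pre-smoothing
(σ_g = 0.25 voxels); the structure tensor is the Gaussian-windowed local
sum of gradient outer products (σ_w = 1.5 voxels). With a tissue mask the
tensor is computed in masked normalized-convolution form: pre-smoothing
interpolates only masked intensities, accumulation weights come from the
mask eroded by 2 voxels (boundary gradients are dominated by the tissue
edge, not the texture), and voxels whose window draws less than 40% of
its mass from the eroded mask get a zero tensor and are invalid.

These scales were calibrated on the phantom as the balance between two
error sources: smaller windows leave per-voxel orientation noise
(HA RMSE and fit R² degrade), larger windows mix orientations across the
wall and flatten the transmural HA profile near the surfaces
(|β₁| biased low). At the defaults the default phantom gives HA RMSE
≈ 7.5°, per-segment β₁ within [−128°, −111°] (truth −120°) and fit R²
≥ 0.93 in every segment, stable across seeds.

Eigen-decomposition uses LAPACK on the dense symmetric 3×3 tensors of the
region of interest; eigenvalues are reported descending. Coherence is
`(λ₂ − λ₃)/(λ₁ + λ₂ + λ₃)` — the contrast of the two smallest
eigenvalues, high exactly when one direction varies least — with voxels
below 0.1 (or with a zero tensor) invalid.

The helical angle treats v₃ as axial data: v₃ is re-signed so its
circumferential component is ≥ 0, then `HA = atan2(v₃·ℓ, v₃·c)` ∈ [−90°,
+90°], with purely longitudinal vectors mapped to +90°. A literal "angle
between v₃ and the circumferential plane" would assign 0° to both
circumferential and longitudinal fibers; the projection convention used
here is the standard helix-angle reading and reproduces the expected
positive-endocardial / negative-epicardial pattern. Voxels whose
tangent-plane projection norm is below 0.2 (near-radial vectors, unstable
angle) are invalid.

Transmural fits are per-segment OLS of HA on depth over all valid voxels
(≥ 10 required; a depth-binned mode is available). Missing fits are
records, not exceptions, so one degenerate segment cannot abort a run.

## Disarray index

"Neighborhood of size 200 µm" is read as a cube of 200 µm side (a 200 µm³
*volume* would be a single voxel at typical spacings and cannot measure
uniformity); the side is configurable and converted to an odd voxel
count ≥ 3. The dyadic mean `D = mean(v vᵀ)` over the neighborhood's valid
vectors gives `MDI = (3 λmax(D) − 1)/2`, clipped to [0, 1]: 1 for perfect
alignment, 0 for isotropy, invariant to global rotations and per-vector
sign flips. Voxels with under 50% valid neighbors are invalid. Regional
summaries report median and IQR (linear-interpolation quartiles);
category rows pool the per-segment medians of their segments, and
"overall" pools all segments.

## Cross-sectional areas

The CSA plane follows the cell, not the grid: the label is resampled
(trilinear, threshold 0.5) onto an in-plane grid at native spacing
through the centroid, perpendicular to the principal axis of the cell's
voxel cloud — grid-aligned sections would inflate the area of oblique
cells by 1/cos(tilt). An optional mode averages sections at 25/50/75% of
the axis extent. Cells spanning under 3 voxels along their axis are
rejected. The synthetic generator voxelizes tilted elliptic cylinders as
ground truth.

## Statistics and reporting

Samples are summarized as mean±SD when a Shapiro–Wilk test (AS R94, via
scipy) does not reject normality at α = 0.05, else as median(IQR).
Two-group comparisons use the pooled-variance two-tailed t test,
implemented directly so that a single-observation group is allowed (it
contributes no variance; df = n₁ + n₂ − 2). Kruskal–Wallis uses the
tie-corrected rank statistic with a χ² p-value; an all-tied input returns
H = 0 with a warning rather than an error. Report tables round half-up at
the printed precision (0.255 → 0.26). The post-MI average column is the
arithmetic mean of per-heart values; with equal segment counts per heart
this equals the pooled segment mean exactly.

## Synthetic phantom

The phantom emulates what the downstream measurements need from a real
high-resolution scan, not scanner physics. Geometry: a truncated
ellipsoid wall (default outer semi-axes 2.0 × 1.1 × 1.1 mm, 400 µm wall,
20% of the long-axis height cut at the base, 15 µm isotropic voxels,
≈ 220×160×160 grid) — a prolate, desk-scale LV that keeps the full
pipeline under a minute; spacing is a free parameter. Truth depth comes
from the ellipsoid level sets via the normal-distance approximation
`(m − 1)/|∇m|`; truth fiber direction is `cos(HA)·c + sin(HA)·ℓ` with the
linear law HA(depth) from +60° (endo) to −60° (epi).

Texture is line-integral convolution of band-limited noise (Gaussian
σ = wavelength/4) along the truth field, streamline arc length 3× the
texture wavelength with unit-voxel Euler steps and sign-consistent
tracking — so the direction of least intensity variation equals the truth
direction by construction. Intensities: background 0.2, cavity 0.35,
myocardium 0.5 ± 0.4×contrast standardized texture, plus Gaussian noise
(SD 0.05) everywhere. All randomness derives from the spec seed through
spawned generator streams; runs are bit-reproducible.

The infarct sector (circumferential × normalized-level interval) jitters
truth orientations by rotations about uniformly random axes with
Gaussian-distributed angle (SD `jitter_sd`), scales texture amplitude by
`contrast_scale`, removes myocardium with depth > `thinning_factor`
(epicardium moved inward) and converts depth < 1 − 1/`cavity_dilation` to
cavity (endocardium moved outward), renormalizing truth depth over the
remaining wall. Segments with ≥ 50% of their voxels inside the region are
recorded as ground-truth MI. A neutral infarct (jitter 0, factors 1)
leaves the phantom bit-identical because jitter uses its own stream.

What the phantom does **not** emulate: phase-contrast fringes and ring
artifacts, trabeculation, papillary muscles, the right ventricle,
vasculature, transmural fiber dispersion and sheetlet structure, and
intensity inhomogeneity. Passing phantom tests therefore demonstrates
correctness of the measurement chain under a known ground truth — not
performance on real scans, where segmentation quality and tissue contrast
dominate.

## Problem sizes and tolerances

The test suite exercises the full default phantom once (orientation
recovery at ≈ 1.8 M myocardial voxels) and uses a half-scale phantom
(20 µm voxels, ≈ 0.3 M myocardial voxels, identical texture-to-voxel
ratios) for the remaining phantom-based tests; disarray-vs-jitter checks
run 3 seeds × 4 jitter levels at that scale. Geometry oracles use digital
annuli and ellipsoids where closed forms are exact to voxelization, with
±1-voxel tolerances. Statistics examples are asserted to 10⁻³ against
hand computation.

## Known limitations

- The basal-cut exclusion assumes a roughly planar cut perpendicular to
  the long axis; oblique cuts are only partially excluded.
- Level binning uses the axial-coordinate range of the myocardium, so
  extreme apical artifacts shift level boundaries slightly.
- The masked structure tensor still flattens the outermost ~1–2 voxels of
  the HA profile; β₁ magnitudes carry a residual low bias of a few
  percent at 15–20 µm spacing.
- CSA is a single- (or three-) section estimate; strongly non-prismatic
  cells would need integrated area profiles.
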