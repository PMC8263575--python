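# myoarch

Multiscale quantification of left-ventricular (LV) myocardial remodeling
from 3D image volumes — the kind of analysis used to characterize
post-infarction hearts in high-resolution ex vivo imaging (e.g.
propagation-based X-ray phase-contrast tomography), where a single scan
supports measurements from whole-organ geometry down to individual
cardiomyocytes.

Given an isotropic grayscale volume and an LV mask (or sparse endo-/
epicardial contours), the package measures:

- **Global geometry** — cavity and myocardial volumes (ml), myocardial mass
  (g, via a tissue density of 1.05 g/ml), and wall thickness from the
  Euclidean distance transform of the mask: per voxel,
  `T = d_endo + d_epi`, the summed distances to the cavity and to the
  epicardial background.
- **A 45-segment regional model** — 5 apex-to-base levels × 9
  circumferential sectors about the fitted long axis, with infarct
  categories: MI segments (user-declared or phantom ground truth), peri-MI
  (grid neighbours of MI), contralateral (diametrically opposite at the
  same level), and remaining.
- **Cardiomyocyte-aggregate orientation** — the 3D structure tensor
  `ST = Σ g gᵀ` (Gaussian-windowed sum of outer products of central-
  difference gradients); its tertiary eigenvector **v₃** (smallest
  eigenvalue) points along the aggregates. The helical angle (HA) is the
  signed angle of v₃'s tangent-plane projection from the local
  circumferential direction, in [−90°, +90°]. Transmural profiles are
  fitted per segment by OLS, `HA = β₀ + β₁·depth`, where depth is the
  normalized wall depth `d_endo / (d_endo + d_epi)` (0 = endocardium,
  1 = epicardium); β₁ is the total HA gradient over the wall.
- **Myocardial disarray index (MDI)** — per voxel, the uniformity of v₃
  within a 200 µm cubic neighborhood via the mean dyadic tensor
  `D = mean(v vᵀ)`: `MDI = (3·λmax(D) − 1)/2 ∈ [0, 1]`, 1 for perfectly
  aligned aggregates, → 0 for isotropic disarray; sign-blind, as axial
  data requires.
- **Cardiomyocyte cross-sectional area (CSA)** — from labeled cell
  volumes, the section area through the cell centroid perpendicular to the
  cell's principal axis, in µm².
- **Statistical reporting** — Shapiro–Wilk-gated mean±SD vs median(IQR)
  summaries, pooled-variance two-tailed t tests, tie-corrected
  Kruskal–Wallis tests, and assembly of global-remodeling and regional-MDI
  tables.

Because suitable public scans are scarce, the package includes a fully
ground-truthed **synthetic LV phantom**: a truncated-ellipsoid wall with a
linear endo→epi helical-angle law (+60° → −60° by default), fiber texture
synthesized by line-integral convolution of noise along the true direction
field, and an optional transmural infarct sector with orientation jitter,
texture loss, wall thinning and cavity dilation. Every stage of the
pipeline is validated against this phantom's stored truth.

## Worked example

```python
from myoarch import phantom, geometry, orientation, disarray

spec = phantom.PhantomSpec(
    outer_radii=(1400.0, 750.0, 750.0), wall_thickness=400.0,
    voxel_spacing=20.0, texture_wavelength=60.0,
    infarct=phantom.InfarctSpec(jitter_sd=30.0, contrast_scale=0.5,
                                thinning_factor=0.6),
    seed=7,
)
ph = phantom.generate_phantom(spec)
myo = ph.mask.myocardium

axis = geometry.fit_heart_axis(ph.mask)
frames = geometry.local_cardiac_frames(ph.mask, axis)
depth = geometry.normalized_wall_depth(ph.mask, frames)
segs = geometry.derive_segment_categories(
    geometry.assign_segments(ph.mask, frames), ph.truth_segments.mi_ids)

orient = orientation.estimate_orientation(ph.volume, roi=myo, mask=myo)
ha = orientation.helical_angle_map(orient, frames)
fits = orientation.fit_all_segments(ha, depth, segs)
mdi = disarray.compute_mdi(orient)
print(disarray.region_summary(mdi.mdi, segs, group_by="category"))
```

Output (MI segments 16, 24, 25; remaining-segment β₁ mean −119.1°,
R² median 0.917 — the phantom's true HA gradient is −120°):

```
     category  median    q1    q3  n_segments
           MI   0.766 0.754 0.777           3
contralateral   0.823 0.815 0.838           5
      peri-MI   0.805 0.788 0.828          12
    remaining   0.830 0.803 0.845          25
      overall   0.823 0.795 0.838          45
```

The infarcted segments show the lowest disarray index — the jittered
orientations inside the infarct are less uniform — while the transmural
helical-angle fits in intact segments recover the imposed linear law.

A command-line interface wraps the same pipeline:

```sh
myoarch generate -c spec.json -o phantom_dir
myoarch analyze  -c run.json            # JSON RunConfig; schema-validated
myoarch report   out/heart1 out/heart2 --control heart1 -o tables/
```

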