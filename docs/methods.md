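# Methods

This note records the models, conventions and numerical choices behind
`adipo3d`, and what the synthetic phantoms do and do not establish about
real tissue.

## Conventions

Grids are indexed `(z, y, x)`; voxel spacing is always reported as
`(dx, dy, dz)` in µm; physical positions are voxel centers with the
origin at the first voxel center. All distances are µm, volumes µm³,
areas µm². Labels are positive 32-bit integers with 0 as background.
Every stochastic stage is driven by an explicit integer seed; the
generator derives independent child streams per stage (volume sampling,
packing, noise) so each stage is individually reproducible.

## Tissue phantom model

The generator emulates the statistical structure that a light-sheet
morphometry pipeline must cope with, not the biophysics of tissue.

**Geometry.** Cells are spheres packed by random sequential addition,
largest first, with a minimum surface-to-surface clearance `ecm_gap`
(default 4 µm) that the ECM shell fills, and a wall clearance
`boundary_margin` (default 10 µm) so that optical blur cannot push a
complete cell's mask onto the grid boundary — without it the
border-exclusion filter would preferentially drop cells that are complete
in truth but clipped in appearance, biasing cohort means. Spheres make
every ground-truth quantity analytic (V, r, centroid, Ψ = 1). Packing is
feasible below ~55% total sphere volume fraction; the defaults sit near
25–30%.

**True volumes.** Volumes follow a lognormal with mean `volume_mean` and
coefficient of variation `volume_cv`. No dispersion value is available
from the reference study conditions (only SEMs of means are printed), so
the default `volume_cv = 0.4` is the package's choice: with the
calibration means used here it places the bulk of the distribution in the
100,000–300,000 µm³ classes that dominate reported class histograms,
while producing a visible right tail above 500,000 µm³. The
`quantile_matched_lognormal` family places the n cells at midpoint
quantiles `(i + 0.5)/n` and rescales so the sample mean equals
`volume_mean` *exactly* — this is the calibration mode used whenever a
cohort must be pinned to a target mean; the plain `lognormal` family
draws i.i.d.

**Optics and noise.** Channels are binary occupancy (lipid inside
spheres, ECM in the ≤ `ecm_gap` shell computed from the analytic sphere
surfaces), blurred by an anisotropic Gaussian `psf_sigma` (default
(2, 2, 4) µm — lateral blur of a low-NA objective, axial blur of a 4 µm
light sheet), attenuated by `exp(-z/L)` with `L = attenuation_length`
(default 400 µm, matching the usable-depth phenomenology of non-delipidated
cleared fat), then degraded by Poisson photon noise (`photon_scale`,
default 200 expected photons at unit intensity) plus Gaussian read noise
(`read_sigma`, default 0.01) — the standard sCMOS model. Setting blur to
0, `attenuation_length` to `inf` and noise to 0 yields the exact binary
rasterization, which the tests exploit.

**Default imaging geometry** follows the reference acquisition protocol:
1.62 µm lateral pixels, 4 µm z-step, fields of view of order millimetres,
usable depth ≲ 400 µm. Cohort-scale experiments in the tests and the
acceptance script render at 3.24 × 3.24 × 4 µm (lateral 2×2 binning) on a
1250 × 1250 × 320 µm domain with 450 cells — about 12M voxels per
phantom — so a two-cohort recovery run completes in a couple of minutes
on one CPU. These are the problem sizes this package treats as its
standard desk-scale conditions.

**What the phantoms do not contain:** deformed (non-spherical) cells,
crown-like immune structures, vasculature, staining heterogeneity,
refractive-index mismatch artifacts, tissue deformation. Consequently a
passing recovery test shows the pipeline is unbiased for *convex,
well-stained, sphere-like* cells under realistic blur, attenuation and
noise; it does not certify accuracy on strongly deformed or poorly
cleared tissue. Measured phantom sphericity is near 1 by construction,
while real adipocytes measure ≈ 0.8.

## Segmentation

The classical chain is `binarize → circular_open → separate_objects →
filter_objects`, all in physical units so anisotropic voxels are handled
uniformly.

- **Depth correction** (default on): a global threshold applied to
  depth-attenuated data cuts shallow cells at a lower fraction of their
  local edge amplitude than deep cells, inflating shallow radii and
  shrinking deep ones. The correction estimates per-slice foreground
  means via a rough Otsu split, fits `log(intensity)` linearly against
  depth, and divides the fitted exponential out (the slope is clamped to
  decay so noise cannot "brighten" with depth). This is the classical
  analogue of the intensity-robustness a trained segmenter has.
- **Thresholding**: Otsu by default; a fixed threshold is available.
  Enclosed holes are filled.
- **Circular open** removes regions that cannot accommodate a sphere of
  `open_radius` (default 10 µm, well under the smallest adipocyte radius
  of ~20 µm). It is realized as binary opening with an ellipsoidal
  footprint of per-axis voxel radii `round(radius/d)`; with a fixed
  footprint the operation is exactly anti-extensive and idempotent.
  Monotonicity in radius holds on isotropic grids; on strongly
  anisotropic grids the per-axis rounding can break strict nesting of the
  digital footprints (a known property of digital morphology), which is
  why the property tests exercise isotropic grids.
- **Separate objects** is a watershed on the negated Euclidean distance
  transform (computed with physical sampling), seeded by the h-maxima of
  the distance map with suppression depth `h_maxima` (default 4 µm):
  maxima shallower than 4 µm — distance-map ripple from surface
  roughness — do not spawn seeds, while genuine necks between ~20 µm+
  cells do. Every mask voxel is assigned to a basin (no watershed lines).
  The opening runs before separation by default; opening a label image is
  ill-defined, so when ordered the other way each separated object is
  opened individually (`open_before_separation=False`).
- **Filtering** drops objects below `min_volume` (default 20,000 µm³,
  below the smallest expected cell ~33,500 µm³ and above debris) and, by
  default, objects touching the grid boundary, whose volumes are clipped
  and biased low. Survivors are relabeled contiguously from 1.

The optional trainable backend (`adipo3d.learning`) is a logistic pixel
classifier over multi-scale Gaussian features trained by full-batch
gradient descent on annotated 2D slices, with a two-round schedule
(defaults 200 then 1500 iterations) mirroring the annotate/correct/retrain
workflow of commercial deep-learning segmenters, and per-iteration loss
logging. It is deliberately simple — a linear model, not a U-Net — and
exists to exercise the trainable code path under the same output contract
as `binarize`; the classical backend is the default everywhere.

## Morphometry

- **Volume** is voxel count × voxel volume; per-label volumes sum exactly
  to the total foreground volume.
- **Surface area** comes from a marching-cubes isosurface of the binary
  mask (level 0.5, physical spacing) followed by Taubin smoothing
  (λ = 0.5, ν = 0.53, 20 iterations). Raw voxel-face counting
  overestimates a sphere's area by ~50%, and raw marching cubes by ~9%
  (staircase); Gaussian field pre-smoothing removes the staircase but
  rounds sharp features — at σ = 1 voxel it shrinks a 40-voxel cube's
  area by 4.3%, and no σ handles both shapes. Taubin smoothing operates
  on the mesh with a pass-band filter that suppresses the voxel-frequency
  staircase without the volumetric shrinkage of plain Laplacian
  smoothing: measured errors are +0.9% for a radius-40-voxel sphere
  (Ψ = 0.990), −1.9% for a 40-voxel cube (Ψ = 0.822 vs 0.806 exact), and
  +2.7% for a 20 µm sphere on a 1.62 × 1.62 × 4 µm grid. Objects thinner
  than 2 voxels on any axis cannot be meshed; their area is reported as
  NaN and logged.
- **Sphericity** is defined as sphere-surface over object-surface,
  $\Psi = \pi^{1/3}(6V)^{2/3}/A$, so that the sphere attains the stated
  maximum of 1. (The other orientation of the ratio — object surface
  over sphere surface — would make 1 the *minimum*; the definition here
  keeps the conventional ceiling.) Meshing tolerance can push measured Ψ
  slightly above 1 on coarse anisotropic grids; values up to ~1.05 are
  possible for near-perfect spheres.
- **Centroids** are unweighted binary-mask centers of gravity, not
  intensity-weighted: lipid interiors are nearly uniform, and the binary
  centroid is insensitive to attenuation across a cell. (Switchable in
  principle; the unweighted version is what ships.)
- **NOD** is the centroid-to-centroid distance to the nearest other
  object, via a KD-tree, and matches brute-force all-pairs exactly. It
  requires ≥ 2 objects; with one object it is NaN (and an error when
  called directly).

## Group statistics

- Summaries report mean ± SEM with the **pooled per-cell n** (e.g.
  n = 1350 cells per group under the default 3 × 450 design), matching
  the convention that produces tight SEMs on per-adipocyte parameters.
  Class-distribution tables instead average per-sample histograms
  (n = number of animals), which is the convention used for distribution
  figures; both conventions coexist deliberately.
- **Mann–Whitney** U uses midrank ties; p-values are exact (full
  enumeration) when n₁+n₂ ≤ 12 without ties, else the normal
  approximation with tie and continuity correction. The U statistic of
  identical samples is n₁n₂/2.
- **Class bins** default to 50,000 µm³ (volume), 5 µm (NOD), 10 µm
  (equivalent diameter) and 0.04 (sphericity), consistent with the named
  class ranges of the reference conditions (e.g. "60–65 µm" NOD classes,
  "70–80 µm" diameter classes); exact reference bin widths are not
  published, so these are package defaults, fully configurable. Binning
  is left-closed/right-open with the last bin closed; underflow/overflow
  bins are appended only when data fall outside the spec'd range, so
  per-sample counts always sum to the cells retained.
- **FDR at Q = 5%**: the default is the two-stage step-up
  (Benjamini–Krieger–Yekutieli), the convention of the widely used
  GraphPad-style "FDR approach at Q"; the standard Benjamini–Hochberg
  step-up is available as `method="standard"`. Both are verified against
  brute-force implementations of their definitions, and the discovery
  set is monotone in Q. Bins empty in one group are skipped and logged.

## Calibrated recovery experiments

The headline validation pins a 450-cell cohort's true mean volume to a
calibration target (quantile matching makes the true sample mean exact),
renders at 3.24 × 3.24 × 4 µm, segments and measures with defaults, and
compares the measured mean to the target. Recovered means sit ~1.3–1.4%
low of the target across seeds; the residual bias is the curvature term
of thresholding a blurred sphere edge (the mid-level crossing of a
convex object sits slightly inside the true surface, ≈ σ²/r). The
acceptance band for these experiments is ±5%.

## Known limitations

- Sphericity of real, deformed adipocytes is validated only indirectly
  (cube/spheroid fixtures); phantom cells are spheres.
- The NOD of a phantom cohort is a property of the packing process, not
  a biological calibration target; only its computation (all-pairs
  minimum) is validated, not its distribution.
- The depth-correction fit assumes a single global exponential; laterally
  heterogeneous attenuation is not modeled or corrected.
- The trainable backend is a linear classifier and is not expected to
  outperform Otsu on well-behaved phantoms; it exists for protocol
  parity, not performance.
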