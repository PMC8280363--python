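# Methods

## Problem

Photodynamic therapy (PDT) of superficial skin lesions (the canonical case
is a port-wine stain) requires a prescribed irradiance — typically
100 ± 10 mW/cm² — over an irregular 3D surface. A flat LED panel driven
uniformly cannot deliver this: points seen obliquely or at larger standoff
fall below the band while the centre saturates. `pdtplan` models a 15 × 15
LED panel illuminating a scanned lesion point cloud and solves the per-unit
drive intensities so that every region of the lesion receives the target
irradiance.

## Radiometric model

Each LED unit is a generalized Lambertian emitter. With axial radiant
intensity `I0` (mW/Sr) and off-axis angle `φ`, the emitted intensity is

    I(φ) = I0 · cos^m(φ),      m = −ln 2 / ln cos(ψ),

where `ψ` is the half luminous angle (the angle at which intensity halves).
The irradiance a surface point with unit normal `n` receives from one unit is

    Ep = I0 · cos θ · cos^m(φ) / r²        [mW/cm²],

with `r` the unit-to-point distance in cm and `θ` the angle between `n` and
the point→LED direction. The panel field is the superposition over all 225
units, which is **linear** in the vector of per-unit intensities; the
planner exploits this by assembling an N × 225 illumination matrix `A`
(irradiance per unit intensity).

Assumptions and numerical choices:

- Back-facing geometry clamps to zero (`cos θ ≤ 0` or `cos φ ≤ 0`
  contributes nothing); no occlusion or self-shadowing test is performed —
  a known limitation for strongly concave targets.
- `I0` is interpreted as the delivered (post-lens) axial intensity; no
  separate lens-coupling factor is applied.
- All units share `ψ` (and hence `m`); the default device is a 15 × 15 grid
  at 10 mm pitch, `ψ` = 15° (m ≈ 19.994), drivable range 0–750 mW/Sr,
  nominal uniform drive 372 mW/Sr.
- Geometry is carried in mm (scanner convention); radiometry divides by 10
  so mW/Sr yields mW/cm².
- A useful analytic oracle: under an unbounded array the central irradiance
  tends to `2π·I0/(m+1)` independent of standoff. A 61 × 61 array
  reproduces this within 1%, and the 15 × 15 panel at 10 cm is within 5%
  at its centre.

## Segmentation

The colored cloud is projected through a long-focal pinhole camera looking
along the cloud's average normal (z-buffered, with a pixel→point index
map; resolution ≈ 1.2 px per median point spacing so ~99% of points get a
pixel). The image is converted sRGB→CIE-L\*a\*b\* and L\* is affinely
rescaled to a fixed range over projected pixels: a global lightness change
acts affinely on L\* (outside the near-black linear segment), so the
rescale cancels illumination drift. Pixels are scored by chromatic
saliency — distance in (a\*, b\*) to the background eigen-color minus
distance to the lesion eigen-color — and thresholded by Otsu's method.
Eigen-colors default to the two centroids of a seeded 2-class k-means in
(a\*, b\*), the redder (larger a\*) one taken as lesion; explicit seeds
may be supplied. The mask maps back through the index map to the lesion
sub-cloud. This saliency construction is a deliberately simple, testable
stand-in for the full saliency pipelines used on clinical imagery.

## Clustering

The lesion cloud is agglomerated under weighted centre-of-mass (WPGMC /
median) linkage — Lance–Williams coefficients α₁ = α₂ = ½, β = −¼, γ = 0
on Euclidean distances of the 3D coordinates only — and cut at a maximum
of 50 regions (the count at which one LED footprint covers roughly one
region; raising it to 70–100 changes the evaluation statistics only
marginally). Each region contributes its centroid and mean normal as one
prescription point. WPGMC needs the full pairwise distance matrix, so
clouds beyond 6,000 points are clustered on a seeded uniform subsample
and remaining points join the nearest subsample centroid; centres are
recomputed from the full membership.

## Intensity optimization

With `A_c` the K × 225 illumination matrix at the cluster centres and `Ẽ`
the prescribed irradiance (default 100 mW/cm² everywhere), the planner
solves the convex bound-constrained linear least-squares problem

    min_{I0}  ½ ‖A_c I0 − Ẽ‖²   s.t.   ls ≤ I0 ≤ hs,

via an active-set BVLS solver (deterministic global optimum; TRF polish
only if BVLS hits its iteration cap). Solutions are KKT-verified in tests:
vanishing gradient on interior coordinates, outward-pointing gradient at
active bounds. The comparison control drives all units at the largest
uniform intensity keeping the maximum point irradiance at or below the top
of the band (110 mW/cm²), clipped to the drivable range.

## Evaluation statistics

- **Effective proportion**: percentage of points whose irradiance lies in
  the closed band [90, 110] mW/cm² (closed because "100 ± 10" reads as an
  inclusive interval).
- **Coefficient of variation**: 100 · population SD / mean. At the cloud
  sizes used (>10⁴ points) the population-vs-sample choice changes results
  by < 0.01 pp.

## Synthetic surfaces and what they do (not) show

No scanned head data are distributed; all inputs are generated:

- **Plane**: 186 × 186 grid over a 10 × 10 cm panel-parallel square at
  10 cm (34,596 points). Under uniform 372 mW/Sr drive: max ≈ 110.8
  mW/cm², effective proportion ≈ 85.6%, CV ≈ 5.1%.
- **Cylinder / spherical cap**: convex surfaces facing the panel, apex at
  the stated standoff, sampled on a uniform grid in the panel-parallel
  projection — the depth-map convention of a structured-light scanner —
  with default grid pitches (0.74 mm cylinder, 0.625 mm cap) chosen to
  land near the reference cloud sizes (18,496 and 25,921 points). The
  r = 5 cm cylinder spans grazing incidence and is largely uncorrectable;
  the r = 10 cm cylinder is fully correctable (occupancy 100%, CV ≈ 1.2%
  after optimization).
- **Lesion patch**: a jittered grid on an elliptical patch of a head-sized
  ellipsoid (semi-axes 70/90/80 mm), oriented obliquely to all axes,
  carrying a nose-like 7 mm Gaussian ridge (facial lesion sites owe their
  control-plan non-uniformity to such small-radius features), an irregular
  painted lesion blob (~55% of the patch) with port-wine RGB against a
  skin tone, and Gaussian color noise (σ = 0.02). Defaults reproduce the
  scan statistics the fixture emulates: ~1,950 points at ~0.68 mm mean
  nearest-neighbor spacing. Generation is bit-reproducible per seed; the
  painted mask is stored as ground truth.

The fixtures emulate scanner geometry and color contrast, not scanner
noise models, specular highlights, hair, or multi-view occlusion — passing
tests show the pipeline's correctness and the optimizer's benefit on
realistic geometry, not clinical segmentation performance.

## Pose-sweep study

`run_scenario` evaluates nine poses — standoffs 120/110/100/90/80 mm at
normal incidence plus ±5°/±10° azimuthal swings (about the vertical axis
through the lesion centre) at 100 mm — and reports control vs optimized
effective proportion and CV per pose. On the default fixture the optimized
plan strictly improves both statistics in every pose (control ≈ 84–86% /
CV ≈ 12–13%; optimized ≈ 90–92% / CV ≈ 5%).

## Known limitations

- No tissue optics: the model targets surface irradiance only, not
  sub-surface fluence, photosensitizer concentration or photobleaching.
- No occlusion test; concave anatomy (nasal folds) would need one.
- The saliency segmenter is calibrated implicitly for red-on-skin-tone
  contrast; other lesion chromaticities need explicit seeds.
- Sampling of curved phantoms is projection-uniform; surface-uniform
  clouds weight oblique regions more heavily and give worse uniformity
  statistics for the same field.
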