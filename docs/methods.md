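# Methods

## Scope and design

This package studies how CT acquisition settings affect the test-retest
reproducibility of radiomic features. It has three parts: an 89-feature
radiomics engine organised in 15 feature classes; a synthetic tumor-phantom
module that emulates same-day repeat CT scans reconstructed at three slice
thicknesses (1.25, 2.5, 5 mm) under a sharp ("lung", L) and a smooth
("standard", S) kernel; and a concordance module built on Lin's concordance
correlation coefficient (CCC) with Dixon's Q outlier screening. The pipeline
ties these together: cohort -> feature table -> per-feature CCC for the 6
identical-setting comparisons (scan 1 vs scan 2 at the same setting) and the
3 equal-thickness cross-kernel comparisons (scan 1 at L vs scan 2 at S).

All volumes use (z, y, x) axis order with per-axis spacing in mm. NRRD and
NIfTI-1 I/O goes through SimpleITK; spacing metadata is required, never
defaulted to 1 mm.

## The feature registry

The registry is a versioned text table pinning 89 features in 15 classes:
Size 3, Shape 4, Shape-Index 9, Sigmoid 2, First-order 8 (Mean/SD/Skewness/
Kurtosis in 2D and 3D), GLCM 17, GTDM 5, Spatial-Correlation 2, Run-Length
11, Laws 5, Edge-Frequency 4, Gabor 2, Wavelets 8, LoG 8, Fractal 1.
The Sigmoid class registers the amplitude and width medians; the boundary-fit
baseline is still returned by the operator but not registered, because it
describes the surrounding parenchyma rather than the tumor margin.

Conventions fixed for reproducibility: population (1/n) moments and excess
kurtosis for first-order statistics; flat ROIs give SD = Skewness =
Kurtosis = 0; all texture entropies use log base 2 with 0*log 0 = 0.

### Quantization

Matrix texture features (GLCM, GTDM, run length) consume a 64-level
equal-width quantization of the in-mask HU range, computed per (scan,
setting). This makes them exactly invariant under positive affine intensity
rescaling, which the suite asserts. A flat ROI quantizes to a single level.

### Texture geometry

All texture offsets are in-plane (2D), accumulated over axial slices,
because CT voxels are strongly anisotropic at 2.5 and 5 mm slice thickness.
GLCM uses distance-1 offsets at 0/45/90/135 degrees, summed into one
symmetric matrix (over directions and over slices with at least 16 in-mask
pixels) and normalised once; feature values therefore match a brute-force
pair-enumeration oracle to 1e-10, which the suite checks, as it does for
GTDM (Amadasun-King with an in-plane 3x3 neighborhood and 1e-12 denominator
guards), run length (4 in-plane directions, out-of-mask pixels break runs),
Laws (zero-mean separable 5x5 kernels from L5/E5/S5, asymmetric pairs
averaged, reflection padding), edge frequency (mean absolute difference at
pixel distances 1-3 over 4 axis directions), and lag-1 spatial correlation.

### Shape and surface

- Compactness (6*sqrt(pi)*V/S^1.5) uses a marching-cubes surface after
  Gaussian smoothing of the binary mask (sigma = 1 voxel). Smoothing removes
  the staircase bias that otherwise overestimates the area of smooth digital
  solids by ~10%; a digital ball then measures within a few percent of 1.
- Roundness uses the Crofton perimeter on the largest axial slice (in-plane
  pixels are isotropic in CT).
- Solidity counts voxel centres inside the convex hull of the mask's voxel
  centres, which keeps the ratio at most 1 for convex digital shapes.
- The shape index is computed from implicit-surface curvatures of a
  Gaussian-smoothed level-set embedding of the mask, evaluated at surface
  voxels, with sigma = 1.5 voxels. Sigma = 1 voxel leaves enough
  discretization anisotropy that a digital ball's near-umbilic points leak
  out of the cap bin; 1.5 voxels suppresses this without flattening
  millimetre-scale spiculation. Umbilic points map to sign(k1) * 1.
- The fractal dimension is surface box counting over the 26-connected
  boundary shell at box sizes 1/2/4/8 voxels. The count at each scale is
  averaged over the eps diagonal grid offsets; without offset averaging,
  box-grid alignment alone shifts the fitted slope by ~0.15 on axis-aligned
  solids.

### Boundary sigmoid fits

Up to 100 outward surface normals (deterministically subsampled) are sampled
by linear interpolation at 0.5 mm steps over +/-4 mm, then fit with
I(d) = B + A/(1 + exp((d - d0)/w)) by least squares; fits whose residual
norm exceeds half the profile's dynamic range are discarded and medians of
A, w, B are reported. Signed distances are Euclidean in mm (negative
inside), with the voxel-centre distance transform shifted half a (minimum)
voxel step toward the interface so first shells sit near +/- half a voxel.

### Multiscale filters

- Gabor: quadrature filters, wavelength 4 px, sigma 2 px, orientations 0 and
  90 degrees; the real kernel is made zero-mean so constants give exactly 0.
- Wavelets: orthonormal 2D Haar (periodization), 2 levels, on the bounding
  box crop with out-of-mask pixels filled by the in-mask mean; the feature is
  the mask-weighted mean squared coefficient divided by the subband's
  pixels-per-coefficient, so level-1 energies of a full square satisfy
  Parseval against the image mean square. Level 2 requires a 4x4 bounding
  box.
- LoG: scale indices s = 1..4 map linearly to in-plane sigmas {0, 5/6, 5/3,
  2.5} px; s = 1 is the raw image (its Mean equals the first-order 3D mean).
  Uniformity is the sum of squared histogram fractions with a fixed bin
  width, (raw in-mask range)/64, at every scale. The fixed width (rather
  than per-response min-max bins) is what makes uniformity increase with
  smoothing — the response distribution narrows into fewer bins — matching
  the intended "smoothing concentrates the histogram" behaviour.

### Degenerate ROIs

Every operator has a stated minimum (surface voxels, bounding-box size,
pair counts). Below it the operator returns NaN ("Not Available") with a
logged reason; it never crashes and never silently returns 0. Summary
tables count NA features as non-reproducible; heat-map cells stay empty.

## The synthetic cohort

The phantom emulates, at desk scale, the structure of a same-day repeat CT
lung study: per subject one fixed anatomy, two acquisitions differing only
in a small rigid displacement and independent noise, and reconstruction of
each acquisition at all six settings.

- High-resolution grid: 0.625 mm isotropic, 72 x 80 x 80 voxels, so the
  three slice thicknesses are exact z-slabs of 2/4/8 voxels.
- Tumor: sphere of radius 5-12 mm (sampled per subject) at ~0 HU in a
  -850 HU lung-like background; interior texture is a Gaussian random field
  (SD 20-60 HU, correlation length 1.5-4 mm); optional margin spiculation as
  a degree-2..5 spherical-harmonic radial perturbation (amplitude 0-0.3);
  an optional adjacent vessel (probability 0.3) as a soft-tissue cylinder
  tangent to the tumor, excluded from the ground-truth mask.
- Acquisition: rigid translation drawn per scan (SD 1 mm per axis, linear
  interpolation) plus white Gaussian noise (SD 20 HU).
- Reconstruction: z slab averaging (mask by slab majority), then in image
  space a Gaussian blur of sigma 1 mm for the smooth kernel or unsharp
  enhancement (alpha = 1, sigma 1 mm) for the sharp kernel. This captures
  the sharp/smooth noise-texture contrast without a projection-domain CT
  model; kVp/mAs/dose physics and beam hardening are deliberately out of
  scope.

What the phantom does not emulate: real lung parenchyma texture and vessels
throughout the background, respiratory deformation, segmentation-reader
variability (ground-truth masks are exact), scanner-specific modulation
transfer functions, and the HU calibration chain. Passing cohort tests
therefore demonstrates that the pipeline recovers the expected ordering of
reproducibility effects (kernel mismatch degrades texture concordance much
more than size/density concordance; thicker, sharper settings are noisier),
not that absolute CCC values transfer to patient data.

The default cohort size is 30 subjects — comparable to the ~30-patient
repeat-CT cohorts used in this literature, and the largest n for which
Dixon's Q critical values are tabulated, keeping the outlier screen
applicable.

## Concordance analysis

- Lin's CCC uses population (1/n) variances: ccc = 2*s_xy /
  (s_x^2 + s_y^2 + (mean_x - mean_y)^2). With small n the 1/n-vs-1/(n-1)
  choice is material, so it is pinned and tested against hand-derived
  values. Identical constant vectors give 1.
- Outlier screening is an explicit policy, not a manual removal: per feature
  and setting pair, Dixon's Q (two-tailed, alpha = 0.05, n <= 30) is applied
  to the per-subject paired differences; a significant suspect is removed
  and the screened CCC reported alongside the raw one.
- The 2D-vs-3D CCC comparison uses a paired subject bootstrap (resample
  subjects, recompute both CCCs, percentile two-sided p; 2000 resamples,
  seeded), since agreement indices have no exact small-sample difference
  test.
- No multiple-testing correction is applied; the output metadata records
  this.
- Cut-off summaries count features with CCC at or above {0.85, 0.90, 0.95}
  per setting pair, with percentages of 89 rounded to integers; 0.85 is the
  conventional reproducibility threshold.

## Determinism and output format

A single global seed fans out to per-stage seeds through SHA-256, so stages
are isolated but the whole run is reproducible: identical configurations
produce byte-identical CSVs (asserted in the suite). CSV numerics use 10
significant digits; every run writes a metadata JSON with the registry
version, config hash and stage seeds.

## Problem sizes

The packaged study runs 30 subjects x 2 scans x 6 settings (360 feature
extractions) in a few minutes on one CPU; unit and oracle tests use <= 8x8
fixtures and ~30-voxel-diameter digital solids.
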