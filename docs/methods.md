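# Methods

This note records the models implemented in `rvspect`, their assumptions,
the defaults and why they were chosen, and the known limitations. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The projector

The system model is a rotation-based parallel-hole SPECT projector. For
each view the source and the attenuation map are rotated into the
detector frame (detector along +y, rotation axis z, rotation center the
matrix center, bilinear in-plane interpolation, out-of-field values
zero); each plane parallel to the detector is multiplied by its
accumulated attenuation factor, convolved with a distance-dependent
Gaussian point-spread function, and the planes are summed toward the
detector. Counts scale as

```
counts = calibration [counts·mL/(MBq·s)] × time_per_view [s] × voxel volume [mL] × Σ planes
```

**Rotation and adjointness.** The rotation is materialized as a sparse
bilinear-interpolation matrix per (shape, angle), and the back-projector
applies its transpose. The forward/back pair is therefore an *exact*
algebraic adjoint for every configuration (attenuation, PSF, multi-bed,
detector mask) — the property the EM update relies on. The price is that
the adjoint of a gather-type interpolation is a splat, which carries a
high-frequency interpolation texture of a few percent in back-projected
images (the radially averaged profile of a uniform back-projection is
flat to well under 2%, the point-wise texture is ~5%). A smoother,
gather-based back-rotation would trade this texture for a broken adjoint
pair; exactness was chosen.

**Attenuation.** CT-like volumes in HU are converted to density by a
piecewise-linear map anchored at air (−1000 HU → 0 g/cm³) and water
(0 HU → 1 g/cm³), then to linear attenuation by thresholding into soft
tissue and bone at 1.15 g/cm³ and scaling by per-material mass
attenuation coefficients (defaults 0.136 and 0.150 cm²/g, approximate
values at the 208 keV photopeak of ¹⁷⁷Lu; the table is configurable).
Attenuation accumulates plane-by-plane along the rotated projection axis
(half of a voxel's own μ·Δy plus all planes nearer the detector), not by
independent ray tracing — consistent with the rotation-based design and
giving a cheap exact adjoint.

**Collimator-detector response.** The distance-dependent resolution is a
Gaussian with

```
FWHM(d)² = intrinsic_fwhm² + (hole_diameter · (L + d) / L)²
```

(L the effective hole length), the standard geometric collimator model.
Defaults (hole 3.0 mm, L 50 mm, intrinsic 3.8 mm) approximate a
medium-energy parallel-hole collimator: roughly 10 mm FWHM at 10 cm.
Kernels are separable, truncated at 4σ and renormalized to sum exactly 1,
so counts are conserved. The PSF distance of a plane is
`orbit_radius + (signed distance of the plane behind the rotation axis)`,
clamped at zero.

**Scatter.** An effective-scatter-source model: the activity is convolved
with a normalized isotropic mono-exponential kernel (default decay length
30 mm), scaled by an amplitude (default 0.3, a typical scatter-to-primary
ratio for ¹⁷⁷Lu at 208 keV), and projected like a source; the term enters
the EM denominator additively and is never deconvolved. An optional
mean-scatter-energy mode projects the scatter source through an
attenuation map scaled by a single factor (default 1.1) representing the
higher attenuation at the mean scattered-photon energy. This two-energy
weighting is a simplification and is **not validated**; the default keeps
the photopeak map. Scatter is disabled by default in the synthetic
studies so that their reference values stay exactly self-consistent.

**Multi-bed.** Acquisitions with several bed positions project and
back-project the source once per bed with the bed's axial offset applied
to the detector window (offsets are rounded to whole axial voxels);
frames are ordered bed-major. A `detector_mask` marks valid pixels when
the physical camera is smaller than the projection matrix; masked pixels
are excluded from both the data term and the sensitivity.

## Source representations

A `SourceModel` couples a fine *internal* grid (default
1.105 × 1.105 × 4.42 mm³, matching the resolution at which region maps
are drawn) with a coarser *emulated* grid (internal × integer factor,
default 4.42 mm³ isotropic) that the projector sees. Down-sampling is a
block mean, up-sampling a partition; both conserve total activity to
machine precision, which the tests assert at 1e-12.

A region map labels every internal voxel; label 0 means "no region".
During the regional-voxel OS-EM update, the back-projected ratio and the
sensitivity are up-sampled to the internal grid and averaged within each
region *before* their quotient is taken. A literal average of the ratio
image alone would not reduce to the maximum-likelihood update for region
basis functions; the quotient-of-averages does, and its fixed point on
noise-free self-projected data is the true regional concentration (the
inverse-crime test exercises exactly this). Whether the averages should
additionally be sensitivity-weighted is an open modeling question; the
unweighted mean is used and recorded here as an assumption. Label-0
voxels update voxel-wise at the emulated size, which is what makes mixed
cuboid/regional descriptions (and plain cuboid reconstruction, the
degenerate case of an all-zero map) fall out of the same code path.

Region maps can leave the first and last transversal slices unlabeled
(default 25 at the paper-scale 128-slice matrix, scaled down in the
desk-scale studies) so that zero-count projection rows from a camera
smaller than the matrix never enter a region.

## OS-EM

Views are assigned to subsets round-robin by angle-index stride, giving
every subset maximally separated angles; the initial estimate is uniform
(1.0 in source units); estimates are floored at a small positive value
(1e-12) after each update; voxels with zero sensitivity are frozen. None
of these choices is standardized in the field; they are fixed and
documented so runs are bit-reproducible. Defaults follow the convergence
behavior of the two representations: 40 iterations × 10 subsets for
cuboid voxels, 8 × 10 for regional voxels (regional estimates stabilize
much earlier because the basis has few degrees of freedom — the
acceptance suite measures the stabilization indices rather than assuming
them). Calibration divides reconstructions by the factor measured on a
uniform-cylinder phantom VOI.

## Recovery-coefficient PVC

η = V/S is estimated from the VOI voxel count (volume) and a
marching-cubes iso-surface (area). Marching cubes on a raw binary mask
overstates the area of smooth objects by ~9% (staircase artifact), so the
mask is first smoothed with a 1-voxel Gaussian — after which a digital
sphere's η is within ~1% of r/3 at the fine internal voxel size, and a
cube's within ~5% of a/6 (edge chamfering; exact voxel-face counting is
available as a diagnostic alternative, which instead overestimates smooth
surfaces by up to ~1.5×). η estimation is intended to run at the internal
(region-map) resolution.

The RC model `RC(η, n) = 1/(1 + αₙ η^(−βₙ))` rises monotonically with η
and tends to 1 for large objects. Fitting uses bounded nonlinear least
squares from (α, β) = (1, 1) with two perturbed restarts. The background
concentration for the spill-in correction comes from a shell VOI —
`dilate(outer) AND NOT dilate(inner)` with a 6-connected structuring
element, defaults inner 1 / outer 3 voxels; the radii are assumptions (no
standard exists) and configurable.

## Synthetic studies

The generator produces co-registered activity, density and region-map
volumes from painted geometric primitives (voxel-center membership — no
anti-aliasing — so that the activity map and the region map agree
exactly, the premise of the regional-voxel method). Two canned studies
mirror common experimental setups:

* **NEMA-like six-sphere phantom**: sphere volumes 1.2–113.1 mL
  (13.2–60 mm diameter) on a ring in an elliptical-cylinder torso; hot
  spheres at 0.8 MBq/mL over 0.08 MBq/mL background (ten-fold contrast,
  typical of post-therapy imaging).
* **Abdominal organ phantom**: kidney-like ellipsoids (~110 mL), a
  spleen-like ellipsoid (~100 mL) and a 29 mL tumor sphere in a warm
  torso, at ¹⁷⁷Lu-like uptake levels (0.4 / 0.25 / 0.8 / 0.05 MBq/mL).

Acquisition defaults mimic a clinical protocol: 60 views over 360°, 45 s
per view, 4.42 mm detector pixels, circular orbit just outside the
phantom. The studies here run at a 64³ emulated matrix (283 mm field of
view) with a two-fold finer in-plane internal grid — a deliberate
reduction from the clinical 128³/four-fold setting that keeps the full
pipeline (including 400-update cuboid reconstructions and multi-seed
noise ensembles) tractable on one CPU while preserving count densities:
the default calibration yields a few million total counts per study,
comparable to post-therapy acquisitions.

Noise comes in two flavors: independent Poisson draws on expected counts,
and a list-mode-style bootstrap that splits a single noisy parent
acquisition's counts multinomially into time bins and resamples bins with
replacement — reproducing the statistical structure of resampled
one-second list-mode bins (expected totals conserved; per-pixel variance
Poisson-like at high counts) without requiring list-mode data.

## Misalignment experiment

SPECT/CT misregistration is emulated by translating the density map
(linear interpolation) and the region map/VOIs (nearest neighbor, so
labels stay integral) before estimation while the projections stay fixed;
shifting the derived maps is equivalent to shifting the CT before
segmentation for a rigid translation. Default sweep: −10 mm to +10 mm in
2 mm steps per axis. A margin filter on structure centroids (default
20 mm from the transaxial field-of-view edge) is available to exclude
peripheral structures whose background shells would leave the field of
view.

## What the synthetic studies do and do not show

Projections are generated by the same projector used in reconstruction
(an inverse crime, used deliberately): self-consistency results —
regional voxels recovering truth to a fraction of a percent — certify the
estimator's correctness, not its clinical accuracy. Real acquisitions add
septal penetration, energy-window scatter beyond the kernel model,
detector motion, intra-regional uptake heterogeneity, and — most
importantly — segmentation error, none of which the phantoms contain.
The method-comparison and misalignment findings (regional voxels above
cuboid+PVC above uncorrected; graceful degradation under misregistration)
are structural properties of the estimators that transfer qualitatively;
the specific error magnitudes do not.

## Known limitations

* No Monte Carlo photon transport, septal penetration, energy spectra,
  dead time, or detector energy resolution.
* The mean-scatter-energy scatter variant is a single-factor placeholder.
* Regional voxels assume region-wise uniform activity; heterogeneous
  uptake within a region biases its mean estimate.
* The Metz-derived aperture response is approximated by its Gaussian
  geometric-FWHM equivalent.
* Bed offsets are rounded to whole axial voxels.
* Anisotropic internal voxels make the 1-voxel η smoothing and the
  6-connected dilation shells anisotropic in mm; both are documented
  behavior, not bugs.
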