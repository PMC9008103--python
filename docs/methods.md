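# Methods

This note records the models, numerical choices and limitations behind
`petharm`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The harmonization model

Two tomographs imaging the same object are modeled as linear systems
with isotropic Gaussian point-spread functions (PSFs).  If the
high-resolution scanner has PSF FWHM `a` and the low-resolution scanner
`b > a`, then blurring the high-resolution image with a kernel of FWHM
`√(b² − a²)` matches the two resolutions exactly (Gaussian
semigroup).  The package does not assume the PSFs are known: it
recovers the matching kernel empirically, as the argmin of the
voxel-wise SSE between the (down-sampled, kernel-blurred)
high-resolution phantom image and the (zero-padded, rigidly registered)
low-resolution image, over FWHM ∈ {0, 0.5, …, 10} mm.  With the default
scanner models (PSFs 3.00 mm and 5.41 mm) the quadrature prediction is
4.50 mm, which lies on the grid; the grid search is validated against
that closed form rather than against itself.

Pipeline order (fixed, matching the phantom experiment): down-sample
the high-resolution image to the low-resolution grid → zero-pad the
low-resolution image to the common dimensions → register it once, at
FWHM 0 → sweep kernels, re-using that registration.  Re-registration
per kernel is available behind a flag but off by default.  Ties in the
SSE break toward the smaller FWHM — the least aggressive degradation.

For dynamic data, `harmonize` applies the same kernel to every frame
independently; when a target grid is supplied the default order is
resample-then-blur, mirroring the phantom pipeline (the alternative
blur-at-native-resolution order is available via `order=`).

## Image primitives

* **Grids.** Axis-aligned voxel grids; physical coordinates are
  measured from the centroid of the voxel centers, so resampling and
  padding keep the image physically centered.  When an axis needs an
  odd number of pad voxels the extra voxel goes on the high-index side
  (a fixed convention so padded images are bit-reproducible).
* **Interpolation.** Trilinear everywhere (resampling, rigid
  resampling, registration), with out-of-field samples set to zero —
  appropriate for an object in air.  Trilinear interpolation is exact
  for affine intensity fields, which the tests exploit as an oracle.
* **Gaussian blur.** Separable sampled kernel, σ_vox =
  (FWHM/2√(2 ln 2))/spacing per axis, truncated at 4σ, zero-extension
  boundaries.  On any axis where the requested FWHM is smaller than the
  voxel pitch the sampled kernel collapses to a delta and the axis is
  left untouched.  This discretization makes the SSE sweep exactly flat
  for kernels below the low-resolution voxel size (2.06 mm on the
  default grid), which is the behavior the method's flat-region
  property describes; a band-unlimited implementation would instead
  show a slow SSE decline there.
* **Registration.** Six-parameter rigid (three rotations about the
  image center in degrees, three translations in mm), SSE cost,
  Powell's derivative-free local search from the identity, trilinear
  sampling.  Tolerances (`xtol` 1e-4, `ftol` 1e-8, `maxiter` 2000) are
  configuration; parameters and cost are logged.  The returned
  transform never scores worse than the identity; constant images warn
  and return the identity.  On same-resolution phantom images the
  search recovers synthetic offsets to ≲0.02 mm / 0.02°; between images
  of *different* resolution the SSE minimum is genuinely displaced from
  the true pose (the resolution-mismatch residual is pose-dependent),
  which is why the kernel search tolerates a one-grid-step shift under
  inter-scanner offsets.

## SRTM kinetics

Forward model: C_T = R1·C_R + (k2 − R1·k2a)·(C_R ⊛ e^{−k2a t}), with
k2a = k2/(1+BP_ND).  The convolution is evaluated on a uniform fine
grid (dt = 0.01 min) by trapezoidal quadrature (computed via FFT
convolution with endpoint correction); reported frame values are
time-averages of C_T over each frame, not midpoint samples.

Fitting uses the basis-function formulation: for each k2a on a
log-spaced grid (128 points in [0.006, 0.6] min⁻¹ by default) the model
is linear in (θ1, θ2) = (R1, k2 − R1·k2a); the grid minimizer of the
residual sum of squares is refined by a bounded scalar search between
its grid neighbors, removing the grid-resolution floor on parameter
accuracy.  The measured reference TAC itself serves as the θ1
regressor; the basis integral uses a fine reference curve reconstructed
by linear interpolation through zero and the frame midpoints (flat
after the last midpoint).  Frame weights are uniform by default
(duration weighting via configuration).  A winning k2a at the grid
boundary logs a warning.  BP_ND is invariant to global rescaling of
both TACs.  Noiseless recovery over R1 ∈ {0.8–1.2}, k2 ∈ {0.2–0.4}
min⁻¹, BP_ND ∈ {0.5–5} is verified to <1 % relative in the tests; the
residual bias is dominated by the midpoint interpolation of the
reference curve within the early 0.5-min frames.

The synthetic reference (cerebellum) curve is a difference of
exponentials A·(e^{−λ1 t} − e^{−λ2 t}) with defaults A = 20 000 Bq/mL,
λ1 = 0.03 min⁻¹, λ2 = 0.6 min⁻¹ — zero at injection, a single peak
near 5 min, slow washout; frame averages use the closed-form
antiderivative.

## Synthetic data: what it emulates, what it does not

A scanner is modeled as *PSF + voxel grid + noise* acting on images
that are already fully corrected (decay, attenuation, scatter, dead
time, randoms) — the same post-reconstruction products the
harmonization method consumes.  Reconstruction internals (OSEM
iterations, sinogram statistics) are deliberately not simulated.
Consequences: simulated noise is Gaussian with standard deviation
`noise_scale·√(activity/frame_duration)` (shorter frames noisier),
spatially white on the scanner grid, rather than the spatially
correlated noise OSEM produces; and scanner PSFs are exactly Gaussian
and spatially invariant, whereas real tomographs vary from center to
edge (the published ranges — 2.3–3.4 mm for the HRRT class, 4.1–7.8 mm
for the HR+ class — motivate the 3.00 / 5.41 mm defaults, chosen inside
those ranges so that the quadrature difference lands on the 0.5 mm
sweep grid).  Passing tests therefore demonstrate the method's
correctness under its own resolution model, not robustness to
non-Gaussian or spatially varying PSFs.

Geometry is parametric ellipsoids on a 1 mm master grid: a uniform
brain cavity for the phantom (single-compartment mode — every cavity
voxel holds the same concentration, default 70.22 kBq/mL); for dynamic
subjects, a brain shell with bilateral striatal ellipsoids (BP_ND = 3.0),
a cerebellar reference region carrying the reference curve exactly, and
background tissue (BP_ND = 0.3), all with R1 = 1.0 and k2 = 0.3 min⁻¹.
Masks are generated with the images, so no atlas registration exists or
is needed.  Inter-subject variability perturbs striatal size (±10 %)
and position (±1.5 mm).  The default master grid is 96³ for the
phantom and 80×96×80 for subjects — sizes at which the full study runs
in minutes on one core while leaving ≥10 voxels of air around the head.

The default 27-frame schedule is 6×0.5 + 3×1 + 2×2 + 16×5 min = 90 min.
F-18 decay bookkeeping for the static phantom uses the 109.77-min
half-life.

## The validation study

Three inter-scanner subjects are each acquired on both scanner models
(zero pose offset — the method assumes registered inputs — with
calibrated noise); the high-resolution scan is additionally harmonized
(resampled to the low-resolution grid, blurred with the kernel found on
the phantom) and all three BP_ND values are compared pairwise against
the low-resolution scan via PD.  Eight test–retest subjects are each
acquired twice on the low-resolution scanner with independent noise and
independent small pose offsets (uniform within ±2 mm, ±1°).  Because
ROI masks live in subject space, each test–retest session is first
aligned by registering its duration-weighted time-average to a
noiseless reference acquisition of the same subject — the analysis-side
counterpart of the registration/motion-correction step every real
pipeline applies; residual registration error then contributes
realistically to PD_T/RT.

`noise_scale` (default 300, `CALIBRATED_NOISE_SCALE`) is a simulator
calibration: it was set so the synthetic test–retest PD lands in a
plausible few-percent range, the regime reported for striatal
raclopride endpoints, and it is documented as a calibration constant,
not a measured quantity.  Day-to-day biological variation is not
modeled, so the synthetic PD_T/RT is noise- and repositioning-driven
only.

Summary statistics are means ± sample SD (ddof = 1) over subjects, with
the whole striatum as a single bilateral ROI and unweighted voxel means
for TACs.  PD uses the absolute difference (a signed variant exists for
directionality checks, since the sharper scanner's BP_ND is
systematically the larger).

## Degenerate inputs and tie-breaks

* Empty kernel grids, non-increasing grids, negative FWHM, non-positive
  spacings/dims, non-contiguous schedules, empty masks, grid
  mismatches, all-zero reference TACs: rejected with `ValueError`.
* Equal-resolution inputs to the kernel search warn and proceed (the
  sweep then selects 0 mm on noiseless identical images).
* Test–retest pairs with equal seeds warn (the sessions would be
  identical).
* SSE ties on the kernel grid select the smallest FWHM and log it.

## Known limitations

* Pairwise harmonization only (one high-resolution, one low-resolution
  scanner), with a single isotropic, spatially invariant kernel.
* Rigid SSE registration only; no mutual-information cost, no
  motion correction within a scan, no oblique grids.
* ROI-level SRTM is the validated path; voxelwise parametric imaging is
  out of scope.
* The digital phantom's uniform-fill mode ignores the internal
  structure a physical anthropomorphic phantom has; only the
  uniform-concentration use is replicated.
* No plasma-input models, SRTM2, or hypothesis testing between cohorts
  (descriptive means ± SD only, as the study design calls for).
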