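# petharm

Harmonization of brain PET images acquired on scanners of different
spatial resolution, for studies that need to pool or compare outcome
measures across tomographs.

When the same subject is scanned on a high-resolution scanner (an
HRRT-class tomograph, ~3 mm FWHM) and a lower-resolution one (an
HR+-class tomograph, ~5.4 mm FWHM), partial-volume effects depress
small-structure outcome measures differently on each scanner: striatal
binding potential from a raclopride-like tracer comes out systematically
higher on the sharper scanner. `petharm` implements the matched-filter
remedy: find, on a uniform phantom, the isotropic Gaussian kernel that
makes the high-resolution images match the low-resolution ones, then
degrade the high-resolution data with that kernel before analysis.

## Method

**Kernel determination.** The high-resolution phantom image is
down-sampled (trilinear) onto the low-resolution scanner's voxel grid,
the low-resolution image is zero-padded to the same dimensions and
rigidly registered to it, and a grid of isotropic Gaussian kernels
(FWHM 0–10 mm in 0.5 mm steps) is swept.  Each candidate is scored by
the voxel-wise sum of squared errors

    SSE(f) = Σ_i ( y_i^hi(f) − y_i^lo )²,

summed over all image voxels; the minimizing FWHM is the harmonization
kernel.  For Gaussian point-spread functions the expected optimum is the
quadrature difference of the two scanner resolutions,
√(FWHM_lo² − FWHM_hi²); with the package's default scanner models
(3.00 mm and 5.41 mm) that is √(5.41² − 3.00²) = 4.50 mm.

**Endpoint.** Dynamic data are analyzed with the simplified reference
tissue model (SRTM).  A target-region TAC C_T is modeled from the
reference-region (cerebellum) TAC C_R as

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a) ∫₀ᵗ C_R(u) e^{−k2a(t−u)} du,
    k2a = k2 / (1 + BP_ND),

fitted by the basis-function method; the striatal non-displaceable
binding potential BP_ND is the outcome measure.

**Comparison statistic.** Endpoint pairs are compared with the percent
difference PD = 100·|a − b| / ((a + b)/2), used both between scanners
and between test and retest sessions on one scanner (PD_T/RT).
Harmonization succeeds when the inter-scanner PD of harmonized data
falls below the within-scanner test–retest variability.

Because no scanner data ship with the package, a synthetic-data module
generates everything the pipeline consumes: a uniform single-compartment
digital brain phantom, dynamic subjects with high-binding striatum /
reference cerebellum / low-binding background, and a scanner forward
model (isotropic Gaussian PSF + voxel grid + count-scaled Gaussian
noise).

## Worked example

```python
from petharm import GaussianKernelMatcher, hrrt_like, hr_plus_like
from petharm.synthetic import PhantomSpec, make_uniform_phantom, simulate_scan

phantom, _ = make_uniform_phantom(PhantomSpec())     # 96³ @ 1 mm, 70.22 kBq/mL
hi = simulate_scan(phantom, hrrt_like((96, 96, 96)))       # 3.00 mm PSF
lo = simulate_scan(phantom, hr_plus_like((96, 96, 96)))    # 5.41 mm PSF

matcher = GaussianKernelMatcher(target_spacing=(2.06, 2.06, 2.4),
                                target_dims=lo.dims)
matcher.fit(hi, lo)
print(matcher.optimal_fwhm_)
# 4.5
```

The selected 4.5 mm kernel is the quadrature difference of the two
scanner PSFs, recovered purely from the images.  The full validation
study (3 inter-scanner subjects, 8 test–retest subjects, calibrated
noise) then orders the endpoint comparisons:

```python
from petharm import run_validation_study
res = run_validation_study(seed=1)
print(res.summary.to_string(index=False))
#         metric     mean       sd  n
#  PD unfiltered 7.537198 3.064868  3
#  PD harmonized 2.822299 2.388537  3
# PD test-retest 5.043911 3.416334  8
```

Unfiltered inter-scanner percent differences (~7.5 %) exceed the
test–retest variability (~5.0 %); after harmonizing the
high-resolution scans with the 4.5 mm kernel the inter-scanner
difference (~2.8 %) drops below it, so pooled analyses are no longer
dominated by the scanner change.

The same operations are exposed on the command line
(`petharm simulate-phantom`, `find-kernel`, `apply`, `fit-srtm`,
`report`); every run writes a YAML manifest with its configuration and
seeds.

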