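"""Digital phantoms and a two-scanner acquisition simulator.

Everything the validation study measures is generated here:

* a uniform single-compartment brain phantom (an anthropomorphic
  fillable phantom used in uniform-fill mode: every cavity voxel holds
  the same F-18 activity concentration), for finding the harmonization
  kernel;
* dynamic raclopride-like "subjects" with a high-binding striatum, a
  cerebellum reference region and low-binding background tissue, built
  on a fine master grid from SRTM ground-truth kinetics;
* a scanner forward model: reconstruction is not simulated — a scanner
  is an isotropic Gaussian PSF, a voxel grid, and additive Gaussian
  noise applied to images that are already fully corrected (decay,
  attenuation, scatter, randoms), which is what the harmonization
  method consumes.

Scanner defaults describe an "HRRT-like" high-resolution tomograph
(3.0 mm PSF, 1.2 mm isotropic voxels; reported HRRT resolution spans
2.3-3.4 mm FWHM) and an "HR+-like" lower-resolution one (5.41 mm PSF,
2.06 x 2.06 x 2.4 mm voxels; reported HR+ resolution spans 4.1-7.8 mm
FWHM).  The PSF difference in quadrature, sqrt(5.41^2 - 3.0^2) = 4.50 mm,
makes 4.5 mm the expected harmonization kernel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .harmonization import DynamicImage
from .image import Image3D, RigidTransform, apply_rigid, gaussian_blur, resample_trilinear
from .kinetics import (
    FrameSchedule,
    ReferenceShape,
    SRTMParams,
    TAC,
    srtm_forward,
)

log = logging.getLogger(__name__)

#: F-18 half-life, minutes.
F18_HALF_LIFE_MIN = 109.77

#: Noise scale for dynamic acquisitions, chosen so that the synthetic
#: test-retest percent difference in striatal BP_ND lands in a
#: plausible few-percent range (see docs/methods.md).  This is a
#: simulator calibration constant, not a measured quantity.
CALIBRATED_NOISE_SCALE = 300.0

__all__ = [
    "F18_HALF_LIFE_MIN",
    "CALIBRATED_NOISE_SCALE",
    "Ellipsoid",
    "PhantomSpec",
    "ScannerModel",
    "SubjectSpec",
    "make_uniform_phantom",
    "make_dynamic_subject",
    "simulate_scan",
    "make_test_retest_pair",
    "activity_concentration_bq_ml",
    "decay_factor",
    "hrrt_like",
    "hr_plus_like",
    "resample_mask",
]


def activity_concentration_bq_ml(activity_mci: float, volume_ml: float) -> float:
    """Concentration (Bq/mL) of ``activity_mci`` mCi in ``volume_ml`` mL.

    1 mCi = 3.7e7 Bq; e.g. 2.9 mCi in 800 mL gives ~134.1 kBq/mL.
    """
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    return activity_mci * 3.7e7 / volume_ml


def decay_factor(dt_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Fraction of activity remaining after ``dt_min`` minutes."""
    return float(2.0 ** (-dt_min / half_life_min))


@dataclass(frozen=True)
class Ellipsoid:
    """An axis-aligned ellipsoid: center (mm, grid-centered coords) and
    semi-axes (mm)."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def __post_init__(self):
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError(f"semiaxes must be > 0, got {self.semiaxes}")

    def mask(self, spacing, dims) -> np.ndarray:
        axes = [
            ((np.arange(dims[i]) - (dims[i] - 1) / 2.0) * spacing[i] - self.center[i])
            / self.semiaxes[i]
            for i in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return xx**2 + yy**2 + zz**2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """A uniform single-compartment phantom: a union of ellipsoidal
    cavities filled with one concentration."""

    cavities: tuple[Ellipsoid, ...] = (
        Ellipsoid((0.0, 0.0, 0.0), (40.0, 34.0, 30.0)),
    )
    fill_bq_ml: float = 70220.0  # concentration at scan start
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dims: tuple[int, int, int] = (96, 96, 96)


def make_uniform_phantom(spec: PhantomSpec) -> tuple[Image3D, np.ndarray]:
    """Rasterize the phantom: cavity voxels at the fill concentration,
    zero elsewhere.  Returns the image and the boolean cavity mask."""
    mask = np.zeros(spec.dims, dtype=bool)
    for cav in spec.cavities:
        mask |= cav.mask(spec.spacing, spec.dims)
    if not mask.any():
        raise ValueError("phantom cavity is empty on this grid")
    values = np.where(mask, float(spec.fill_bq_ml), 0.0)
    return Image3D(values, spec.spacing), mask


def _derive_dims(fov_mm, spacing) -> tuple[int, int, int]:
    return tuple(int(np.ceil(f / s)) for f, s in zip(fov_mm, spacing))


@dataclass(frozen=True)
class ScannerModel:
    """A tomograph as the simulator sees it: isotropic PSF, voxel grid,
    and a noise scale (0 = noiseless)."""

    name: str
    psf_fwhm: float
    voxel_spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    noise_scale: float = 0.0

    def __post_init__(self):
        if self.psf_fwhm < 0:
            raise ValueError(f"psf_fwhm must be >= 0, got {self.psf_fwhm}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def hrrt_like(
    fov_mm=(96.0, 96.0, 96.0), noise_scale: float = 0.0, psf_fwhm: float = 3.0
) -> ScannerModel:
    """High-resolution scanner: 3.0 mm PSF, 1.2 mm isotropic voxels."""
    spacing = (1.2, 1.2, 1.2)
    return ScannerModel("HRRT-like", psf_fwhm, spacing, _derive_dims(fov_mm, spacing),
                        noise_scale)


def hr_plus_like(
    fov_mm=(96.0, 96.0, 96.0), noise_scale: float = 0.0, psf_fwhm: float = 5.41
) -> ScannerModel:
    """Lower-resolution scanner: 5.41 mm PSF, 2.06 x 2.06 x 2.4 mm voxels."""
    spacing = (2.06, 2.06, 2.4)
    return ScannerModel("HR+-like", psf_fwhm, spacing, _derive_dims(fov_mm, spacing),
                        noise_scale)


@dataclass(frozen=True)
class SubjectSpec:
    """A raclopride-like digital subject on a fine master grid.

    Regions are parametric ellipsoids; the cerebellum's TAC is exactly
    the reference curve, the striatum and background follow SRTM
    kinetics driven by it.
    """

    brain: Ellipsoid = Ellipsoid((0.0, 4.0, 4.0), (36.0, 44.0, 34.0))
    striatum: tuple[Ellipsoid, ...] = (
        Ellipsoid((-14.0, 10.0, 6.0), (9.0, 16.0, 9.0)),
        Ellipsoid((14.0, 10.0, 6.0), (9.0, 16.0, 9.0)),
    )
    cerebellum: Ellipsoid = Ellipsoid((0.0, -28.0, -16.0), (22.0, 12.0, 11.0))
    striatum_params: SRTMParams = SRTMParams(r1=1.0, k2=0.3, bp_nd=3.0)
    background_params: SRTMParams = SRTMParams(r1=1.0, k2=0.3, bp_nd=0.3)
    reference: ReferenceShape = ReferenceShape()
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dims: tuple[int, int, int] = (80, 96, 80)

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.dims, self.spacing))

    def perturbed(self, rng: np.random.Generator) -> "SubjectSpec":
        """A subject with slightly different anatomy: striatal size
        scaled by +-10% and centers shifted by <= 1.5 mm (inter-subject
        variability; PVE severity then differs between subjects)."""
        scale = rng.uniform(0.9, 1.1)
        striatum = tuple(
            Ellipsoid(
                tuple(np.asarray(e.center) + rng.uniform(-1.5, 1.5, 3)),
                tuple(np.asarray(e.semiaxes) * scale),
            )
            for e in self.striatum
        )
        return SubjectSpec(
            brain=self.brain,
            striatum=striatum,
            cerebellum=self.cerebellum,
            striatum_params=self.striatum_params,
            background_params=self.background_params,
            reference=self.reference,
            spacing=self.spacing,
            dims=self.dims,
        )


def make_dynamic_subject(
    spec: SubjectSpec, schedule: FrameSchedule | None = None
) -> tuple[DynamicImage, dict[str, np.ndarray]]:
    """Ground-truth dynamic image on the master grid plus region masks.

    Every voxel's time course equals its region's frame-averaged TAC;
    the cerebellum carries the reference curve itself.  Striatum and
    cerebellum must not overlap.
    """
    if schedule is None:
        schedule = FrameSchedule.default_dynamic()
    striatum = np.zeros(spec.dims, dtype=bool)
    for e in spec.striatum:
        striatum |= e.mask(spec.spacing, spec.dims)
    cereb = spec.cerebellum.mask(spec.spacing, spec.dims)
    if (striatum & cereb).any():
        raise ValueError("striatum and cerebellum region labels overlap")
    brain = spec.brain.mask(spec.spacing, spec.dims) | striatum | cereb
    background = brain & ~striatum & ~cereb

    ref_tac = spec.reference.frame_averages(schedule)
    str_tac = srtm_forward(spec.striatum_params, spec.reference, schedule).values
    bg_tac = srtm_forward(spec.background_params, spec.reference, schedule).values

    vals = np.zeros(spec.dims + (schedule.n_frames,))
    vals[background] = bg_tac
    vals[cereb] = ref_tac
    vals[striatum] = str_tac
    masks = {"striatum": striatum, "cerebellum": cereb, "background": background,
             "brain": brain}
    return DynamicImage(vals, spec.spacing, schedule), masks


def resample_mask(
    mask: np.ndarray,
    spacing,
    target_spacing,
    target_dims,
    threshold: float = 0.5,
) -> np.ndarray:
    """Carry a boolean master-grid mask onto a scanner grid: trilinear
    interpolation of the indicator, thresholded at ``threshold``."""
    img = Image3D(mask.astype(np.float64), spacing)
    out = resample_trilinear(img, target_spacing, target_dims)
    return out.values >= threshold


def _acquire_frame(
    frame: Image3D,
    scanner: ScannerModel,
    offset: RigidTransform,
    rng: np.random.Generator | None,
    duration_min: float,
) -> Image3D:
    out = apply_rigid(frame, offset) if not offset.is_identity() else frame
    out = gaussian_blur(out, scanner.psf_fwhm)
    out = resample_trilinear(out, scanner.voxel_spacing, scanner.dims)
    if scanner.noise_scale > 0:
        sd = scanner.noise_scale * np.sqrt(np.maximum(out.values, 0.0) / duration_min)
        out = out.with_values(out.values + rng.normal(0.0, 1.0, out.dims) * sd)
    return out


def simulate_scan(
    truth,
    scanner: ScannerModel,
    offset: RigidTransform | None = None,
    seed: int | None = None,
    static_duration_min: float = 15.0,
):
    """Acquire a ground-truth image on a scanner.

    Per frame: rigid pose offset -> PSF blur -> resample to the scanner
    grid -> additive zero-mean Gaussian noise with standard deviation
    ``noise_scale * sqrt(max(value, 0) / frame_duration_min)`` (shorter
    frames are noisier, as fewer counts are collected).  Deterministic
    given ``seed``; a seed is mandatory whenever noise_scale > 0.
    """
    if offset is None:
        offset = RigidTransform.identity()
    if scanner.noise_scale > 0 and seed is None:
        raise ValueError("seed is required when noise_scale > 0")
    rng = np.random.default_rng(seed) if seed is not None else None

    if isinstance(truth, DynamicImage):
        frames = [
            _acquire_frame(
                truth.frame(i), scanner, offset, rng, truth.schedule.frame_durations[i]
            )
            for i in range(truth.n_frames)
        ]
        return DynamicImage(
            np.stack([f.values for f in frames], axis=-1),
            scanner.voxel_spacing,
            truth.schedule,
        )
    return _acquire_frame(truth, scanner, offset, rng, static_duration_min)


def _small_offset(rng: np.random.Generator, max_mm: float, max_deg: float) -> RigidTransform:
    return RigidTransform(
        tuple(rng.uniform(-max_deg, max_deg, 3)),
        tuple(rng.uniform(-max_mm, max_mm, 3)),
    )


def make_test_retest_pair(
    truth: DynamicImage,
    scanner: ScannerModel,
    seeds: tuple[int, int],
    max_offset_mm: float = 2.0,
    max_offset_deg: float = 1.0,
) -> tuple[DynamicImage, DynamicImage]:
    """Two acquisitions of the same subject differing only in noise and
    in small independent pose offsets (<= 2 mm, <= 1 degree)."""
    if seeds[0] == seeds[1]:
        warnings.warn("test and retest seeds are equal; scans will be identical",
                      stacklevel=2)
    scans = []
    for seed in seeds:
        pose_rng = np.random.default_rng(seed)
        if max_offset_mm > 0 or max_offset_deg > 0:
            offset = _small_offset(pose_rng, max_offset_mm, max_offset_deg)
        else:
            offset = RigidTransform.identity()
        noise_seed = seed if scanner.noise_scale > 0 else None
        scans.append(simulate_scan(truth, scanner, offset, noise_seed))
    return scans[0], scans[1]
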