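"""Voxel-grid image type and the geometric/filtering primitives.

All physical coordinates are in mm, measured from the grid's physical
center (the centroid of all voxel centers), with axes aligned to the
array axes (RAS-aligned, no oblique handling).  Activity values are in
Bq/mL.  Out-of-field samples are treated as zero everywhere (an object
in air), both for interpolation and for Gaussian filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

log = logging.getLogger(__name__)

#: FWHM of a Gaussian = FWHM_TO_SIGMA^-1 ... conversion constant 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

__all__ = [
    "FWHM_PER_SIGMA",
    "Image3D",
    "RigidTransform",
    "resample_trilinear",
    "pad_to_dims",
    "gaussian_blur",
    "apply_rigid",
    "register_rigid",
    "sse",
]


@dataclass(frozen=True)
class Image3D:
    """A 3D scalar volume with per-axis voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (activity concentration, Bq/mL).
    spacing : tuple of float
        Voxel spacing (sx, sy, sz) in mm; all components > 0.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={values.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        """Physical extent (dims * spacing) per axis, mm."""
        return tuple(n * s for n, s in zip(self.dims, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis,
        measured from the grid center."""
        n = self.dims[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing[axis]

    def with_values(self, values: np.ndarray) -> "Image3D":
        return Image3D(values, self.spacing)

    def same_grid(self, other: "Image3D") -> bool:
        # spacing tolerance absorbs float32 NIfTI header round-off (sub-nm)
        return self.dims == other.dims and np.allclose(
            self.spacing, other.spacing, rtol=1e-5, atol=1e-6
        )


@dataclass(frozen=True)
class RigidTransform:
    """A rigid-body transform: rotation about the image center, then translation.

    ``rotations`` are (rx, ry, rz) in degrees applied extrinsically in
    x, y, z order; ``translations`` are (tx, ty, tz) in mm.  The mapping
    is ``p' = R p + t`` in centered physical coordinates.
    """

    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "rotations", tuple(float(r) for r in self.rotations))
        object.__setattr__(
            self, "translations", tuple(float(t) for t in self.translations)
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix."""
        return Rotation.from_euler("xyz", self.rotations, degrees=True).as_matrix()

    def inverse(self) -> "RigidTransform":
        R = self.matrix()
        t = np.asarray(self.translations)
        rot = Rotation.from_matrix(R.T).as_euler("xyz", degrees=True)
        return RigidTransform(tuple(rot), tuple(-R.T @ t))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        R1, t1 = self.matrix(), np.asarray(self.translations)
        R2, t2 = other.matrix(), np.asarray(other.translations)
        rot = Rotation.from_matrix(R1 @ R2).as_euler("xyz", degrees=True)
        return RigidTransform(tuple(rot), tuple(R1 @ t2 + t1))

    def is_identity(self, atol: float = 1e-12) -> bool:
        return all(abs(r) <= atol for r in self.rotations) and all(
            abs(t) <= atol for t in self.translations
        )

    def params(self) -> np.ndarray:
        return np.array(self.translations + self.rotations)


def _validate_triple(name: str, triple, positive: bool = True):
    t = tuple(triple)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {triple}")
    if positive and any(v <= 0 for v in t):
        raise ValueError(f"{name} components must be > 0, got {triple}")
    return t


def resample_trilinear(
    img: Image3D,
    target_spacing: tuple[float, float, float],
    target_dims: tuple[int, int, int],
) -> Image3D:
    """Resample onto a new grid by trilinear interpolation.

    The target grid is centered on the source grid's physical center;
    sample points outside the source field of view take the value 0.
    """
    ts = _validate_triple("target_spacing", (float(s) for s in target_spacing))
    td = _validate_triple("target_dims", (int(d) for d in target_dims))
    # source fractional index of each target voxel center, per axis
    idx_1d = []
    for ax in range(3):
        x = (np.arange(td[ax]) - (td[ax] - 1) / 2.0) * ts[ax]  # mm, centered
        idx_1d.append(x / img.spacing[ax] + (img.dims[ax] - 1) / 2.0)
    ii, jj, kk = np.meshgrid(*idx_1d, indexing="ij")
    out = ndimage.map_coordinates(
        img.values, [ii, jj, kk], order=1, mode="constant", cval=0.0
    )
    return Image3D(out, ts)


def pad_to_dims(img: Image3D, target_dims: tuple[int, int, int]) -> Image3D:
    """Zero-pad to ``target_dims``, keeping the original block centered.

    When the pad count on an axis is odd the extra voxel goes on the
    high-index side.
    """
    td = tuple(int(d) for d in target_dims)
    pads = []
    for ax in range(3):
        extra = td[ax] - img.dims[ax]
        if extra < 0:
            raise ValueError(
                f"target_dims {td} smaller than image dims {img.dims} on axis {ax}"
            )
        pads.append((extra // 2, extra - extra // 2))
    return Image3D(np.pad(img.values, pads, mode="constant"), img.spacing)


def _sigma_vox(fwhm_mm: float, spacing: tuple[float, float, float]) -> list[float]:
    """Per-axis sigma in voxel units; a kernel narrower than the voxel
    pitch cannot be represented on the grid and collapses to a delta
    (no smoothing on that axis)."""
    sigmas = []
    for s in spacing:
        if fwhm_mm < s:
            sigmas.append(0.0)
        else:
            sigmas.append((fwhm_mm / FWHM_PER_SIGMA) / s)
    return sigmas


def gaussian_blur(img: Image3D, fwhm_mm: float) -> Image3D:
    """Isotropic Gaussian blur parameterized by FWHM in mm.

    Separable sampled kernel, truncated at 4 sigma, zero-extension at
    the boundary.  ``fwhm_mm = 0`` returns the input unchanged; on any
    axis where the requested FWHM is below the voxel pitch the sampled
    kernel collapses to a delta, so images on coarse grids are left
    unchanged by sub-voxel kernels.
    """
    fwhm_mm = float(fwhm_mm)
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    sigmas = _sigma_vox(fwhm_mm, img.spacing)
    if all(s == 0 for s in sigmas):
        return img.with_values(img.values.copy())
    out = ndimage.gaussian_filter(
        img.values, sigma=sigmas, mode="constant", cval=0.0, truncate=4.0
    )
    return img.with_values(out)


def apply_rigid(img: Image3D, t: RigidTransform) -> Image3D:
    """Resample an image under a rigid transform (pull-back, trilinear).

    The output grid equals the input grid; for each output voxel at
    physical position p the value is the input interpolated at
    ``R^-1 (p - t)``; out-of-FOV samples are 0.
    """
    if t.is_identity():
        return img.with_values(img.values.copy())
    R = t.matrix()
    trans = np.asarray(t.translations)
    coords = np.meshgrid(*(img.axis_coords(ax) for ax in range(3)), indexing="ij")
    p = np.stack([c.ravel() for c in coords])  # 3 x N, mm
    q = R.T @ (p - trans[:, None])  # source physical coords
    idx = [
        q[ax] / img.spacing[ax] + (img.dims[ax] - 1) / 2.0 for ax in range(3)
    ]
    out = ndimage.map_coordinates(
        img.values, idx, order=1, mode="constant", cval=0.0
    ).reshape(img.dims)
    return img.with_values(out)


def sse(a: Image3D, b: Image3D) -> float:
    """Sum of squared voxel-wise differences over the whole volume."""
    if not a.same_grid(b):
        raise ValueError(
            f"images must share dims and spacing: {a.dims}/{a.spacing} vs "
            f"{b.dims}/{b.spacing}"
        )
    d = a.values - b.values
    return float(np.dot(d.ravel(), d.ravel()))


@dataclass
class RegistrationConfig:
    """Settings for the derivative-free rigid registration."""

    xtol: float = 1e-4
    ftol: float = 1e-8
    maxiter: int = 2000

    def as_dict(self) -> dict:
        return {"xtol": self.xtol, "ftol": self.ftol, "maxiter": self.maxiter}


def register_rigid(
    moving: Image3D,
    fixed: Image3D,
    config: RegistrationConfig | None = None,
) -> RigidTransform:
    """Rigidly register ``moving`` to ``fixed`` by minimizing the SSE cost.

    Both images must already share a grid.  The cost is the sum of
    squared differences between ``fixed`` and the rigidly transformed
    ``moving`` image; a Powell derivative-free local search starts from
    the identity.  The returned transform's cost never exceeds the
    identity cost.  Degenerate (constant) images trigger a warning and
    the identity transform is returned.
    """
    if config is None:
        config = RegistrationConfig()
    if not moving.same_grid(fixed):
        raise ValueError("moving and fixed images must share dims and spacing")
    if np.ptp(moving.values) == 0 or np.ptp(fixed.values) == 0:
        warnings.warn(
            "constant image supplied to register_rigid; returning identity",
            stacklevel=2,
        )
        return RigidTransform.identity()

    # precompute output-voxel physical coordinates once
    coords = np.meshgrid(*(fixed.axis_coords(ax) for ax in range(3)), indexing="ij")
    p = np.stack([c.ravel() for c in coords])
    fixed_flat = fixed.values.ravel()
    inv_spacing = np.array([1.0 / s for s in moving.spacing])
    half = np.array([(n - 1) / 2.0 for n in moving.dims])

    def cost(x: np.ndarray) -> float:
        R = Rotation.from_euler("xyz", x[3:], degrees=True).as_matrix()
        q = R.T @ (p - x[:3, None])
        idx = q * inv_spacing[:, None] + half[:, None]
        vals = ndimage.map_coordinates(
            moving.values, idx, order=1, mode="constant", cval=0.0
        )
        d = vals - fixed_flat
        return float(np.dot(d, d))

    x0 = np.zeros(6)
    cost0 = cost(x0)
    res = optimize.minimize(
        cost,
        x0,
        method="Powell",
        options={
            "xtol": config.xtol,
            "ftol": config.ftol,
            "maxiter": config.maxiter,
        },
    )
    log.info(
        "register_rigid: cost %.6g -> %.6g in %d evals (config %s)",
        cost0,
        res.fun,
        res.nfev,
        config.as_dict(),
    )
    if res.fun > cost0:
        log.warning("registration did not improve on identity; returning identity")
        return RigidTransform.identity()
    x = res.x
    return RigidTransform(tuple(x[3:]), tuple(x[:3]))
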