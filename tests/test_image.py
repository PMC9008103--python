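"""Image primitives: resampling, padding, blurring, rigid transforms, SSE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petharm.image import (
    FWHM_PER_SIGMA,
    Image3D,
    RigidTransform,
    apply_rigid,
    gaussian_blur,
    pad_to_dims,
    register_rigid,
    resample_trilinear,
    sse,
)


def rand_image(shape=(8, 8, 8), spacing=(1, 1, 1), seed=0):
    rng = np.random.default_rng(seed)
    return Image3D(rng.random(shape), spacing)


class TestImage3D:
    def test_rejects_non_positive_spacing(self):
        with pytest.raises(ValueError):
            Image3D(np.zeros((2, 2, 2)), (1.0, 0.0, 1.0))

    def test_rejects_non_finite_values(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            Image3D(vals, (1, 1, 1))

    def test_axis_coords_are_centered(self):
        img = Image3D(np.zeros((4, 5, 2)), (2.0, 1.0, 3.0))
        assert np.allclose(img.axis_coords(0), [-3, -1, 1, 3])
        assert np.allclose(img.axis_coords(1), [-2, -1, 0, 1, 2])


class TestResample:
    def test_constant_image_stays_constant_on_interior_grid(self):
        img = Image3D(np.full((21, 21, 21), 7.5), (1, 1, 1))
        out = resample_trilinear(img, (2.0, 2.0, 2.0), (8, 8, 8))
        assert out.dims == (8, 8, 8)
        assert np.allclose(out.values, 7.5, atol=1e-12)

    def test_identity_grid_returns_input(self):
        img = rand_image((9, 10, 11), (1.2, 1.0, 0.9))
        out = resample_trilinear(img, img.spacing, img.dims)
        assert np.abs(out.values - img.values).max() < 1e-12

    def test_exact_on_affine_intensity_field(self):
        # trilinear interpolation reproduces v = a x + b y + c z + d exactly
        img = Image3D(np.zeros((25, 25, 25)), (1.0, 1.0, 1.0))
        a, b, c, d = 2.0, -1.0, 0.5, 100.0
        xs = [img.axis_coords(ax) for ax in range(3)]
        xx, yy, zz = np.meshgrid(*xs, indexing="ij")
        img = img.with_values(a * xx + b * yy + c * zz + d)
        out = resample_trilinear(img, (1.7, 1.3, 2.1), (9, 9, 7))
        txs = [out.axis_coords(ax) for ax in range(3)]
        txx, tyy, tzz = np.meshgrid(*txs, indexing="ij")
        expect = a * txx + b * tyy + c * tzz + d
        assert np.abs(out.values - expect).max() < 1e-9

    def test_rejects_invalid_target(self):
        img = rand_image()
        with pytest.raises(ValueError):
            resample_trilinear(img, (0.0, 1.0, 1.0), (4, 4, 4))
        with pytest.raises(ValueError):
            resample_trilinear(img, (1.0, 1.0, 1.0), (4, 0, 4))


class TestPad:
    def test_pad_preserves_sum_and_support(self):
        # the HRRT/HR+ case: 128 x 128 x 63 zero-padded to 152 x 152 x 105
        rng = np.random.default_rng(3)
        img = Image3D(rng.random((128, 128, 63)) + 0.5, (2.06, 2.06, 2.4))
        out = pad_to_dims(img, (152, 152, 105))
        assert out.dims == (152, 152, 105)
        assert np.isclose(out.values.sum(), img.values.sum(), rtol=0)
        assert np.count_nonzero(out.values) == np.count_nonzero(img.values)
        assert out.spacing == img.spacing

    def test_pad_to_same_dims_is_identity(self):
        img = rand_image((5, 6, 7))
        out = pad_to_dims(img, (5, 6, 7))
        assert np.array_equal(out.values, img.values)

    def test_single_voxel_centering(self):
        img = Image3D(np.full((1, 1, 1), 7.0), (1, 1, 1))
        out = pad_to_dims(img, (3, 3, 3))
        assert out.values[1, 1, 1] == 7.0
        assert out.values.sum() == 7.0

    def test_odd_pad_extra_voxel_on_high_side(self):
        img = Image3D(np.ones((2, 2, 2)), (1, 1, 1))
        out = pad_to_dims(img, (5, 5, 5))
        # pad 3: one voxel low side, two voxels high side
        assert np.array_equal(np.nonzero(out.values[:, 1, 1])[0], [1, 2])

    def test_rejects_shrinking(self):
        with pytest.raises(ValueError):
            pad_to_dims(rand_image((4, 4, 4)), (3, 4, 4))


class TestGaussianBlur:
    def test_zero_fwhm_is_identity(self, smooth_image):
        out = gaussian_blur(smooth_image, 0.0)
        assert np.array_equal(out.values, smooth_image.values)

    def test_impulse_matches_sampled_separable_kernel(self):
        n, fwhm = 61, 4.5
        vals = np.zeros((n, n, n))
        vals[n // 2, n // 2, n // 2] = 1.0
        out = gaussian_blur(Image3D(vals, (1, 1, 1)), fwhm)
        sigma = fwhm / FWHM_PER_SIGMA
        radius = int(4.0 * sigma + 0.5)
        j = np.arange(-radius, radius + 1)
        k1 = np.exp(-(j**2) / (2 * sigma**2))
        k1 /= k1.sum()
        full = np.zeros(n)
        full[n // 2 - radius : n // 2 + radius + 1] = k1
        expect = full[:, None, None] * full[None, :, None] * full[None, None, :]
        assert np.abs(out.values - expect).max() < 1e-12

    def test_measured_half_maximum_width_matches_fwhm(self):
        # blur an impulse and read the FWHM off the profile
        n, fwhm = 81, 6.0
        vals = np.zeros((n, n, n))
        vals[n // 2, n // 2, n // 2] = 1.0
        out = gaussian_blur(Image3D(vals, (1, 1, 1)), fwhm)
        profile = out.values[:, n // 2, n // 2]
        half = profile.max() / 2
        above = np.nonzero(profile >= half)[0]
        lo, hi = above[0], above[-1]
        # sub-voxel crossings by linear interpolation
        x_left = (lo - 1) + (half - profile[lo - 1]) / (profile[lo] - profile[lo - 1])
        x_right = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        assert abs((x_right - x_left) - fwhm) < 0.05

    def test_semigroup_quadrature(self, smooth_image):
        double = gaussian_blur(gaussian_blur(smooth_image, 3.0), 4.5)
        single = gaussian_blur(smooth_image, np.hypot(3.0, 4.5))
        interior = (slice(10, -10),) * 3
        a, b = double.values[interior], single.values[interior]
        rel = np.abs(a - b) / b.max()
        assert rel.max() < 1e-3

    def test_preserves_total_counts_away_from_edges(self):
        # compact support (ball of radius 15 mm) stays > 4 sigma from edges
        n = 61
        x = np.arange(n) - (n - 1) / 2
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        img = Image3D(np.where(xx**2 + yy**2 + zz**2 <= 15.0**2, 100.0, 0.0), (1, 1, 1))
        out = gaussian_blur(img, 5.0)
        assert np.isclose(out.values.sum(), img.values.sum(), rtol=1e-6)

    def test_sub_voxel_kernel_collapses_to_identity(self):
        img = rand_image((12, 12, 12), spacing=(2.06, 2.06, 2.4))
        out = gaussian_blur(img, 2.0)  # below the voxel pitch on every axis
        assert np.array_equal(out.values, img.values)

    def test_rejects_negative_fwhm(self, smooth_image):
        with pytest.raises(ValueError):
            gaussian_blur(smooth_image, -1.0)


class TestRigidTransform:
    @given(
        st.lists(st.floats(-10, 10), min_size=6, max_size=6),
    )
    def test_compose_with_inverse_is_identity(self, params):
        t = RigidTransform(tuple(params[:3]), tuple(params[3:]))
        round_trip = t.compose(t.inverse())
        assert np.abs(round_trip.params()).max() < 1e-9

    def test_identity_transform_returns_input(self, smooth_image):
        out = apply_rigid(smooth_image, RigidTransform.identity())
        assert np.abs(out.values - smooth_image.values).max() < 1e-12

    def test_translation_by_one_voxel_shifts_indices(self):
        img = rand_image((7, 7, 7), spacing=(1.5, 1.0, 1.0), seed=4)
        out = apply_rigid(img, RigidTransform((0, 0, 0), (1.5, 0, 0)))
        assert np.allclose(out.values[1:], img.values[:-1], atol=1e-12)
        assert np.allclose(out.values[0], 0.0)

    def test_rotation_90deg_matches_index_permutation(self):
        # zero-bordered pattern so edge samples falling just outside the
        # FOV (floating-point eps at exact 90 deg) do not matter
        rng = np.random.default_rng(5)
        v = np.zeros((11, 11, 5))
        v[2:-2, 2:-2, 1:-1] = rng.random((7, 7, 3))
        img = Image3D(v, (1, 1, 1))
        out = apply_rigid(img, RigidTransform((0, 0, 90), (0, 0, 0)))
        n = v.shape[0]
        # out[i, j] = v[j, n-1-i]: rotation (x, y) -> (-y, x)
        expect = np.empty_like(v)
        for i in range(n):
            for j in range(n):
                expect[i, j] = v[j, n - 1 - i]
        assert np.abs(out.values - expect).max() < 1e-9

    def test_transform_then_inverse_recovers_interior(self, smooth_image):
        t = RigidTransform((2.0, -1.0, 3.0), (1.3, -0.7, 2.1))
        round_trip = apply_rigid(apply_rigid(smooth_image, t), t.inverse())
        interior = (slice(8, -8),) * 3
        err = np.abs(round_trip.values[interior] - smooth_image.values[interior])
        assert err.max() < 1e-2 * smooth_image.values.max()


class TestSSE:
    def test_zero_iff_equal(self, smooth_image):
        assert sse(smooth_image, smooth_image) == 0.0
        other = smooth_image.with_values(smooth_image.values + 1e-3)
        assert sse(smooth_image, other) > 0

    def test_unit_difference_gives_voxel_count(self):
        img = rand_image((6, 5, 4))
        other = img.with_values(img.values + 1.0)
        assert np.isclose(sse(img, other), 6 * 5 * 4)

    def test_matches_brute_force_loop(self):
        a, b = rand_image(seed=1), rand_image(seed=2)
        brute = 0.0
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    brute += (a.values[i, j, k] - b.values[i, j, k]) ** 2
        assert np.isclose(sse(a, b), brute, rtol=1e-12)

    def test_symmetric(self):
        a, b = rand_image(seed=1), rand_image(seed=2)
        assert sse(a, b) == sse(b, a)

    def test_rejects_grid_mismatch(self):
        with pytest.raises(ValueError):
            sse(rand_image((4, 4, 4)), rand_image((4, 4, 5)))
        with pytest.raises(ValueError):
            sse(rand_image(spacing=(1, 1, 1)), rand_image(spacing=(1, 1, 2)))


class TestRegisterRigid:
    def test_identical_images_give_identity(self, smooth_image):
        t = register_rigid(smooth_image, smooth_image)
        assert np.abs(t.params()).max() < 1e-3

    def test_constant_image_warns_and_returns_identity(self):
        img = Image3D(np.ones((8, 8, 8)), (1, 1, 1))
        with pytest.warns(UserWarning, match="constant image"):
            t = register_rigid(img, img)
        assert t.is_identity()
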