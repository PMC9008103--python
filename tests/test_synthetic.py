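"""Phantom construction, dynamic subjects, and the scanner forward model."""

import numpy as np
import pytest

from petharm.endpoints import compute_bp, extract_roi_tac, percent_difference
from petharm.image import RigidTransform
from petharm.kinetics import SRTMParams
from petharm.synthetic import (
    CALIBRATED_NOISE_SCALE,
    Ellipsoid,
    F18_HALF_LIFE_MIN,
    PhantomSpec,
    ScannerModel,
    SubjectSpec,
    activity_concentration_bq_ml,
    decay_factor,
    hr_plus_like,
    hrrt_like,
    make_dynamic_subject,
    make_test_retest_pair,
    make_uniform_phantom,
    simulate_scan,
)


@pytest.fixture(scope="module")
def subject():
    spec = SubjectSpec()
    truth, masks = make_dynamic_subject(spec)
    return spec, truth, masks


class TestUniformPhantom:
    def test_cavity_voxels_carry_fill_concentration(self, phantom):
        img, mask = phantom
        assert np.all(img.values[mask] == 70220.0)
        assert np.all(img.values[~mask] == 0.0)

    def test_fill_linearity(self):
        spec = PhantomSpec(dims=(32, 32, 32),
                           cavities=(Ellipsoid((0, 0, 0), (12, 10, 9)),))
        img1, _ = make_uniform_phantom(spec)
        img2, _ = make_uniform_phantom(
            PhantomSpec(dims=(32, 32, 32), fill_bq_ml=2 * spec.fill_bq_ml,
                        cavities=spec.cavities)
        )
        assert np.allclose(img2.values, 2 * img1.values)

    def test_empty_cavity_rejected(self):
        spec = PhantomSpec(
            dims=(16, 16, 16),
            cavities=(Ellipsoid((200.0, 0, 0), (2, 2, 2)),),  # outside the FOV
        )
        with pytest.raises(ValueError, match="empty"):
            make_uniform_phantom(spec)

    def test_activity_concentration_unit_conversion(self):
        # 2.9 mCi mixed into 800 mL -> about 134.1 kBq/mL
        conc = activity_concentration_bq_ml(2.9, 800.0)
        assert conc == pytest.approx(134125.0, rel=1e-6)

    def test_f18_decay_bookkeeping(self):
        assert decay_factor(F18_HALF_LIFE_MIN) == pytest.approx(0.5)
        assert decay_factor(0.0) == 1.0
        # concentration after 67 min at 134.1 kBq/mL start
        c = 134125.0 * decay_factor(67.0)
        assert c == pytest.approx(134125.0 * 2 ** (-67.0 / 109.77))


class TestDynamicSubject:
    def test_cerebellum_tac_is_exactly_the_reference(self, subject, schedule):
        spec, truth, masks = subject
        ref = spec.reference.frame_averages(schedule)
        # every cerebellum voxel carries the reference curve bit-exactly
        assert np.array_equal(
            truth.values[masks["cerebellum"]],
            np.broadcast_to(ref, (masks["cerebellum"].sum(), len(ref))),
        )
        tac = extract_roi_tac(truth, masks["cerebellum"])
        assert np.allclose(tac.values, ref, rtol=1e-12)

    def test_striatum_fit_recovers_generative_bp(self, subject):
        _, truth, masks = subject
        bp = compute_bp(truth, masks["striatum"], masks["cerebellum"])
        assert bp == pytest.approx(3.0, rel=0.01)

    def test_overlapping_regions_rejected(self):
        spec = SubjectSpec(
            striatum=(Ellipsoid((0.0, -28.0, -16.0), (9.0, 9.0, 9.0)),),  # on cerebellum
        )
        with pytest.raises(ValueError, match="overlap"):
            make_dynamic_subject(spec)

    def test_regions_partition_brain(self, subject):
        _, _, masks = subject
        assert not (masks["striatum"] & masks["cerebellum"]).any()
        assert not (masks["striatum"] & masks["background"]).any()


class TestSimulateScan:
    def test_noiseless_identity_scanner_reproduces_truth(self, subject):
        spec, truth, _ = subject
        scanner = ScannerModel("ideal", 0.0, spec.spacing, spec.dims)
        out = simulate_scan(truth, scanner)
        assert np.abs(out.values - truth.values).max() < 1e-9

    def test_determinism_and_seed_sensitivity(self, subject):
        spec, truth, _ = subject
        scanner = hr_plus_like(spec.fov_mm, noise_scale=50.0)
        a = simulate_scan(truth, scanner, seed=7)
        b = simulate_scan(truth, scanner, seed=7)
        c = simulate_scan(truth, scanner, seed=8)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_noise_requires_seed(self, subject):
        spec, truth, _ = subject
        scanner = hr_plus_like(spec.fov_mm, noise_scale=50.0)
        with pytest.raises(ValueError, match="seed"):
            simulate_scan(truth, scanner)

    def test_shorter_frames_are_noisier(self, subject):
        spec, truth, _ = subject
        scanner = hr_plus_like(spec.fov_mm, noise_scale=CALIBRATED_NOISE_SCALE)
        clean = simulate_scan(truth, hr_plus_like(spec.fov_mm))
        noisy = simulate_scan(truth, scanner, seed=3)
        resid = noisy.values - clean.values
        # compare a 0.5-min frame against a 5-min frame at similar activity
        sd_short = resid[..., 5].std()
        sd_long = resid[..., 26].std()
        assert sd_short > sd_long

    def test_partial_volume_bp_decreases_with_psf(self, subject):
        spec, truth, masks = subject
        bps = []
        for psf in [0.0, 2.0, 4.0, 6.0, 8.0]:
            scanner = ScannerModel("sweep", psf, spec.spacing, spec.dims)
            scan = simulate_scan(truth, scanner)
            bps.append(compute_bp(scan, masks["striatum"], masks["cerebellum"]))
        assert all(a > b for a, b in zip(bps, bps[1:]))


class TestTestRetest:
    def test_noiseless_zero_offset_pair_is_identical(self, subject):
        spec, truth, masks = subject
        scanner = hr_plus_like(spec.fov_mm)
        a, b = make_test_retest_pair(
            truth, scanner, (1, 2), max_offset_mm=0.0, max_offset_deg=0.0
        )
        assert np.array_equal(a.values, b.values)
        from petharm.synthetic import resample_mask

        m = {
            k: resample_mask(v, spec.spacing, scanner.voxel_spacing, scanner.dims)
            for k, v in masks.items()
            if k in ("striatum", "cerebellum")
        }
        bp_a = compute_bp(a, m["striatum"], m["cerebellum"])
        bp_b = compute_bp(b, m["striatum"], m["cerebellum"])
        assert percent_difference(bp_a, bp_b) == 0.0

    def test_fixed_seeds_reproduce(self, subject):
        spec, truth, _ = subject
        scanner = hr_plus_like(spec.fov_mm, noise_scale=CALIBRATED_NOISE_SCALE)
        a1, b1 = make_test_retest_pair(truth, scanner, (11, 12))
        a2, b2 = make_test_retest_pair(truth, scanner, (11, 12))
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(b1.values, b2.values)

    def test_equal_seeds_warn(self, subject):
        spec, truth, _ = subject
        scanner = hr_plus_like(spec.fov_mm)
        with pytest.warns(UserWarning, match="seeds"):
            make_test_retest_pair(truth, scanner, (5, 5),
                                  max_offset_mm=0.0, max_offset_deg=0.0)


class TestScannerModels:
    def test_default_scanner_parameters(self):
        hi = hrrt_like()
        lo = hr_plus_like()
        assert hi.psf_fwhm == 3.0 and hi.voxel_spacing == (1.2, 1.2, 1.2)
        assert lo.psf_fwhm == 5.41 and lo.voxel_spacing == (2.06, 2.06, 2.4)
        # PSFs sit inside the published resolution ranges of the two tomographs
        assert 2.3 <= hi.psf_fwhm <= 3.4
        assert 4.1 <= lo.psf_fwhm <= 7.8

    def test_rejects_negative_psf(self):
        with pytest.raises(ValueError):
            ScannerModel("bad", -1.0, (1, 1, 1), (8, 8, 8))
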