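"""Segmentation methods: reference statistic, thresholds, IADT calibration.

The IADT tests run on analytically blurred sphere images (no
reconstruction involved), so the threshold machinery is checked against
controlled partial-volume and background conditions.
"""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from luquant import segmentation as seg


def blurred_sphere_image(n=48, voxel=4.8, radius_mm=28.0, amplitude=1.0,
                         background=0.0, sigma_mm=9.0):
    """Sphere of given amplitude over uniform background, Gaussian-blurred."""
    c = (n - 1) / 2.0
    x = (np.arange(n) - c) * voxel
    r = np.sqrt(x[:, None, None]**2 + x[None, :, None]**2 + x[None, None, :]**2)
    vol = np.where(r <= radius_mm, amplitude, 0.0)
    img = gaussian_filter(vol, sigma_mm / voxel) + background
    return img, (r <= radius_mm)


class TestReferenceValue:
    def test_uniform_image(self):
        img = np.full((4, 4, 4), 3.5)
        assert seg.reference_value(img, np.ones_like(img, bool)) == 3.5

    def test_mean_of_nine_hottest(self):
        img = np.arange(1.0, 21.0).reshape(4, 5, 1)
        assert seg.reference_value(img, np.ones_like(img, bool)) \
            == pytest.approx(np.mean(np.arange(12.0, 21.0)))

    def test_stable_under_low_value_additions(self):
        img = np.arange(1.0, 21.0).reshape(4, 5, 1)
        voi = np.ones_like(img, bool)
        before = seg.reference_value(img, voi)
        img2 = np.concatenate([img, np.full((4, 5, 1), 5.0)], axis=2)
        voi2 = np.ones_like(img2, bool)
        assert seg.reference_value(img2, voi2) == before

    def test_too_small_voi_raises(self):
        img = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="at least 9"):
            seg.reference_value(img, np.ones_like(img, bool))


class TestFixedThreshold:
    def test_tiny_fraction_selects_entire_voi(self):
        img, _ = blurred_sphere_image(background=0.01)
        voi = np.ones_like(img, bool)
        res = seg.fixed_threshold_segment(img, voi, 1e-4, 0.11)
        assert res.mask.sum() == voi.sum()

    def test_matches_brute_force_scan(self):
        img, _ = blurred_sphere_image()
        voi = img > 0.001
        res = seg.fixed_threshold_segment(img, voi, 0.40, 0.11)
        ref = seg.reference_value(img, voi)
        expected = np.zeros_like(voi)
        for idx in np.ndindex(img.shape):
            expected[idx] = voi[idx] and img[idx] >= 0.40 * ref
        assert np.array_equal(res.mask, expected)
        assert res.activity_MBq == pytest.approx(img[expected].sum())

    def test_invalid_fraction_rejected(self):
        img, _ = blurred_sphere_image()
        with pytest.raises(ValueError):
            seg.fixed_threshold_segment(img, img > 0, 1.5, 0.11)

    def test_empty_mask_flagged(self):
        img = np.zeros((4, 4, 4))
        img[0, 0, :9] = 1.0  # 9 hot voxels, rest zero
        voi = np.ones_like(img, bool)
        res = seg.fixed_threshold_segment(np.where(img > 0, -0.0, 0.0) + img,
                                          voi, 0.5, 0.1)
        assert not res.empty  # hot voxels survive their own threshold
        res2 = seg.fixed_threshold_segment(np.zeros((4, 4, 4)) - 0.0, voi, 0.5, 0.1)
        # all-zero image: threshold 0 keeps everything, never empty
        assert res2.mask.sum() == voi.sum()


class TestCtBased:
    def test_unblurred_image_recovers_exactly(self):
        img, mask = blurred_sphere_image(sigma_mm=1e-6)
        res = seg.ct_based_segment(img, mask, 0.11)
        assert res.activity_MBq == pytest.approx(img[mask].sum())

    def test_blur_causes_spill_out_underestimation(self):
        sharp, mask = blurred_sphere_image(sigma_mm=1e-6)
        blurred, _ = blurred_sphere_image(sigma_mm=12.0)
        assert blurred[mask].sum() < sharp[mask].sum()

    def test_empty_mask_raises(self):
        img, _ = blurred_sphere_image()
        with pytest.raises(ValueError, match="empty"):
            seg.ct_based_segment(img, np.zeros_like(img, bool), 0.11)


class TestCalibrationCurves:
    def make_curves(self):
        return seg.CalibrationCurves(sbr=[4.1, 5.3, 8.0, 14.0],
                                     volume_fraction=[0.55, 0.50, 0.45, 0.40],
                                     activity_fraction=[0.40, 0.35, 0.30, 0.25])

    def test_query_at_knot_returns_stored_fraction(self):
        curves = self.make_curves()
        fa, fv = curves.query(8.0)
        assert (fa, fv) == (0.30, 0.45)

    def test_extrapolation_continues_the_end_segments(self):
        curves = self.make_curves()
        # beyond the highest knot the fractions keep falling toward the
        # 1/SBR -> 0 intercept instead of clamping at the knot value
        fa_hi, fv_hi = curves.query(1e9)
        fa_14, fv_14 = curves.query(14.0)
        assert fa_hi < fa_14 and fv_hi < fv_14
        assert fa_hi >= 0.02 and fv_hi >= 0.02
        # below the lowest knot the fractions keep rising, bounded by 0.95
        fa_lo, fv_lo = curves.query(2.0)
        assert 0.95 >= fa_lo > curves.query(4.1)[0]
        assert 0.95 >= fv_lo > curves.query(4.1)[1]

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            seg.CalibrationCurves([4.0, 8.0], [0.5, 1.2], [0.3, 0.4])

    def test_json_round_trip(self, tmp_path):
        curves = self.make_curves()
        path = str(tmp_path / "curves.json")
        seg.save_curves(curves, path)
        back = seg.load_curves(path)
        assert np.array_equal(back.sbr, curves.sbr)
        assert np.array_equal(back.activity_fraction, curves.activity_fraction)


def calibration_set(sbrs=(14.0, 8.0, 5.3, 4.1)):
    """Analytic calibration scans: blurred spheres over known backgrounds."""
    scans = []
    vox = 4.8
    for sbr in sbrs:
        amp, bg = 1.0, 1.0 / sbr
        img, mask = blurred_sphere_image(amplitude=amp, background=bg)
        true_vol = mask.sum() * vox**3 / 1000.0
        true_act = amp * mask.sum()  # activity carried by insert voxels only
        voi = np.ones_like(img, bool)
        scans.append(seg.CalibrationScanInsert(
            image=img, voi=voi, true_volume_ml=true_vol,
            true_activity_MBq=true_act, sbr=sbr,
            voxel_volume_ml=vox**3 / 1000.0, label="cal"))
    return scans


class TestIadt:
    def test_curve_fractions_rise_as_sbr_falls(self):
        """Lower signal-to-background pushes both optimal thresholds up:
        the mask must shrink to offset background spill-in."""
        curves = seg.build_iadt_curves(calibration_set())
        assert np.all(np.diff(curves.activity_fraction) <= 0)  # vs ascending SBR
        assert np.all(np.diff(curves.volume_fraction) <= 0)

    def test_self_consistency_on_calibration_scan(self):
        scans = calibration_set()
        curves = seg.build_iadt_curves(scans)
        scan = scans[1]  # SBR 8
        res = seg.iadt_segment(scan.image, scan.voi, curves, scan.voxel_volume_ml)
        assert res.activity_MBq == pytest.approx(scan.true_activity_MBq, rel=0.02)
        assert res.volume_ml == pytest.approx(scan.true_volume_ml, rel=0.05)

    def test_zero_background_uses_infinite_sbr_limit(self):
        """With no background the SBR estimate diverges and the result must
        equal fixed dual-threshold segmentation at the curves' high-SBR
        limiting fractions."""
        curves = seg.build_iadt_curves(calibration_set())
        # sharp sphere: the background really is identically zero
        img, _ = blurred_sphere_image(background=0.0, sigma_mm=1e-6)
        voi = np.ones_like(img, bool)
        res = seg.iadt_segment(img, voi, curves, 0.11)
        assert res.sbr_estimate is None  # infinite SBR
        fa, fv = curves.query(np.inf)
        ref = seg.reference_value(img, voi)
        assert res.activity_MBq == pytest.approx(img[voi & (img >= fa * ref)].sum())
        assert res.volume_ml == pytest.approx((voi & (img >= fv * ref)).sum() * 0.11)

    def test_deterministic(self):
        curves = seg.build_iadt_curves(calibration_set())
        img, _ = blurred_sphere_image(background=0.15)
        voi = np.ones_like(img, bool)
        a = seg.iadt_segment(img, voi, curves, 0.11)
        b = seg.iadt_segment(img, voi, curves, 0.11)
        assert np.array_equal(a.mask, b.mask)
        assert a.activity_MBq == b.activity_MBq

    def test_insufficient_sbr_levels_rejected(self):
        with pytest.raises(ValueError, match="2 distinct SBR"):
            seg.build_iadt_curves(calibration_set(sbrs=(8.0,)))

    def test_unreachable_truth_excluded_with_warning(self):
        scans = calibration_set()
        # an insert whose claimed activity exceeds anything in the image
        img, mask = blurred_sphere_image(background=0.1)
        bad = seg.CalibrationScanInsert(image=img, voi=np.ones_like(img, bool),
                                        true_volume_ml=1.0,
                                        true_activity_MBq=1e9, sbr=10.0,
                                        voxel_volume_ml=0.11, label="bogus")
        with pytest.warns(UserWarning, match="bogus"):
            curves = seg.build_iadt_curves(scans + [bad])
        assert 10.0 not in curves.nominal_sbr
        assert len(curves.sbr) == 4
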