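"""ROI statistics, thresholding, bed classification and display transfer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from residuoscope import (
    AcquisitionSpec,
    RegionMask,
    calibrate_threshold,
    classify_bed,
    display_transfer,
    make_tumor_bed_pair,
    mean_region_rate,
    normalize_by_exposure,
    segment_tumor,
    tumor_to_muscle_ratio,
)
from residuoscope.acquisition import EmissionRateImage
from residuoscope.quantify import ThresholdModel, full_frame_mask


def _img(arr, **prov):
    return EmissionRateImage(rates=np.asarray(arr, dtype=float), provenance=prov)


def _phantom(spec, clusters=(), noise=True, seed=0, cv=0.0, tumor=12000.0, muscle=1000.0):
    t, m, b, scene = make_tumor_bed_pair(
        spec, tumor, muscle, clusters, heterogeneity_cv=cv, noise=noise, seed=seed
    )
    return (
        normalize_by_exposure(t),
        normalize_by_exposure(m),
        normalize_by_exposure(b),
        scene,
    )


class TestMeanRegionRate:
    def test_uniform(self):
        img = _img(np.full((10, 10), 100.0))
        assert mean_region_rate(img, full_frame_mask(img)) == 100.0

    def test_half_and_half(self):
        arr = np.zeros((10, 10))
        arr[:, 5:] = 200.0
        img = _img(arr)
        assert mean_region_rate(img, full_frame_mask(img)) == pytest.approx(100.0)

    def test_large_roi_tracks_generator_truth(self, small_spec):
        _, muscle, _, _ = _phantom(small_spec, noise=True, seed=3)
        roi = full_frame_mask(muscle)
        assert roi.n_pixels >= 10_000
        assert mean_region_rate(muscle, roi) == pytest.approx(1000.0, rel=0.01)

    def test_shape_mismatch_rejected(self):
        img = _img(np.ones((5, 5)))
        roi = RegionMask(mask=np.ones((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            mean_region_rate(img, roi)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="positive pixel"):
            RegionMask(mask=np.zeros((5, 5), dtype=bool))


class TestTumorToMuscleRatio:
    def test_constructed_ratio_twelve(self, noiseless_spec):
        tumor, muscle, _, _ = _phantom(noiseless_spec, noise=False)
        ratio = tumor_to_muscle_ratio(tumor, full_frame_mask(tumor), muscle, full_frame_mask(muscle))
        assert ratio == pytest.approx(12.0, abs=1e-9)

    def test_identical_images_ratio_one(self):
        img = _img(np.random.default_rng(0).uniform(10, 20, (12, 12)))
        roi = full_frame_mask(img)
        assert tumor_to_muscle_ratio(img, roi, img, roi) == pytest.approx(1.0)

    def test_noisy_recovery_of_printed_vm249_ratio(self, small_spec):
        # the sharpest probe's contrast: tumor/muscle = 22.7
        tumor, muscle, _, _ = _phantom(small_spec, noise=True, seed=5, tumor=22700.0, muscle=1000.0)
        ratio = tumor_to_muscle_ratio(tumor, full_frame_mask(tumor), muscle, full_frame_mask(muscle))
        assert ratio == pytest.approx(22.7, rel=0.01)

    def test_zero_muscle_rejected(self):
        tumor = _img(np.full((5, 5), 10.0))
        muscle = _img(np.zeros((5, 5)))
        roi = full_frame_mask(tumor)
        with pytest.raises(ValueError, match="zero"):
            tumor_to_muscle_ratio(tumor, roi, muscle, roi)

    def test_gain_invariance(self, noiseless_spec):
        tumor, muscle, _, _ = _phantom(noiseless_spec, noise=False)
        r1 = tumor_to_muscle_ratio(tumor, full_frame_mask(tumor), muscle, full_frame_mask(muscle))
        g_t = _img(tumor.rates * 3.7)
        g_m = _img(muscle.rates * 3.7)
        r2 = tumor_to_muscle_ratio(g_t, full_frame_mask(g_t), g_m, full_frame_mask(g_m))
        assert r2 == pytest.approx(r1, rel=1e-12)


class TestSegmentTumor:
    def test_noiseless_disc_segmented_exactly(self, noiseless_spec):
        pitch = noiseless_spec.pixel_pitch_um
        cluster = (60 * pitch, 80 * pitch, 200.0, 12000.0)
        _, _, bed, scene = _phantom(noiseless_spec, [cluster], noise=False)
        mask = segment_tumor(bed)
        np.testing.assert_array_equal(mask.mask, scene.truth_mask)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment_tumor(_img(np.full((10, 10), 5.0)))

    def test_noisy_jaccard_high(self, small_spec):
        pitch = small_spec.pixel_pitch_um
        cluster = (60 * pitch, 80 * pitch, 300.0, 12000.0)
        _, _, bed, scene = _phantom(small_spec, [cluster], noise=True, seed=7)
        mask = segment_tumor(bed)
        inter = np.sum(mask.mask & scene.truth_mask)
        union = np.sum(mask.mask | scene.truth_mask)
        assert inter / union >= 0.95


class TestCalibrateThreshold:
    def test_eighty_percent_rule(self):
        img = _img(np.full((10, 10), 1000.0))
        model = calibrate_threshold(img, full_frame_mask(img), fraction=0.8)
        assert model.threshold_rate == pytest.approx(800.0)
        assert model.tumor_min_rate == pytest.approx(1000.0)

    def test_fraction_one(self):
        img = _img(np.full((10, 10), 1234.0))
        model = calibrate_threshold(img, full_frame_mask(img), fraction=1.0)
        assert model.threshold_rate == pytest.approx(model.tumor_min_rate)

    def test_fraction_out_of_range_rejected(self):
        img = _img(np.ones((5, 5)))
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                calibrate_threshold(img, full_frame_mask(img), fraction=bad)

    def test_percentile_statistic_close_to_noiseless_min(self, small_spec, noiseless_spec):
        noiseless, *_ = _phantom(noiseless_spec, noise=False)
        ref = calibrate_threshold(noiseless, full_frame_mask(noiseless), median_filter_size=0)
        spec = AcquisitionSpec(
            pixel_pitch_um=6.5, frame_shape=small_spec.frame_shape,
            exposure_time_ms=250.0, read_noise_sd=2.0, dark_offset=100.0,
        )
        noisy, *_ = _phantom(spec, noise=True, seed=11)
        model = calibrate_threshold(
            noisy, full_frame_mask(noisy), min_statistic="percentile", percentile=1.0
        )
        assert model.threshold_rate == pytest.approx(ref.threshold_rate, rel=0.05)

    def test_threshold_model_consistency_enforced(self):
        with pytest.raises(ValueError):
            ThresholdModel(threshold_rate=1.0, fraction=0.8, tumor_min_rate=2.0,
                           min_statistic="literal-min")


class TestClassifyBed:
    def _model(self, threshold, shape=(20, 20)):
        return ThresholdModel(
            threshold_rate=threshold, fraction=0.8, tumor_min_rate=threshold / 0.8,
            min_statistic="literal-min", frame_shape=shape,
        )

    def test_bright_bed_positive(self):
        arr = np.full((20, 20), 100.0)
        arr[5:9, 5:9] = 900.0
        cls = classify_bed(_img(arr), self._model(800.0), pixel_pitch_um=6.5)
        assert cls.status == "positive"
        assert cls.supra_area_um2 == pytest.approx(16 * 6.5**2)

    def test_dim_bed_negative(self):
        cls = classify_bed(_img(np.full((20, 20), 100.0)), self._model(800.0))
        assert cls.status == "negative"
        assert cls.largest_component_px == 0

    def test_single_16um_cluster_detected_and_overlaps_truth(self, noiseless_spec):
        pitch = noiseless_spec.pixel_pitch_um
        cluster = (60 * pitch, 80 * pitch, 16.0, 12000.0)
        tumor, _, bed, scene = _phantom(noiseless_spec, [cluster], noise=False)
        model = calibrate_threshold(tumor, full_frame_mask(tumor))
        cls = classify_bed(bed, model)
        assert cls.status == "positive"
        assert np.sum(cls.supra_threshold_mask & scene.truth_mask) >= 4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            classify_bed(_img(np.ones((10, 10))), self._model(0.5, shape=(20, 20)))

    def test_exposure_invariance_of_classification(self, noiseless_spec):
        pitch = noiseless_spec.pixel_pitch_um
        cluster = (60 * pitch, 80 * pitch, 26.0, 12000.0)
        results = []
        for t_ms in (10.0, 250.0):
            spec = AcquisitionSpec(
                pixel_pitch_um=pitch, frame_shape=noiseless_spec.frame_shape,
                exposure_time_ms=t_ms, read_noise_sd=0.0, dark_offset=0.0,
            )
            tumor, _, bed, _ = _phantom(spec, [cluster], noise=False)
            model = calibrate_threshold(tumor, full_frame_mask(tumor))
            results.append(classify_bed(bed, model).status)
        assert results[0] == results[1] == "positive"

    def test_monotone_in_fraction(self, noiseless_spec):
        pitch = noiseless_spec.pixel_pitch_um
        cluster = (60 * pitch, 80 * pitch, 40.0, 10500.0)
        tumor, _, bed, _ = _phantom(noiseless_spec, [cluster], noise=False)
        roi = full_frame_mask(tumor)
        last_positive = None
        for fraction in (0.2, 0.4, 0.6, 0.8, 1.0):
            model = calibrate_threshold(tumor, roi, fraction=fraction)
            positive = classify_bed(bed, model).is_positive
            if last_positive is not None and last_positive is False:
                # raising fraction never converts negative back to positive
                assert positive is False
            last_positive = positive


class TestDisplayTransfer:
    def test_linear_map_endpoints_and_midpoint(self):
        tumor = _img(np.array([[800.0, 1800.0], [1300.0, 1000.0]]))
        out = display_transfer(tumor)[0]
        assert out[0, 0] == 0
        assert out[0, 1] == 255
        assert out[1, 0] == 128  # 127.5 rounds half-to-even

    def test_below_range_clipped_to_zero(self):
        tumor = _img(np.array([[800.0, 1800.0]]))
        bed = _img(np.array([[100.0, 900.0]]))
        out = display_transfer(tumor, [bed])[0]
        assert out[0, 0] == 0

    def test_not_idempotent(self):
        # pushing already-mapped 8-bit data through the same tumor-anchored
        # map again collapses it toward zero
        tumor = _img(np.array([[800.0, 1800.0], [1300.0, 1000.0]]))
        once = display_transfer(tumor)[0]
        twice = display_transfer(tumor, [_img(once.astype(float))])[0]
        assert not np.array_equal(once, twice)

    def test_constant_tumor_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            display_transfer(_img(np.full((4, 4), 5.0)))

    def test_same_map_for_all_images(self):
        tumor = _img(np.array([[0.0, 255.0]]))
        a = _img(np.array([[10.0, 20.0]]))
        out_t, out_a = display_transfer(tumor, [tumor, a])
        assert out_t[0, 1] == 255
        np.testing.assert_array_equal(out_a, np.array([[10, 20]], dtype=np.uint8))


@given(fraction=st.floats(min_value=0.05, max_value=1.0))
@settings(max_examples=25, deadline=None)
def test_threshold_scales_linearly_with_fraction(fraction):
    img = EmissionRateImage(rates=np.full((6, 6), 1000.0))
    model = calibrate_threshold(img, full_frame_mask(img), fraction=fraction)
    assert model.threshold_rate == pytest.approx(fraction * 1000.0)
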