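"""Generator contracts: bar targets, microsphere series, phantoms, cohorts."""

import numpy as np
import pytest

from residuoscope import (
    AcquisitionSpec,
    CohortSpec,
    make_bar_target,
    make_microsphere_series,
    make_tumor_bed_pair,
    normalize_by_exposure,
    simulate_cohort,
)
from residuoscope.calibration import sphere_rate_photometry, detect_spheres
from residuoscope.resolution import ctf_modulus, measure_bar_contrast
from residuoscope.synthetic import ARM_NEGATIVE, ARM_POSITIVE, bar_target_shape, rasterize_disc

from oracles import bar_contrast_oracle, disc_pixel_count_oracle

FREQS = [10.0, 15.0, 20.0, 25.0, 30.0, 40.0]


def _bar_spec(freqs=FREQS, pitch=6.5):
    return AcquisitionSpec(
        pixel_pitch_um=pitch,
        frame_shape=bar_target_shape(freqs, pitch),
        read_noise_sd=0.0,
        dark_offset=0.0,
    )


class TestBarTarget:
    def test_unblurred_full_contrast_gives_ctf_one(self):
        spec = _bar_spec()
        img, groups = make_bar_target(spec, FREQS, blur_sigma_um=0.0, contrast=1.0, noise=False)
        rates = normalize_by_exposure(img, background="none")
        for g in groups:
            assert ctf_modulus(measure_bar_contrast(rates, g)) == pytest.approx(1.0)

    @pytest.mark.parametrize("blur_sigma_um", [5.0, 10.0, 20.0])
    def test_blurred_ctf_matches_convolution_oracle(self, blur_sigma_um):
        spec = _bar_spec()
        img, groups = make_bar_target(
            spec, FREQS, blur_sigma_um=blur_sigma_um, contrast=1.0, noise=False
        )
        rates = normalize_by_exposure(img, background="none")
        for g in groups:
            measured = ctf_modulus(measure_bar_contrast(rates, g))
            expected = bar_contrast_oracle(
                g.frequency_cpmm, spec.pixel_pitch_um, blur_sigma_um, 1.0,
                start_px=g.start_px,
            )
            assert measured == pytest.approx(expected, rel=0.02, abs=0.005)

    def test_same_seed_bit_identical(self):
        spec = _bar_spec()
        a, _ = make_bar_target(spec, FREQS, blur_sigma_um=8.0, noise=True, seed=42)
        b, _ = make_bar_target(spec, FREQS, blur_sigma_um=8.0, noise=True, seed=42)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_beyond_nyquist_rejected_with_limit_named(self):
        spec = _bar_spec()
        nyquist = 1000.0 / (2 * spec.pixel_pitch_um)
        with pytest.raises(ValueError, match=f"{nyquist:g}"):
            make_bar_target(spec, [nyquist * 1.1])

    def test_contrast_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_bar_target(_bar_spec(), FREQS, contrast=0.0)


class TestMicrosphereSeries:
    def test_counts_double_with_exposure_noise_off(self, small_spec):
        frames, truth = make_microsphere_series(
            small_spec, [1.0], [10.0, 20.0], brightest_rate=2.0e4, noise=False, seed=3
        )
        signal = []
        for f in frames:
            signal.append(float((f.pixels.astype(float) - small_spec.dark_offset).sum()))
        # per-pixel rounding to integer counts leaves sub-percent slack
        assert signal[1] == pytest.approx(2.0 * signal[0], rel=0.01)

    def test_extreme_fraction_ratio_recovered(self, small_spec):
        # the device was calibrated over a 0.4%..100% nominal range
        frames, truth = make_microsphere_series(
            small_spec, [0.004, 1.0], [250.0], brightest_rate=2.0e5, noise=False, seed=5
        )
        rates = truth.groupby("nominal_fraction").true_rate.first()
        assert rates[0.004] / rates[1.0] == pytest.approx(0.004, rel=1e-12)
        measured = []
        for f in frames:
            img = normalize_by_exposure(f)
            centers = detect_spheres(img, 20)
            r_px = 3.0 / small_spec.pixel_pitch_um
            measured.append(sphere_rate_photometry(img, centers, r_px))
        assert measured[0] / measured[1] == pytest.approx(0.004, rel=0.05)

    def test_truth_rate_never_exceeds_well_ceiling(self):
        spec = AcquisitionSpec(frame_shape=(120, 160), full_well=30000)
        _, truth = make_microsphere_series(
            spec, [1.0], [250.0], brightest_rate=1.0e6, noise=False, seed=0
        )
        ceiling = (spec.full_well - spec.dark_offset) / 0.25
        assert (truth.true_rate <= ceiling + 1e-9).all()
        assert truth.saturated.all()

    def test_overcrowding_raises_density_error(self):
        spec = AcquisitionSpec(frame_shape=(32, 32))
        with pytest.raises(ValueError, match="density"):
            make_microsphere_series(spec, [1.0], [10.0], n_spheres=200, seed=0)

    def test_determinism(self, small_spec):
        a, ta = make_microsphere_series(small_spec, [0.5], [10.0], seed=9)
        b, tb = make_microsphere_series(small_spec, [0.5], [10.0], seed=9)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        assert ta.equals(tb)


class TestTumorBedPhantom:
    def test_ratio_by_construction(self, noiseless_spec):
        tumor, muscle, _, _ = make_tumor_bed_pair(
            noiseless_spec, 12000.0, 1000.0, noise=False, seed=0
        )
        t = normalize_by_exposure(tumor, background="none").rates.mean()
        m = normalize_by_exposure(muscle, background="none").rates.mean()
        assert t / m == pytest.approx(12.0, abs=1e-12)

    def test_no_clusters_means_empty_truth(self, noiseless_spec):
        *_, scene = make_tumor_bed_pair(noiseless_spec, 12000.0, 1000.0, noise=False, seed=0)
        assert scene.truth_mask.sum() == 0

    @pytest.mark.parametrize("offset", [(0.0, 0.0), (2.3, 1.1), (3.2, 3.2), (-2.9, 0.7)])
    def test_16um_cluster_footprint_matches_disc_oracle(self, noiseless_spec, offset):
        pitch = noiseless_spec.pixel_pitch_um
        center = (60 * pitch + offset[0], 80 * pitch + offset[1])
        *_, scene = make_tumor_bed_pair(
            noiseless_spec, 12000.0, 1000.0, [(center[0], center[1], 16.0, 12000.0)],
            noise=False, seed=0,
        )
        n = int(scene.truth_mask.sum())
        expected = disc_pixel_count_oracle(noiseless_spec.frame_shape, center, 16.0, pitch)
        assert n == expected
        assert 4 <= n <= 9

    def test_cluster_outside_frame_rejected(self, noiseless_spec):
        with pytest.raises(ValueError, match="outside"):
            make_tumor_bed_pair(
                noiseless_spec, 12000.0, 1000.0, [(1e6, 1e6, 16.0, 12000.0)], noise=False
            )

    def test_rate_ordering_validated(self, noiseless_spec):
        with pytest.raises(ValueError):
            make_tumor_bed_pair(noiseless_spec, 100.0, 1000.0)

    def test_poisson_region_mean_converges(self, small_spec):
        # >= 1e4 pixels: sample mean of normalized rates within 1% of truth
        _, muscle, _, _ = make_tumor_bed_pair(small_spec, 12000.0, 1000.0, noise=True, seed=7)
        rates = normalize_by_exposure(muscle).rates
        assert rates.size >= 10_000
        assert rates.mean() == pytest.approx(1000.0, rel=0.01)

    def test_rasterize_disc_requires_positive_diameter(self):
        with pytest.raises(ValueError):
            rasterize_disc((10, 10), (5.0, 5.0), 0.0, 6.5)


class TestCohorts:
    def test_zero_hazard_all_censored(self):
        df = simulate_cohort(CohortSpec(n_per_arm=25, baseline_hazard=0.0, true_hazard_ratio=2.0))
        assert (df.event == 0).all()
        assert (df.time_months == 12.0).all()

    def test_seed_determinism(self):
        spec = CohortSpec(n_per_arm=40, baseline_hazard=0.1, true_hazard_ratio=3.0, seed=11)
        assert simulate_cohort(spec).equals(simulate_cohort(spec))

    def test_empirical_hazard_ratio_converges(self):
        spec = CohortSpec(
            n_per_arm=40_000, baseline_hazard=0.05, true_hazard_ratio=3.0,
            followup_max=1e9, seed=2,
        )
        df = simulate_cohort(spec)
        neg = df[df.arm == ARM_NEGATIVE]
        pos = df[df.arm == ARM_POSITIVE]
        rate_neg = neg.event.sum() / neg.time_months.sum()
        rate_pos = pos.event.sum() / pos.time_months.sum()
        assert rate_pos / rate_neg == pytest.approx(3.0, rel=0.03)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_arm=0, baseline_hazard=0.1, true_hazard_ratio=1.0)
        with pytest.raises(ValueError):
            CohortSpec(n_per_arm=5, baseline_hazard=0.1, true_hazard_ratio=0.0)
        with pytest.raises(ValueError):
            CohortSpec(n_per_arm=5, baseline_hazard=0.1, true_hazard_ratio=1.0, followup_max=0)
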