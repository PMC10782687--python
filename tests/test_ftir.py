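"""Spectral preprocessing and band quantification."""

import numpy as np
import pytest

from gpresem import (
    BandDefinition,
    BandExtractor,
    DEFAULT_BANDS,
    Spectrum,
    average_replicates,
    band_value,
    baseline_correct,
    demo_spectrum,
    normalize_unit_area,
    synthetic_spectrum,
)

BANDS = {b.name: b for b in DEFAULT_BANDS}


class TestSpectrum:
    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValueError, match="monotone"):
            Spectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 2.0]), np.zeros(3))

    def test_descending_grid_accepted_and_normalised(self):
        s = Spectrum(np.array([4000.0, 3000.0, 600.0]), np.array([1.0, 2.0, 3.0]))
        asc = s.ascending()
        assert asc.wavenumbers[0] == 600.0
        assert asc.absorbance[0] == 3.0


class TestAverageReplicates:
    def test_identical_spectra_unchanged(self):
        s = synthetic_spectrum(peaks=((1000.0, 1.0, 30.0),))
        avg = average_replicates([s, s])
        assert np.allclose(avg.absorbance, s.absorbance)

    def test_single_spectrum_identity(self):
        s = synthetic_spectrum()
        avg = average_replicates([s])
        assert np.allclose(avg.absorbance, s.absorbance)

    def test_64_replicates_reduce_noise_eightfold(self):
        clean = synthetic_spectrum(peaks=())
        sigma = 0.08
        reps = [
            synthetic_spectrum(peaks=(), noise_sd=sigma, seed=i) for i in range(64)
        ]
        avg = average_replicates(reps)
        residual_sd = np.std(avg.absorbance - clean.absorbance)
        assert residual_sd == pytest.approx(sigma / 8, rel=0.25)

    def test_grid_mismatch_rejected(self):
        a = synthetic_spectrum(wn_min=600, wn_max=4000)
        b = synthetic_spectrum(wn_min=600, wn_max=3996)
        with pytest.raises(ValueError, match="common"):
            average_replicates([a, b])


class TestBaseline:
    def test_straight_line_zeroed(self):
        wn = np.arange(600.0, 4000.0, 4.0)
        s = Spectrum(wn, 0.2 + 0.001 * wn)
        out = baseline_correct(s, "linear")
        assert np.allclose(out.absorbance, 0.0, atol=1e-12)

    def test_flat_zero_unchanged(self):
        wn = np.arange(600.0, 4000.0, 4.0)
        out = baseline_correct(Spectrum(wn, np.zeros_like(wn)), "linear")
        assert np.allclose(out.absorbance, 0.0)

    def test_peak_on_ramp_recovered(self):
        """A Gaussian on a linear ramp: corrected peak height within 1%."""
        peak = (2000.0, 0.8, 40.0)
        s = synthetic_spectrum(peaks=(peak,), baseline_coeffs=(0.05, 0.1))
        out = baseline_correct(s, "linear")
        recovered = out.interpolate([2000.0])[0]
        assert recovered == pytest.approx(0.8, rel=0.01)

    def test_rubberband_on_convex_baseline(self):
        s = synthetic_spectrum(
            peaks=((1500.0, 1.0, 30.0),), baseline_coeffs=(2.0, -1.5, 0.3)
        )
        out = baseline_correct(s, "rubberband")
        assert out.interpolate([1500.0])[0] == pytest.approx(1.0, rel=0.02)
        assert np.min(out.absorbance) > -1e-9

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            baseline_correct(synthetic_spectrum(), "omnic")


class TestNormalizeUnitArea:
    def test_defining_property(self):
        s = synthetic_spectrum(peaks=((1200.0, 1.0, 50.0),), baseline_coeffs=(0.1,))
        out = normalize_unit_area(s)
        grid = np.arange(900.0, 1800.0 + 1, 1.0)
        area = np.trapezoid(out.interpolate(grid), grid)
        assert area == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        s = synthetic_spectrum(peaks=((1200.0, 1.0, 50.0),), baseline_coeffs=(0.1,))
        scaled = Spectrum(s.wavenumbers, 5.0 * s.absorbance)
        assert np.allclose(
            normalize_unit_area(s).absorbance,
            normalize_unit_area(scaled).absorbance,
            atol=1e-12,
        )

    def test_constant_becomes_reciprocal_width(self):
        wn = np.arange(600.0, 4000.0, 4.0)
        out = normalize_unit_area(Spectrum(wn, np.full_like(wn, 7.0)))
        assert np.allclose(out.absorbance, 1 / 900.0)

    def test_idempotence(self):
        s = synthetic_spectrum(peaks=((1200.0, 1.0, 50.0),), baseline_coeffs=(0.1,))
        once = normalize_unit_area(s)
        twice = normalize_unit_area(once)
        assert np.allclose(once.absorbance, twice.absorbance, atol=1e-12)

    def test_zero_area_rejected(self):
        wn = np.arange(600.0, 4000.0, 4.0)
        with pytest.raises(ValueError, match="area"):
            normalize_unit_area(Spectrum(wn, np.zeros_like(wn)))


class TestBandValue:
    def test_constant_spectrum_any_band(self):
        wn = np.arange(600.0, 4000.0, 4.0)
        s = Spectrum(wn, np.full_like(wn, 0.37))
        for band in DEFAULT_BANDS:
            assert band_value(s, band) == pytest.approx(0.37)

    def test_triangular_peak_interpolation(self):
        """Triangular peak centred at 970: the LMP value is the mean of the
        five every-10 sampled points, hand-computed from the tent shape."""
        wn = np.arange(600.0, 4000.0, 2.0)  # step 2 puts apex and band points on-grid
        apex, half_width = 970.0, 30.0
        ab = np.maximum(0.0, 1.0 - np.abs(wn - apex) / half_width)
        s = Spectrum(wn, ab)
        pts = np.array([950.0, 960.0, 970.0, 980.0, 990.0])
        expected = np.mean(np.maximum(0.0, 1.0 - np.abs(pts - apex) / half_width))
        assert band_value(s, BANDS["LMP"]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx((1 / 3 + 2 / 3 + 1 + 2 / 3 + 1 / 3) / 5)

    def test_linearity_in_absorbance(self):
        a = synthetic_spectrum(peaks=((970.0, 0.5, 20.0),))
        b = synthetic_spectrum(peaks=((1550.0, 0.7, 60.0),))
        combined = Spectrum(a.wavenumbers, 2 * a.absorbance + 3 * b.absorbance)
        for band in DEFAULT_BANDS:
            assert band_value(combined, band) == pytest.approx(
                2 * band_value(a, band) + 3 * band_value(b, band), abs=1e-12
            )

    def test_grid_reversal_invariance(self):
        s = synthetic_spectrum(peaks=((970.0, 0.5, 20.0), (1550.0, 0.7, 60.0)))
        rev = Spectrum(s.wavenumbers[::-1], s.absorbance[::-1])
        for band in DEFAULT_BANDS:
            assert band_value(rev, band) == pytest.approx(band_value(s, band))

    def test_segment_outside_grid(self):
        s = synthetic_spectrum(wn_min=1000, wn_max=2000)
        with pytest.raises(ValueError, match="outside the grid"):
            band_value(s, BANDS["LMP"])

    def test_grid_sampling_mode(self):
        s = synthetic_spectrum()
        band = BandDefinition("LMP_grid", ((950.0, 990.0),), sampling="grid")
        mask = (s.wavenumbers >= 950) & (s.wavenumbers <= 990)
        assert band_value(s, band) == pytest.approx(np.mean(s.absorbance[mask]))

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BandDefinition("bad", ((1000.0, 1100.0), (1050.0, 1200.0)))


class TestDemoSpectrum:
    def test_calibrated_band_values(self):
        s = demo_spectrum()
        assert band_value(s, BANDS["LMP"]) == pytest.approx(0.5512, abs=1e-4)
        assert band_value(s, BANDS["SAM"]) == pytest.approx(3.9617, abs=1e-4)
        assert band_value(s, BANDS["GSH"]) == pytest.approx(0.00515, abs=1e-5)


class TestBandExtractor:
    def test_pipeline_recovers_band_contrasts(self):
        """Full chain (average -> baseline -> normalise -> bands) preserves
        the ordering and ratios of generating peak heights within noise."""
        rng_seeds = range(8)
        heights = {"LMP": 0.6, "SAM": 0.3, "GSH": 0.15}
        peaks = ((970.0, heights["LMP"], 12.0), (1550.0, heights["SAM"], 50.0),
                 (2545.0, heights["GSH"], 8.0))
        replicate_sets = [
            [
                synthetic_spectrum(
                    peaks=peaks, baseline_coeffs=(0.02, 0.01), noise_sd=0.004,
                    seed=100 * k + i,
                )
                for i in range(16)
            ]
            for k in rng_seeds
        ]
        ex = BandExtractor(baseline="linear", normalize=True).fit()
        table = ex.transform(replicate_sets)
        assert list(table.columns) == ["LMP", "SAM", "GSH"]
        assert (table["LMP"] > table["SAM"]).all()  # narrow tall peak dominates its band mean
        # unit-area scaling cancels in ratios: compare to the noiseless pipeline
        clean = ex.transform([synthetic_spectrum(peaks=peaks, baseline_coeffs=(0.02, 0.01))])
        ratio = table["LMP"] / table["GSH"]
        clean_ratio = clean["LMP"][0] / clean["GSH"][0]
        assert np.allclose(ratio, clean_ratio, rtol=0.15)

    def test_transformer_clone(self):
        from sklearn.base import clone

        ex = BandExtractor(baseline="rubberband", normalize=False)
        assert clone(ex).get_params()["baseline"] == "rubberband"
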