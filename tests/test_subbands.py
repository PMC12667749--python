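import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirsikit import preprocess, subbands, synth
from mirsikit.model import (
    BandDefinition,
    ClassLabel,
    Spectrum,
    SpectrumSet,
    default_band_table,
    default_grid,
    make_grid,
)
from mirsikit.subbands import (
    DerivativeParams,
    band_integral,
    count_consistent_bands,
    detect_significant_peaks,
    fit_gaussian_subbands,
    peak_occurrence,
    percent_reduction,
    second_derivative,
    usable_bands,
)

KFF = ClassLabel("kidney", "FF")


def gaussian(x, center, fwhm, amp=1.0):
    return amp * np.exp(-4 * np.log(2) * (x - center) ** 2 / fwhm**2)


class TestSecondDerivative:
    def test_426_points_trim_to_400(self):
        grid = default_grid()
        d2 = second_derivative(Spectrum(grid, np.zeros(426)))
        assert len(d2.grid) == 400
        assert d2.grid.values[0] == 976.0 and d2.grid.values[-1] == 1774.0

    def test_trimming_preserves_interior_grid(self):
        grid = default_grid()
        d2 = second_derivative(Spectrum(grid, np.zeros(426)))
        np.testing.assert_array_equal(d2.grid.values, grid.values[13:-13])

    def test_quadratic_reproduced_exactly(self):
        # an order-2 fit reproduces quadratics: d2 of a*x^2 is the constant 2a
        grid = default_grid()
        a = 3.7e-4
        d2 = second_derivative(Spectrum(grid, a * grid.values**2))
        np.testing.assert_allclose(d2.absorbance, 2 * a, rtol=1e-9)

    def test_band_dip_located_at_center(self):
        """SG second-derivative minimum of a noise-free Gaussian band lands on
        the same grid point as a dense finite-difference oracle."""
        grid = default_grid()
        y = gaussian(grid.values, 1546.0, 20.0)
        d2 = second_derivative(Spectrum(grid, y))
        ours = d2.grid.values[np.argmin(d2.absorbance)]
        fine = np.arange(950.0, 1800.0 + 1e-9, 0.01)
        oracle_d2 = np.gradient(np.gradient(gaussian(fine, 1546.0, 20.0),
                                            fine), fine)
        oracle = fine[np.argmin(oracle_d2)]
        assert abs(ours - oracle) <= grid.step / 2

    @pytest.mark.parametrize("window,order", [(4, 2), (3, 2), (13, 14)])
    def test_invalid_params_rejected(self, window, order):
        with pytest.raises(ValueError):
            DerivativeParams(window_length=window, poly_order=order)


class TestDetection:
    def test_zero_derivative_yields_no_calls(self):
        grid = default_grid()
        d2 = Spectrum(grid, np.zeros(426))
        assert detect_significant_peaks(d2, sigma=1.0) == []

    def test_constructed_dip_detected_with_correct_significance(self):
        grid = make_grid(976, 1774, 2)
        sigma = 0.1
        y = np.zeros(len(grid))
        y[grid.index_of(1658.0)] = -10 * sigma
        calls = detect_significant_peaks(Spectrum(grid, y), sigma)
        assert len(calls) == 1
        assert calls[0].center == 1658.0
        assert calls[0].significance == pytest.approx(10.0)

    def test_sigma_required(self):
        grid = default_grid()
        with pytest.raises(ValueError):
            detect_significant_peaks(Spectrum(grid, np.zeros(426)), 0.0)

    @given(scale=st.floats(0.1, 100))
    def test_scale_consistency(self, scale):
        """Scaling a spectrum and sigma together leaves the call set fixed."""
        grid = default_grid()
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, len(grid))
        base = detect_significant_peaks(Spectrum(grid, y), 0.8)
        scaled = detect_significant_peaks(Spectrum(grid, scale * y),
                                          scale * 0.8)
        assert [c.center for c in base] == [c.center for c in scaled]
        np.testing.assert_allclose(
            [c.significance for c in base],
            [c.significance for c in scaled], rtol=1e-9,
        )

    def test_mean_spectrum_calls_match_generator_bands(self, default_gen,
                                                       masked_kidney_ff):
        _, stats, sset = masked_kidney_ff
        d2 = second_derivative(sset.mean_spectrum())
        calls = detect_significant_peaks(d2, stats.sigma)
        expected = sorted(b.center for b in default_gen.band_tables[KFF])
        got = [c.center for c in calls]
        assert len(got) == len(expected)
        np.testing.assert_allclose(got, expected, atol=2.0)

    def test_false_call_rate_on_pure_noise(self, default_gen):
        """At 3 sigma, pure-noise spectra average < 1 spurious call each."""
        cube = synth.simulate_cube(default_gen, KFF, "r", seed=8)
        mask, _ = preprocess.tissue_mask(cube)
        sigma = preprocess.background_stats(cube, mask).sigma
        rng = np.random.default_rng(99)
        noise = rng.normal(0, default_gen.noise_sd, (1000, 426))
        grid = default_grid()
        total = 0
        tgrid, d2 = subbands.second_derivative_matrix(grid, noise)
        for row in d2:
            total += len(detect_significant_peaks(Spectrum(tgrid, row), sigma))
        assert total / 1000 < 1.0


def _roi_set(matrix, roi_id="roi-0"):
    grid = default_grid()
    ids = np.column_stack([np.arange(len(matrix)), np.zeros(len(matrix))])
    return SpectrumSet(grid, matrix, ids, roi_id, KFF)


class TestOccurrence:
    def test_saturated_band_counts_every_spectrum(self):
        grid = default_grid()
        y = -gaussian(grid.values, 1400.0, 20.0, amp=1.0) * -1  # positive band
        matrix = np.tile(y, (120, 1))
        band = BandDefinition("protein", 1400.0, 1388, 1412)
        table = peak_occurrence([_roi_set(matrix)], [band], sigma=1e-4,
                                n_per_roi=100, seed=0)
        assert table.counts.loc[1400.0, "roi-0"] == 100

    def test_band_off_trimmed_range_rejected(self, masked_kidney_ff):
        _, stats, sset = masked_kidney_ff
        band = BandDefinition("DNA", 966.0, 954, 978)
        with pytest.raises(ValueError, match="trimmed"):
            peak_occurrence([sset], [band], stats.sigma, seed=0)

    def test_usable_bands_drops_out_of_range_centers(self):
        bands = default_band_table()
        kept = usable_bands(bands, default_grid())
        assert len(kept) == len(bands) - 1
        assert all(b.center != 966.0 for b in kept)

    def test_absent_band_rarely_called(self, masked_kidney_ff):
        """A reference band with no generator counterpart (and no close
        neighbor) stays under the 3-sigma false-call ceiling."""
        _, stats, sset = masked_kidney_ff
        band = BandDefinition("artifact", 1026.0, 1014, 1028)
        table = peak_occurrence([sset], [band], stats.sigma,
                                n_per_roi=100, seed=1)
        assert table.counts.loc[1026.0, sset.roi_id] <= 5

    def test_partial_presence_band_tracks_bernoulli_rate(self, default_gen):
        """kidney-FFPE 1026 cm^-1 occurrence stays inside the 95% binomial
        envelope of its presence probability 0.5."""
        label = ClassLabel("kidney", "FFPE")
        counts = []
        for i in range(8):
            cube = synth.simulate_cube(default_gen, label, f"r{i}",
                                       synth.roi_seed(11, label, i))
            mask, _ = preprocess.tissue_mask(cube)
            sigma = preprocess.background_stats(cube, mask).sigma
            sset = preprocess.sample_pixels(cube, mask, 400, seed=i)
            band = BandDefinition("artifact", 1026.0, 1014, 1028)
            table = peak_occurrence([sset], [band], sigma,
                                    n_per_roi=100, seed=i)
            counts.append(table.counts.loc[1026.0, "r" + str(i)])
        # 95% binomial interval for n=100, p=0.5 is roughly [40, 60]
        assert 40 <= np.median(counts) <= 60

    def test_empty_occurrence_counts_no_bands(self):
        import pandas as pd
        table = subbands.OccurrenceTable(pd.DataFrame(), 100, 2.0)
        assert count_consistent_bands(table) == 0


class TestGaussianFit:
    def test_single_band_recovered_within_one_percent(self):
        grid = default_grid()
        y = gaussian(grid.values, 1658.0, 20.0, amp=1.0)
        fit = fit_gaussian_subbands(Spectrum(grid, y), [1658.0])
        (sb,) = fit.subbands
        assert sb.center == pytest.approx(1658.0, abs=0.2)
        assert sb.fwhm == pytest.approx(20.0, rel=0.01)
        assert sb.amplitude == pytest.approx(1.0, rel=0.01)
        assert fit.residual_rms < 1e-6

    def test_two_close_bands_recovered(self):
        """Two bands 20 cm^-1 apart, noise-free: amplitudes within 5% of a
        dense-grid fit started from the true values (which recovers them
        exactly for an exact model)."""
        grid = default_grid()
        y = (gaussian(grid.values, 1400.0, 20.0, 0.8)
             + gaussian(grid.values, 1420.0, 20.0, 0.5))
        fit = fit_gaussian_subbands(Spectrum(grid, y), [1400.0, 1420.0])
        amps = sorted(sb.amplitude for sb in fit.subbands)
        assert amps[0] == pytest.approx(0.5, rel=0.05)
        assert amps[1] == pytest.approx(0.8, rel=0.05)

    def test_empty_centers_rejected(self):
        grid = default_grid()
        with pytest.raises(ValueError):
            fit_gaussian_subbands(Spectrum(grid, np.zeros(426)), [])


class TestBandIntegral:
    def test_constant_over_24_window(self):
        grid = default_grid()
        band = BandDefinition("Amide I", 1658.0, 1646, 1670)
        val = band_integral(Spectrum(grid, np.ones(426)), band)
        assert val == pytest.approx(24.0)

    def test_cubic_integrated_exactly(self):
        grid = default_grid()
        x = grid.values
        y = 1e-8 * (x - 1300.0) ** 3 + 2.0
        band = BandDefinition("test", 1658.0, 1646, 1670)  # 13 points, odd
        analytic = (1e-8 * ((1670 - 1300.0) ** 4 - (1646 - 1300.0) ** 4) / 4
                    + 2.0 * 24)
        assert band_integral(Spectrum(grid, y), band) == pytest.approx(analytic)

    def test_even_point_window_handled_with_trapezoid(self):
        grid = default_grid()
        x = grid.values
        y = 0.01 * x  # linear: exact under both Simpson and trapezoid
        band = BandDefinition("test", 1657.0, 1646, 1668)  # 12 points, even
        analytic = 0.01 * (1668**2 - 1646**2) / 2
        assert band_integral(Spectrum(grid, y), band) == pytest.approx(analytic)

    def test_gaussian_area_closed_form(self):
        grid = default_grid()
        y = gaussian(grid.values, 1400.0, 20.0)
        band = BandDefinition("test", 1400.0, 1340, 1460)
        area = 20.0 * np.sqrt(np.pi / np.log(16))
        assert band_integral(Spectrum(grid, y), band) == pytest.approx(
            area, rel=5e-3
        )

    def test_window_outside_grid_rejected(self):
        grid = default_grid()
        band = BandDefinition("test", 960.0, 940, 980)
        with pytest.raises(ValueError, match="outside"):
            band_integral(Spectrum(grid, np.ones(426)), band)


class TestPercentReduction:
    @pytest.mark.parametrize("ff,ffpe,expected",
                             [(3.0, 1.0, 200 / 3), (5.0, 5.0, 0.0)])
    def test_arithmetic(self, ff, ffpe, expected):
        assert percent_reduction(ff, ffpe) == pytest.approx(expected)

    def test_nonpositive_ff_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)
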