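"""AFM PSD analytics and Hill titration fitting."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from rnaloops import (
    HeightMap,
    compute_psd,
    crossover,
    fit_autoaffine,
    fit_hill,
    fit_power_law,
    percent_compaction,
    compare_constructs,
    simulate_heightmap,
    simulate_titration,
)
from rnaloops.afm import Spectrum, estimate_noise_floor
from rnaloops.errors import DataError, FitError, ParameterError
from rnaloops.titration import TitrationCurve


class TestComputePsd:
    def test_constant_map_has_zero_power(self):
        hm = HeightMap(np.full((64, 64), 3.0), 1.0)
        spec = compute_psd([hm])
        assert np.allclose(spec.power[1:], 0.0)

    def test_single_cosine_peaks_at_its_frequency(self):
        n, pix = 255, 0.98
        x = np.arange(n) * pix
        row = np.cos(2 * np.pi * x / (16 * pix))
        hm = HeightMap(np.tile(row, (n, 1)), pix)
        spec = compute_psd([hm])
        peak = spec.frequency[np.argmax(spec.power[1:]) + 1]
        assert peak == pytest.approx(1 / (16 * pix), rel=0.05)

    def test_white_noise_parseval(self, rng):
        hm = HeightMap(rng.normal(0, 0.5, (255, 255)), 0.98)
        spec = compute_psd([hm])
        detrended = hm.heights - hm.heights.mean(axis=1, keepdims=True)
        variance = detrended.var(axis=1).mean()
        assert abs(spec.power[1:].sum() - variance) / variance < 0.01

    def test_offset_invariance_and_quadratic_scaling(self, rng):
        base = rng.normal(0, 0.3, (128, 128))
        a = compute_psd([HeightMap(base, 1.0)])
        b = compute_psd([HeightMap(base + 5.0, 1.0)])
        c = compute_psd([HeightMap(3.0 * base, 1.0)])
        assert np.allclose(a.power, b.power)
        assert np.allclose(c.power, 9.0 * a.power)

    def test_y_axis_analyses_columns(self, rng):
        img = np.zeros((64, 64))
        img[:, 10] = 1.0  # a vertical ridge: flat along y, structured along x
        along_x = compute_psd([HeightMap(img, 1.0)], axis="x")
        along_y = compute_psd([HeightMap(img, 1.0)], axis="y")
        assert along_x.power[1:].sum() > 0
        assert np.allclose(along_y.power[1:], 0.0)

    def test_mixed_pixel_sizes_rejected(self):
        a = HeightMap(np.zeros((64, 64)), 0.98)
        b = HeightMap(np.zeros((64, 64)), 1.96)
        with pytest.raises(DataError):
            compute_psd([a, b])


class TestAutoaffineFits:
    def test_exact_power_law_recovered(self):
        f = np.logspace(-3, 0, 120)
        spec = Spectrum(np.concatenate(([0.0], f)), np.concatenate(([0.0], 2.5 * f**-2)))
        fit = fit_power_law(spec, (1e-3, 1.0))
        assert fit.gamma == pytest.approx(2.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(2.5, rel=1e-6)

    def test_analytic_crossover(self):
        # log10 P = -2 log10 f  meets  log10 P = -4 (flat)  at f = 10^-2
        f = np.logspace(-3, 0, 120)
        steep = fit_power_law(Spectrum(f, f**-2.0 * 1e-8), (1e-3, 1.0))
        flat = fit_power_law(Spectrum(f, np.full_like(f, 1e-4)), (1e-3, 1.0))
        scale = crossover(flat, steep)
        assert scale.crossover_frequency == pytest.approx(1e-2, rel=1e-6)
        assert scale.length_nm == pytest.approx(100.0, rel=1e-6)

    def test_angular_convention_reported(self):
        f = np.logspace(-3, 0, 120)
        steep = fit_power_law(Spectrum(f, f**-2.0 * 1e-8), (1e-3, 1.0))
        flat = fit_power_law(Spectrum(f, np.full_like(f, 1e-4)), (1e-3, 1.0))
        cycles = crossover(flat, steep, "cycles")
        angular = crossover(flat, steep, "angular")
        assert angular.length_nm == pytest.approx(2 * np.pi * cycles.length_nm)
        assert "2*pi" in angular.convention

    def test_parallel_fits_rejected(self):
        f = np.logspace(-3, 0, 120)
        a = fit_power_law(Spectrum(f, f**-2.0), (1e-3, 1.0))
        with pytest.raises(FitError):
            crossover(a, a)

    def test_characteristic_length_tracks_particle_diameter(self):
        """30-nm compact particles give a ~30-nm characteristic length."""
        maps = [simulate_heightmap("compact", diameter_nm=30, seed=s) for s in range(15)]
        spec = compute_psd(maps)
        _, _, scale = fit_autoaffine(spec)
        assert abs(scale.length_nm - 30) / 30 < 0.15

    def test_monotonic_over_diameter_range(self):
        """Characteristic length rises monotonically with planted diameter.

        A 500-nm crop is used so the low-frequency plateau stays resolvable
        for the largest particles.
        """
        diameters = [15, 25, 30, 45, 55, 65, 75, 85]
        lengths = []
        for d in diameters:
            maps = [
                simulate_heightmap("compact", diameter_nm=d, crop_nm=500, seed=s)
                for s in range(8)
            ]
            _, _, scale = fit_autoaffine(compute_psd(maps))
            lengths.append(scale.length_nm)
        assert spearmanr(diameters, lengths).statistic > 0.95

    def test_noise_floor_estimate(self, rng):
        hm = HeightMap(rng.normal(0, 0.1, (128, 128)), 1.0)
        spec = compute_psd([hm])
        floor = estimate_noise_floor(spec)
        assert floor == pytest.approx(np.median(spec.power[1:]), rel=0.2)


class TestPercentCompaction:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(85.0, 65.0, 23.529411764705884), (70.0, 56.0, 20.0), (42.0, 42.0, 0.0)],
    )
    def test_values(self, before, after, expected):
        assert percent_compaction(before, after) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ParameterError):
            percent_compaction(0.0, 10.0)


class TestHillFit:
    def test_noiseless_parameters_recovered_exactly(self):
        curve = simulate_titration(12.0, 9.6, c_half=1.0, n_hill=2.0)
        fit = fit_hill(curve)
        assert fit.r0 == pytest.approx(12.0, abs=1e-6)
        assert fit.r_inf == pytest.approx(9.6, abs=1e-6)
        assert fit.c_half_mM == pytest.approx(1.0, abs=1e-6)
        assert fit.n_hill == pytest.approx(2.0, abs=1e-6)
        assert fit.percent_compaction == pytest.approx(20.0, abs=1e-6)

    def test_fitted_curve_midpoint_identity(self):
        curve = simulate_titration(11.0, 8.5, c_half=2.5, n_hill=1.5, noise_sd=0.05, seed=4)
        fit = fit_hill(curve)
        mid = fit.predict([fit.c_half_mM])[0]
        assert mid == pytest.approx((fit.r0 + fit.r_inf) / 2, abs=1e-9)

    def test_zero_noise_bias_below_two_percent(self, rng):
        for _ in range(50):
            r_inf = rng.uniform(7, 11)
            r0 = r_inf * rng.uniform(1.1, 1.5)
            c_half = 10 ** rng.uniform(-1, 1)
            n = rng.uniform(0.8, 4.0)
            curve = simulate_titration(r0, r_inf, c_half, n)
            fit = fit_hill(curve)
            assert abs(fit.r0 - r0) / r0 < 0.02
            assert abs(fit.r_inf - r_inf) / r_inf < 0.02
            assert abs(fit.c_half_mM - c_half) / c_half < 0.02
            assert abs(fit.n_hill - n) / n < 0.02

    def test_median_midpoint_error_under_noise(self):
        errors = []
        for seed in range(100):
            curve = simulate_titration(12.0, 9.6, 1.0, 2.0, noise_sd=0.1, seed=seed)
            fit = fit_hill(curve)
            errors.append(abs(fit.c_half_mM - 1.0) / 1.0)
        assert np.median(errors) < 0.10

    def test_expansion_flagged_but_fitted(self):
        curve = simulate_titration(12.0, 9.6, 1.0, 2.0)
        rising = TitrationCurve(curve.concentrations_mM, curve.radii_nm[::-1].copy())
        fit = fit_hill(rising)
        assert fit.direction == "expansion"

    def test_degenerate_data_rejected(self):
        with pytest.raises(FitError):
            fit_hill(TitrationCurve(np.logspace(-2, 2, 8), np.full(8, 10.0)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fit_hill(TitrationCurve([0.1, 1, 10], [12, 10.8, 9.6]))

    def test_summary_reports_key_quantities(self):
        fit = fit_hill(simulate_titration(12.0, 9.6, 1.0, 2.0))
        text = fit.summary()
        assert "C_Mg1/2" in text and "compaction" in text


class TestCompareConstructs:
    def test_identical_fits_give_zero(self):
        fit = fit_hill(simulate_titration(12.0, 9.6, 1.0, 2.0))
        assert compare_constructs(fit, fit) == pytest.approx(0.0)

    def test_sign_flips_under_swap(self):
        a = fit_hill(simulate_titration(12.0, 9.6, 1.0, 2.0))
        b = fit_hill(simulate_titration(12.0, 10.4, 1.5, 2.0))
        fwd = compare_constructs(a, b)
        rev = compare_constructs(b, a)
        assert fwd > 0 and rev < 0
        assert fwd == pytest.approx(-rev, rel=0.1)

    def test_planted_eight_percent_difference_recovered(self):
        wild = fit_hill(simulate_titration(12.0, 9.6, 1.0, 2.0, noise_sd=0.05, seed=1))
        mutant = fit_hill(
            simulate_titration(12.0, 9.6 * 1.08, 1.6, 2.0, noise_sd=0.05, seed=2)
        )
        assert compare_constructs(wild, mutant) == pytest.approx(8.0, abs=1.0)

    def test_no_difference_below_the_midpoint(self):
        """Constructs share R_h below C_half; the gap opens above it."""
        wild = fit_hill(simulate_titration(12.0, 9.6, 1.0, 2.0))
        mutant = fit_hill(simulate_titration(12.0, 9.6 * 1.08, 1.0, 2.0))
        low = np.array([0.01, 0.05, 0.1])
        high = np.array([10.0, 50.0, 100.0])
        low_gap = np.abs(wild.predict(low) - mutant.predict(low)).max()
        high_gap = np.abs(wild.predict(high) - mutant.predict(high)).min()
        assert low_gap < 0.05
        assert high_gap > 0.5


class TestHeightMapIO:
    def test_text_round_trip(self, rng, tmp_path):
        hm = HeightMap(rng.normal(0, 0.1, (64, 64)), 0.98)
        back = HeightMap.from_text(hm.to_text())
        assert back.pixel_size_nm == hm.pixel_size_nm
        assert np.allclose(back.heights, hm.heights, atol=1e-3)

    def test_tiff_round_trip(self, rng, tmp_path):
        hm = HeightMap(rng.normal(0, 0.1, (64, 64)), 0.98)
        path = tmp_path / "map.tiff"
        hm.to_tiff(path)
        back = HeightMap.from_tiff(path, 0.98)
        assert np.allclose(back.heights, hm.heights, atol=1e-5)

    def test_non_square_rejected(self):
        with pytest.raises(DataError):
            HeightMap(np.zeros((10, 20)), 1.0)
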