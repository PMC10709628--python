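"""Preprocessing chain: resampling, rubber-band baseline, Savitzky-Golay
derivatives, vector normalization, background subtraction."""

import numpy as np
import pytest
from oracles import lower_hull_baseline_bruteforce

from starchir import synth
from starchir.preprocess import (
    PreprocessConfig,
    preprocess_features,
    resample,
    rubberband_baseline,
    sg_derivative,
    subtract_background,
    subtract_water_vapor,
    synthetic_vapor_reference,
    vector_normalize,
)
from starchir.spectra import ROIBand, Spectrum, WavenumberGrid


def _spec(x, y):
    return Spectrum(WavenumberGrid(np.asarray(x, float)), np.asarray(y, float))


class TestResample:
    def test_identity_on_target_grid(self):
        g = WavenumberGrid.regular(1000, 1100, 2)
        s = Spectrum(g, np.sin(g.values / 30))
        out = resample(s, g)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-15)

    def test_linear_function_exact_anywhere(self):
        g = WavenumberGrid.regular(1000, 1200, 8)
        s = Spectrum(g, 2.0 * g.values)
        tgt = WavenumberGrid.regular(1003, 1195, 3)
        out = resample(s, tgt)
        np.testing.assert_allclose(out.absorbance, 2.0 * tgt.values, rtol=1e-12)

    def test_midpoint_interpolation(self):
        s = _spec([1000, 1002, 1004], [0.1, 0.3, 0.1])
        out = resample(s, WavenumberGrid(np.array([1000.0, 1001.0, 1004.0])))
        assert out.absorbance[1] == pytest.approx(0.2)

    def test_extrapolation_rejected(self):
        g = WavenumberGrid.regular(1000, 1100, 2)
        s = Spectrum(g, np.zeros(len(g)))
        with pytest.raises(ValueError, match="extrapolat"):
            resample(s, WavenumberGrid.regular(900, 1100, 2))


class TestRubberband:
    def test_straight_line_corrects_to_zero(self):
        g = WavenumberGrid.regular(1000, 1200, 4)
        s = Spectrum(g, 0.002 * g.values + 1.0)
        corrected, baseline = rubberband_baseline(s)
        np.testing.assert_allclose(corrected.absorbance, 0.0, atol=1e-12)
        np.testing.assert_allclose(baseline.absorbance, s.absorbance, atol=1e-12)

    def test_gaussian_on_ramp_recovers_amplitude(self):
        g = WavenumberGrid.regular(1000, 1400, 2)
        x = g.values
        peak = 0.8 * np.exp(-0.5 * ((x - 1200) / 20) ** 2)
        s = Spectrum(g, peak + 0.001 * x)
        corrected, _ = rubberband_baseline(s)
        assert corrected.absorbance.max() == pytest.approx(0.8, rel=0.01)

    def test_v_shape_zero_at_hull_vertices(self):
        s = _spec([1000, 1010, 1020], [0.5, 0.1, 0.6])
        corrected, _ = rubberband_baseline(s)
        assert corrected.absorbance[0] == 0.0
        assert corrected.absorbance[1] == 0.0  # the minimum is a hull vertex
        assert corrected.absorbance[2] == 0.0

    def test_bounded_by_input_and_zero(self, rng):
        g = WavenumberGrid.regular(900, 1700, 4)
        y = np.abs(rng.normal(0.3, 0.2, len(g)))
        corrected, _ = rubberband_baseline(Spectrum(g, y))
        assert np.all(corrected.absorbance >= 0.0)
        assert np.all(corrected.absorbance <= y + 1e-12)

    def test_matches_bruteforce_pair_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 200))
            x = np.sort(rng.uniform(900, 1800, n))
            x += np.arange(n) * 1e-6  # ensure strictly increasing
            y = rng.normal(0.5, 0.3, n).cumsum() * 0.05 + rng.uniform(0, 2)
            s = Spectrum(WavenumberGrid(x), y)
            _, baseline = rubberband_baseline(s)
            oracle = lower_hull_baseline_bruteforce(x, y)
            np.testing.assert_allclose(baseline.absorbance, oracle, atol=1e-9)


class TestSGDerivative:
    def test_quadratic_gives_constant_second_derivative(self):
        g = WavenumberGrid.regular(900, 1800, 2)
        s = Spectrum(g, (g.values / 100.0) ** 2)
        out = sg_derivative(s)
        np.testing.assert_allclose(out.absorbance, 2.0 / 100.0**2, rtol=1e-6)

    def test_cubic_exact_everywhere(self):
        g = WavenumberGrid.regular(900, 1800, 2)
        t = g.values / 1000.0
        s = Spectrum(g, t**3 - 2 * t**2 + t)
        out = sg_derivative(s)
        expected = (6 * t - 4) / 1000.0**2
        np.testing.assert_allclose(out.absorbance, expected, atol=1e-12)

    def test_constant_gives_zero(self):
        g = WavenumberGrid.regular(900, 1800, 2)
        out = sg_derivative(Spectrum(g, np.full(len(g), 0.7)))
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_linearity(self, rng):
        g = WavenumberGrid.regular(900, 1800, 2)
        a = Spectrum(g, rng.normal(size=len(g)))
        b = Spectrum(g, rng.normal(size=len(g)))
        combo = Spectrum(g, 2.0 * a.absorbance - 0.5 * b.absorbance)
        lhs = sg_derivative(combo).absorbance
        rhs = 2.0 * sg_derivative(a).absorbance - 0.5 * sg_derivative(b).absorbance
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_non_uniform_grid_rejected(self):
        x = np.concatenate([np.arange(900, 1000, 2.0), np.arange(1000, 1200, 4.0)])
        s = Spectrum(WavenumberGrid(x), np.zeros(x.size))
        with pytest.raises(ValueError, match="resample"):
            sg_derivative(s)

    def test_window_longer_than_spectrum_rejected(self):
        g = WavenumberGrid.regular(1000, 1020, 2)
        with pytest.raises(ValueError):
            sg_derivative(Spectrum(g, np.zeros(len(g))))


class TestVectorNormalize:
    def test_three_four_five(self):
        s = _spec([1000, 1002], [3.0, 4.0])
        out = vector_normalize(s)
        np.testing.assert_allclose(out.absorbance, [0.6, 0.8])

    def test_unit_norm_and_idempotence(self, rng):
        g = WavenumberGrid.regular(900, 1800, 2)
        s = Spectrum(g, rng.normal(size=len(g)))
        out = vector_normalize(s)
        assert np.linalg.norm(out.absorbance) == pytest.approx(1.0, abs=1e-12)
        again = vector_normalize(out)
        np.testing.assert_allclose(again.absorbance, out.absorbance, atol=1e-12)

    def test_zero_vector_rejected(self):
        s = _spec([1000, 1002], [0.0, 0.0])
        with pytest.raises(ValueError):
            vector_normalize(s)


class TestFeatureChain:
    def test_invariant_to_additive_linear_baseline(self, full_grid, signatures16):
        spec = synth.synthesize_spectrum(signatures16[0], full_grid, seed=4)
        x = full_grid.values
        tilted = spec.copy(absorbance=spec.absorbance + 0.05 + 1e-4 * x)
        f0 = preprocess_features(spec)
        f1 = preprocess_features(tilted)
        assert np.max(np.abs(f0 - f1)) < 1e-6

    def test_invariant_to_positive_scaling(self, full_grid, signatures16):
        spec = synth.synthesize_spectrum(signatures16[1], full_grid, seed=5)
        f0 = preprocess_features(spec)
        f1 = preprocess_features(spec.copy(absorbance=3.7 * spec.absorbance))
        assert np.max(np.abs(f0 - f1)) < 1e-9

    def test_noise_far_from_starch_in_feature_space(self, full_grid, signatures16, rng):
        sig = signatures16[0]
        a = preprocess_features(synth.synthesize_spectrum(sig, full_grid, seed=1))
        b = preprocess_features(synth.synthesize_spectrum(sig, full_grid, seed=2))
        within = np.linalg.norm(a - b)
        noise = Spectrum(full_grid, np.abs(rng.normal(0.1, 0.03, len(full_grid))))
        far = np.linalg.norm(a - preprocess_features(noise))
        assert far > 5 * within


class TestBackgroundSubtraction:
    def test_zero_scale_is_identity(self, full_grid, signatures16):
        t = synth.synthesize_spectrum(signatures16[0], full_grid, seed=1)
        b = synth.synthesize_spectrum(synth.default_soil_signature(), full_grid, seed=2)
        out = subtract_background(t, b, scale=0.0)
        np.testing.assert_array_equal(out.absorbance, t.absorbance)

    def test_self_subtraction_gives_zero(self, full_grid, signatures16):
        t = synth.synthesize_spectrum(signatures16[0], full_grid, seed=1)
        out = subtract_background(t, t, scale=1.0)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_auto_scale_recovers_mixing_coefficient(self, full_grid, signatures16):
        # the projection estimator presumes the fit window is soil-dominated
        # (heavily encrusted deposits); use a matrix much thicker than the grain
        soil = synth.default_soil_signature().scaled(8.0)
        soil_spec = synth.synthesize_spectrum(soil, full_grid, noise_sd=0.0, seed=3,
                                              drift_scale=0.0)
        sig = synth.ClassSignature(
            signatures16[0].label, signatures16[0].bands, amp_cv=0.0, center_jitter_sd=0.0
        )
        starch = synth.synthesize_spectrum(sig, full_grid, noise_sd=0.0, seed=4,
                                           drift_scale=0.0)
        mix = starch.copy(absorbance=starch.absorbance + 0.7 * soil_spec.absorbance)
        out = subtract_background(mix, soil_spec, scale="auto")
        assert out.meta["background_scale"] == pytest.approx(0.7, rel=0.10)

    def test_grid_mismatch_rejected(self, full_grid):
        other = WavenumberGrid.regular(900, 1800, 2)
        t = Spectrum(full_grid, np.ones(len(full_grid)))
        b = Spectrum(other, np.ones(len(other)))
        with pytest.raises(ValueError):
            subtract_background(t, b)

    def test_auto_scale_clipped_at_two(self, full_grid):
        x = full_grid.values
        band = np.exp(-0.5 * ((x - 1030) / 60) ** 2)
        t = Spectrum(full_grid, 10.0 * band)
        b = Spectrum(full_grid, band)
        out = subtract_background(t, b, scale="auto")
        assert out.meta["background_scale"] == 2.0


class TestWaterVapor:
    def test_subtraction_attenuates_vapor_lines(self, full_grid):
        vapor = synthetic_vapor_reference(full_grid)
        contaminated = Spectrum(full_grid, 0.4 * vapor.absorbance + 0.01)
        cleaned = subtract_water_vapor(contaminated)
        sel = (full_grid.values >= 1300) & (full_grid.values <= 1900)
        assert np.std(cleaned.absorbance[sel]) < 0.05 * np.std(contaminated.absorbance[sel])
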