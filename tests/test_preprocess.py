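"""Preprocessing chain: smoothing, baseline, normalization, atmospheric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import savgol_coeffs

from irhisto import (
    PhantomConfig,
    PreprocessConfig,
    Spectrum,
    ValidationError,
    WavenumberAxis,
    atmospheric_correct,
    default_signatures,
    generate,
    offset_correct,
    preprocess_chain,
    rubber_band_baseline,
    savitzky_golay,
    vector_normalize,
)
from irhisto.phantom import DEFAULT_AXIS


class TestSavitzkyGolay:
    def test_constant_unchanged(self, default_axis):
        s = Spectrum(default_axis, np.full(len(default_axis), 0.7))
        out = savitzky_golay(s, 7, 3)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(coeffs=st.lists(st.floats(-1, 1), min_size=4, max_size=4))
    def test_cubic_polynomials_preserved(self, coeffs, default_axis):
        t = np.linspace(-1, 1, len(default_axis))
        s = Spectrum(default_axis, np.polyval(coeffs, t))
        out = savitzky_golay(s, 7, 3)
        np.testing.assert_allclose(out.absorbance[3:-3], s.absorbance[3:-3],
                                   atol=1e-9)

    def test_noise_variance_reduction_matches_coefficient_norm(self, default_axis):
        # independent oracle: variance gain of a linear filter on white noise
        # equals the squared L2 norm of its impulse response
        expected = float(np.sum(savgol_coeffs(7, 3) ** 2))
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(200):
            noise = rng.standard_normal(len(default_axis))
            sm = savitzky_golay(Spectrum(default_axis, noise), 7, 3)
            ratios.append(sm.absorbance[3:-3].var() / noise[3:-3].var())
        assert np.mean(ratios) == pytest.approx(expected, rel=0.05)

    def test_spectrum_shorter_than_window_rejected(self):
        axis = WavenumberAxis(np.linspace(1800, 1772, 8))
        s = Spectrum(axis, np.zeros(8))
        with pytest.raises(ValidationError):
            savitzky_golay(s, 9, 3)


class TestRubberBand:
    def test_affine_spectrum_maps_to_zero(self, default_axis):
        s = Spectrum(default_axis, 0.4 + 0.001 * default_axis.values)
        corrected, baseline = rubber_band_baseline(s)
        np.testing.assert_allclose(corrected.absorbance, 0.0, atol=1e-9)
        np.testing.assert_allclose(baseline.absorbance, s.absorbance, atol=1e-9)

    def test_single_band_on_zero_baseline_unchanged(self, default_axis):
        band = np.exp(-0.5 * ((default_axis.values - 1350) / 20) ** 2)
        corrected, _ = rubber_band_baseline(Spectrum(default_axis, band))
        np.testing.assert_allclose(corrected.absorbance[1:-1], band[1:-1],
                                   atol=1e-9)

    def test_band_plus_affine_recovered_within_two_percent(self, default_axis):
        nu = default_axis.values
        band = 0.8 * np.exp(-0.5 * ((nu - 1350) / 15) ** 2)
        baseline = 0.3 + 0.0004 * nu
        corrected, _ = rubber_band_baseline(Spectrum(default_axis, band + baseline))
        assert np.max(np.abs(corrected.absorbance - band)) < 0.02 * 0.8

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_baseline_is_convex_minorant(self, seed, default_axis):
        rng = np.random.default_rng(seed)
        s = Spectrum(default_axis, rng.random(len(default_axis)))
        corrected, baseline = rubber_band_baseline(s)
        assert np.all(corrected.absorbance >= -1e-12)
        assert np.all(baseline.absorbance <= s.absorbance + 1e-12)
        assert abs(corrected.absorbance[0]) < 1e-12
        assert abs(corrected.absorbance[-1]) < 1e-12


class TestNormalizeAndOffset:
    def test_three_four_five(self, default_axis):
        a = np.zeros(len(default_axis))
        a[0], a[1] = 3.0, 4.0
        out = vector_normalize(Spectrum(default_axis, a))
        assert out.absorbance[0] == pytest.approx(0.6)
        assert out.absorbance[1] == pytest.approx(0.8)
        assert np.linalg.norm(out.absorbance) == pytest.approx(1.0, abs=1e-12)

    def test_normalization_idempotent(self, default_axis):
        s = Spectrum(default_axis, np.sin(default_axis.values / 13) + 2)
        once = vector_normalize(s)
        twice = vector_normalize(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)

    def test_zero_norm_rejected(self, default_axis):
        with pytest.raises(ValidationError):
            vector_normalize(Spectrum(default_axis, np.zeros(len(default_axis))))

    @pytest.mark.parametrize("values, expected", [
        ([1.0, 2.0, 3.0], [0.0, 1.0, 2.0]),
        ([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]),
        ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
    ])
    def test_offset_examples(self, values, expected, default_axis):
        a = np.tile(values, len(default_axis) // 3 + 1)[:len(default_axis)]
        out = offset_correct(Spectrum(default_axis, a))
        assert out.absorbance.min() == 0.0
        np.testing.assert_allclose(out.absorbance, a - min(values), atol=1e-12)


class TestChain:
    def test_constant_spectrum_fails_at_normalization(self, default_axis):
        s = Spectrum(default_axis, np.full(len(default_axis), 2.0))
        with pytest.raises(ValidationError, match="zero-norm"):
            preprocess_chain(s)

    def test_pure_signature_shape_preserved(self):
        sig = default_signatures("anagen")["ORS"].evaluate(DEFAULT_AXIS)
        out = preprocess_chain(sig)
        cos = np.dot(out.absorbance, sig.absorbance) / (
            np.linalg.norm(out.absorbance) * np.linalg.norm(sig.absorbance))
        assert cos > 0.999

    def test_chain_stabilizes_under_repeated_application(self, noisy_phantom):
        """Re-running the chain contracts: successive changes shrink.

        Exact idempotence is impossible because Savitzky-Golay smoothing is
        a convolution, not a projection; re-smoothing an already smoothed
        spectrum still moves it slightly.  The baseline/normalize/offset
        portion of the chain, however, is idempotent (next test).
        """
        rng = np.random.default_rng(3)
        rr, cc = np.nonzero(noisy_phantom.image.mask)
        for j in rng.choice(rr.size, size=20, replace=False):
            s = noisy_phantom.image.pixel(rr[j], cc[j])
            c1 = preprocess_chain(s)
            c2 = preprocess_chain(c1)
            c3 = preprocess_chain(c2)
            d12 = np.abs(c2.absorbance - c1.absorbance).max()
            d23 = np.abs(c3.absorbance - c2.absorbance).max()
            assert d12 < 0.05 * np.abs(c1.absorbance).max()
            assert d23 <= d12 * 1.2

    def test_baseline_normalize_offset_subchain_idempotent(self, noisy_phantom):
        rng = np.random.default_rng(4)
        rr, cc = np.nonzero(noisy_phantom.image.mask)

        def subchain(s):
            out, _ = rubber_band_baseline(s)
            return offset_correct(vector_normalize(out))

        for j in rng.choice(rr.size, size=10, replace=False):
            once = subchain(noisy_phantom.image.pixel(rr[j], cc[j]))
            twice = subchain(once)
            np.testing.assert_allclose(twice.absorbance, once.absorbance,
                                       atol=1e-9)

    @settings(derandomize=True, max_examples=15)
    @given(scale=st.floats(0.01, 100))
    def test_chain_is_scale_invariant(self, scale):
        sig = default_signatures("anagen")["IRS"].evaluate(DEFAULT_AXIS)
        base = preprocess_chain(sig)
        scaled = preprocess_chain(sig.copy(absorbance=scale * sig.absorbance))
        np.testing.assert_allclose(scaled.absorbance, base.absorbance, atol=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            PreprocessConfig(sg_points=6)
        with pytest.raises(ValidationError):
            PreprocessConfig(sg_points=7, sg_order=7)


class TestAtmosphericCorrection:
    def _template(self, axis):
        rng = np.random.default_rng(17)
        nu = axis.values
        t = np.zeros_like(nu)
        for c, w, a in zip(rng.uniform(1400, 1800, 8), rng.uniform(0.8, 2, 8),
                           rng.normal(0, 0.05, 8)):
            t += a * np.exp(-0.5 * ((nu - c) / w) ** 2)
        return Spectrum(axis, t, label="vapor")

    def test_exact_alpha_recovery_on_polynomial_background(self, default_axis):
        template = self._template(default_axis)
        t = np.linspace(-1, 1, len(default_axis))
        clean = 0.5 + 0.2 * t - 0.1 * t**2          # within SG detrend order
        from irhisto.spectral_data import SpectralImage
        cube = np.tile(clean + 0.3 * template.absorbance, (4, 4, 1))
        img = SpectralImage(default_axis, cube)
        out = atmospheric_correct(img, template)
        np.testing.assert_allclose(out.cube[0, 0], clean, atol=1e-6)

    def test_zero_template_rejected(self, default_axis):
        from irhisto.spectral_data import SpectralImage
        img = SpectralImage(default_axis, np.zeros((4, 4, len(default_axis))))
        with pytest.raises(ValidationError):
            atmospheric_correct(img, Spectrum(default_axis,
                                              np.zeros(len(default_axis))))

    def test_vapor_mse_reduced_by_at_least_80_percent(self):
        base = dict(shape=(64, 32), noise_sd=0.0, scatter_sigma=0.0,
                    baseline_coeffs_sd=(0, 0, 0), outlier_fraction=0.0, seed=5)
        vap = generate(PhantomConfig(vapor_amp=0.05, **base))
        clean = generate(PhantomConfig(vapor_amp=0.0, **base))
        mse0 = np.mean((vap.image.cube - clean.image.cube) ** 2)
        corrected = atmospheric_correct(vap.image, vap.vapor)
        mse1 = np.mean((corrected.cube - clean.image.cube) ** 2)
        assert mse1 <= 0.2 * mse0
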