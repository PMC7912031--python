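"""Windowed PCA, confidence ellipses, and group-separation reporting."""

import numpy as np
import pytest
from scipy.stats import chi2

from irhisto import (
    PhantomConfig,
    Spectrum,
    ValidationError,
    confidence_ellipse,
    generate,
    region_mean_spectra,
    run_pca,
    separation_report,
)
from irhisto.pca import Ellipse95, PCAResult, SpectrumSet, ellipses_overlap
from irhisto.phantom import DEFAULT_AXIS


def _spectrum_set(X, groups):
    spectra = [Spectrum(DEFAULT_AXIS, row) for row in X]
    return SpectrumSet(spectra, list(groups))


class TestRunPCA:
    def test_one_dimensional_manifold_has_unit_evr(self):
        rng = np.random.default_rng(0)
        direction = rng.random(len(DEFAULT_AXIS))
        base = rng.random(len(DEFAULT_AXIS))
        X = base + np.outer(rng.standard_normal(12), direction)
        res = run_pca(_spectrum_set(X, ["a"] * 12), None, n_components=2,
                      preprocess=False)
        assert res.evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_full_component_variance_conservation_and_reconstruction(self):
        rng = np.random.default_rng(1)
        n = 8
        X = rng.random((n, len(DEFAULT_AXIS)))
        res = run_pca(_spectrum_set(X, ["a"] * n), None, n_components=n - 1,
                      preprocess=False)
        assert res.evr.sum() == pytest.approx(1.0, abs=1e-9)
        Xc = X - X.mean(axis=0)
        recon = res.scores @ res.loadings
        assert np.linalg.norm(Xc - recon) / np.linalg.norm(Xc) < 1e-9

    def test_loadings_orthonormal_with_positive_peak_convention(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, len(DEFAULT_AXIS)))
        res = run_pca(_spectrum_set(X, ["a"] * 10), None, n_components=3,
                      preprocess=False)
        np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(3),
                                   atol=1e-9)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.random((9, len(DEFAULT_AXIS)))
        perm = rng.permutation(9)
        res = run_pca(_spectrum_set(X, ["a"] * 9), None, 3, preprocess=False)
        res_p = run_pca(_spectrum_set(X[perm], ["a"] * 9), None, 3,
                        preprocess=False)
        np.testing.assert_allclose(res_p.scores, res.scores[perm], atol=1e-8)

    def test_evr_non_increasing(self):
        rng = np.random.default_rng(4)
        X = rng.random((15, len(DEFAULT_AXIS)))
        res = run_pca(_spectrum_set(X, ["a"] * 15), None, 5, preprocess=False)
        assert np.all(np.diff(res.evr) <= 1e-12)

    def test_too_few_samples_rejected(self):
        X = np.random.default_rng(5).random((2, len(DEFAULT_AXIS)))
        with pytest.raises(ValidationError):
            run_pca(_spectrum_set(X, ["a", "a"]), None, 3, preprocess=False)


class TestRegionMeans:
    def test_zero_degradation_region_mean_equals_pure(self, clean_phantom):
        sset = region_mean_spectra(clean_phantom.image, clean_phantom.labels,
                                   ["ORS", "IRS"])
        for spec, group in zip(sset.spectra, sset.group):
            np.testing.assert_allclose(
                spec.absorbance, clean_phantom.pure[group].absorbance, atol=1e-12)

    def test_low_noise_means_within_half_percent(self):
        truth = generate(PhantomConfig(shape=(128, 64), noise_sd=0.005,
                                       scatter_sigma=0.0,
                                       baseline_coeffs_sd=(0, 0, 0),
                                       vapor_amp=0.0, outlier_fraction=0.0,
                                       seed=31))
        sset = region_mean_spectra(truth.image, truth.labels,
                                   ["ORS", "IRS", "CTS"])
        for spec, group in zip(sset.spectra, sset.group):
            pure = truth.pure[group].absorbance
            assert np.linalg.norm(spec.absorbance - pure) < 0.005 * np.linalg.norm(pure)

    def test_absent_structure_reported(self, clean_phantom):
        with pytest.raises(ValidationError, match="background"):
            region_mean_spectra(clean_phantom.image, clean_phantom.labels,
                                ["ORS", "background"])


class TestConfidenceEllipse:
    def test_isotropic_cloud_radii_match_chi2_scale(self):
        rng = np.random.default_rng(42)
        pts = rng.standard_normal((2000, 2))
        ell = confidence_ellipse(pts)
        expected = np.sqrt(chi2.ppf(0.95, 2))       # ~2.448
        assert ell.r1 == pytest.approx(expected, rel=0.05)
        assert ell.r2 == pytest.approx(expected, rel=0.05)

    def test_collinear_points_give_degenerate_vertical_ellipse(self):
        pts = np.column_stack([np.zeros(10), np.linspace(0, 1, 10)])
        ell = confidence_ellipse(pts)
        assert ell.angle == pytest.approx(np.pi / 2, abs=1e-6)
        assert ell.r2 < 1e-6

    def test_large_sample_coverage_is_95_percent(self):
        rng = np.random.default_rng(7)
        pts = rng.multivariate_normal([1, -2], [[2.0, 0.7], [0.7, 1.0]],
                                      size=10_000)
        ell = confidence_ellipse(pts)
        assert ell.contains(pts).mean() == pytest.approx(0.95, abs=0.01)


class TestSeparationReport:
    def _result(self, scores, groups):
        return PCAResult(scores=scores, loadings=np.zeros((2, 4)),
                         evr=np.array([0.9, 0.1]), window=None,
                         group=list(groups))

    def test_distant_clouds_separated(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((30, 2))
        b = rng.standard_normal((30, 2)) + 50
        rep = separation_report(self._result(np.vstack([a, b]),
                                             ["a"] * 30 + ["b"] * 30))
        assert rep[("a", "b")] == "separated"

    def test_identical_clouds_overlap(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((30, 2))
        rep = separation_report(self._result(np.vstack([a, a]),
                                             ["a"] * 30 + ["b"] * 30))
        assert rep[("a", "b")] == "overlapping"

    def test_nested_ellipses_overlap(self):
        big = Ellipse95((0, 0), 5.0, 4.0, 0.0)
        small = Ellipse95((0.5, 0.0), 0.5, 0.4, 0.3)
        assert ellipses_overlap(big, small)
        assert ellipses_overlap(small, big)
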