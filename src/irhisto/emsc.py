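"""Extended multiplicative scatter correction (EMSC) of whole images.

Each pixel spectrum is modeled as::

    s(nu) = a + sum_j c_j * t^j + b * m(nu) + residual,   t = affine(nu) in [-1, 1]

with a reference spectrum ``m`` (by default the mean of all masked-in pixels
across the images of a run, so that corrected images share one spectral
space), a polynomial baseline of order ``d`` (default 2: offset, slope,
curvature — the baseline and thickness terms), and a multiplicative factor
``b`` absorbing scatter/thickness variation.  The corrected spectrum is
``(s - a - sum c_j t^j) / b``, i.e. baseline-removed and b-normalized.

Outlier/artifact pixels are rejected by robust, scale-free thresholds:
``rms > median(rms) + k * MAD(rms)`` (default k = 5) or ``b`` outside
``[b_min, b_max]`` (defaults 0.05 and 20).  Rejected pixels are removed from
the corrected image's mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .spectral_data import (
    SpectralImage,
    Spectrum,
    SpectralWindow,
    ValidationError,
    crop_to_window,
)

__all__ = [
    "EMSCModel",
    "EMSCResult",
    "EMSCCorrector",
    "fit_emsc_pixel",
    "correct_image",
    "correct_images",
]


@dataclass
class EMSCModel:
    """Reference spectrum plus polynomial order and analysis window."""

    reference: Spectrum
    poly_order: int = 2
    window: SpectralWindow | None = None

    def __post_init__(self):
        if not 0 <= self.poly_order <= 4:
            raise ValidationError(f"poly_order must be in [0, 4], got {self.poly_order}")
        ref = self.reference
        if self.window is not None:
            ref = crop_to_window(ref, self.window)
        if np.linalg.norm(ref.absorbance) == 0:
            raise ValidationError("EMSC reference is zero on the analysis window")


@dataclass
class EMSCResult:
    """Corrected image with per-pixel fit diagnostics."""

    corrected: SpectralImage
    b_map: np.ndarray
    residual_rms: np.ndarray
    outlier_mask: np.ndarray  # True = rejected
    reference: Spectrum | None = None


class EMSCCorrector(TransformerMixin, BaseEstimator):
    """Scikit-learn style EMSC on ``(n_spectra, n_bands)`` matrices.

    Parameters
    ----------
    reference : array-like or None
        Reference spectrum ``m``.  When None, ``fit`` uses the column mean
        of the training matrix (common-reference EMSC).
    poly_order : int
        Baseline polynomial order ``d`` (0-4).
    b_min, b_max : float
        Hard acceptance bounds on the multiplicative coefficient.
    rms_mad_factor : float
        Robust threshold factor of the residual-rms rejection rule.

    Attributes
    ----------
    reference_ : ndarray
        Reference spectrum used for correction.
    design_ : ndarray
        ``(n_bands, d + 2)`` design matrix ``[1, t, .., t^d, m]``.
    b_, rms_, outliers_ : ndarray
        Per-spectrum diagnostics of the last ``transform`` call.
    """

    def __init__(self, reference=None, poly_order: int = 2, b_min: float = 0.05,
                 b_max: float = 20.0, rms_mad_factor: float = 5.0):
        self.reference = reference
        self.poly_order = poly_order
        self.b_min = b_min
        self.b_max = b_max
        self.rms_mad_factor = rms_mad_factor

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not 0 <= self.poly_order <= 4:
            raise ValidationError(f"poly_order must be in [0, 4], got {self.poly_order}")
        if self.reference is None:
            if X.shape[0] < 10:
                raise ValidationError(
                    "common-reference EMSC needs >= 10 training spectra"
                )
            ref = X.mean(axis=0)
        else:
            ref = np.asarray(self.reference, dtype=float)
        if ref.size != X.shape[1]:
            raise ValidationError("reference length differs from spectrum length")
        if np.linalg.norm(ref) == 0:
            raise ValidationError("EMSC reference has zero norm")
        t = np.linspace(-1.0, 1.0, ref.size)
        cols = [t**j for j in range(self.poly_order + 1)] + [ref]
        self.reference_ = ref
        self.design_ = np.stack(cols, axis=1)
        self._pinv = np.linalg.pinv(self.design_)
        return self

    def transform(self, X):
        """Correct spectra; rejected rows are returned as NaN.

        Stores ``b_``, ``rms_`` and ``outliers_`` for the call.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        coeffs = X @ self._pinv.T                     # (n, d + 2)
        fitted = coeffs @ self.design_.T
        resid = X - fitted
        rms = np.sqrt(np.mean(resid**2, axis=1))
        b = coeffs[:, -1]
        baseline = coeffs[:, :-1] @ self.design_[:, :-1].T
        bad = (b < self.b_min) | (b > self.b_max)
        if self.rms_mad_factor is not None:
            med = np.median(rms)
            mad = np.median(np.abs(rms - med))
            bad |= rms > med + self.rms_mad_factor * mad
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = (X - baseline) / b[:, None]
        corrected[bad] = np.nan
        self.b_ = b
        self.rms_ = rms
        self.outliers_ = bad
        self.coeffs_ = coeffs
        return corrected


def fit_emsc_pixel(s: Spectrum, model: EMSCModel):
    """Fit the EMSC model to one spectrum.

    Returns
    -------
    coeffs : ndarray
        ``[a, c_1 .. c_d, b]``.
    corrected : Spectrum or None
        b-normalized, baseline-removed spectrum; None when ``|b| < b_min``
        (the pixel is rejected and the correction undefined).
    rms : float
        Root-mean-square residual of the fit (AU).
    """
    spec = s if model.window is None else crop_to_window(s, model.window)
    ref = model.reference if model.window is None else crop_to_window(
        model.reference, model.window)
    est = EMSCCorrector(reference=ref.absorbance, poly_order=model.poly_order,
                        rms_mad_factor=None)
    est.fit(spec.absorbance[None, :])
    corrected = est.transform(spec.absorbance[None, :])
    coeffs = est.coeffs_[0]
    rms = float(est.rms_[0])
    if est.outliers_[0]:
        return coeffs, None, rms
    return coeffs, spec.copy(absorbance=corrected[0]), rms


def correct_images(images: list[SpectralImage], poly_order: int = 2,
                   reference: Spectrum | None = None,
                   window: SpectralWindow | None = None,
                   b_min: float = 0.05, b_max: float = 20.0,
                   rms_mad_factor: float = 5.0) -> list[EMSCResult]:
    """Common-reference EMSC over a set of images.

    When ``reference`` is None the reference is the mean of masked-in pixels
    pooled across *all* images, so the corrected images live in one spectral
    space and can be clustered jointly.  The outlier rule is applied over the
    pooled rms/b distributions for the same reason.
    """
    if not images:
        raise ValidationError("need at least one image")
    if window is not None:
        window = window.clamp_to(images[0].axis)
        images = [crop_to_window(img, window) for img in images]
    mats = []
    for img in images:
        X, _ = img.as_matrix()
        mats.append(X)
    pooled = np.concatenate(mats, axis=0)
    if pooled.shape[0] < 10:
        raise ValidationError("common-reference EMSC needs >= 10 masked-in pixels")
    ref_vec = None
    if reference is not None:
        ref = reference if reference.axis == images[0].axis else None
        if ref is None:
            from .spectral_data import resample_to_axis
            ref = resample_to_axis(reference, images[0].axis)
        ref_vec = ref.absorbance
    est = EMSCCorrector(reference=ref_vec, poly_order=poly_order, b_min=b_min,
                        b_max=b_max, rms_mad_factor=rms_mad_factor)
    est.fit(pooled)
    corrected_pool = est.transform(pooled)
    if np.all(est.outliers_):
        raise ValidationError("EMSC rejected every pixel")
    ref_spec = Spectrum(images[0].axis, est.reference_, label="emsc_reference")

    results = []
    start = 0
    for img, X in zip(images, mats):
        n = X.shape[0]
        sl = slice(start, start + n)
        start += n
        rr, cc = np.nonzero(img.mask)
        shape = img.shape
        b_map = np.zeros(shape)
        rms_map = np.zeros(shape)
        out_map = np.zeros(shape, dtype=bool)
        b_map[rr, cc] = est.b_[sl]
        rms_map[rr, cc] = est.rms_[sl]
        out_map[rr, cc] = est.outliers_[sl]
        cube = np.zeros_like(img.cube)
        corr = corrected_pool[sl].copy()
        corr[est.outliers_[sl]] = 0.0
        cube[rr, cc] = corr
        new_mask = img.mask & ~out_map
        corrected = SpectralImage(img.axis, cube, pixel_size=img.pixel_size,
                                  mask=new_mask, name=img.name)
        results.append(EMSCResult(corrected=corrected, b_map=b_map,
                                  residual_rms=rms_map, outlier_mask=out_map,
                                  reference=ref_spec))
    return results


def correct_image(img: SpectralImage, poly_order: int = 2,
                  reference: Spectrum | None = None, **kwargs) -> EMSCResult:
    """EMSC of a single image (dataset-mean reference unless supplied)."""
    return correct_images([img], poly_order=poly_order, reference=reference,
                          **kwargs)[0]
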