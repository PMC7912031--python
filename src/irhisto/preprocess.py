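"""Spectrum-level preprocessing: smoothing, rubber-band baseline,
vector normalization, offset correction, and atmospheric correction.

The chain follows the classical OPUS-style protocol for extracted pixel
spectra: Savitzky-Golay smoothing (7 points), elastic (rubber-band, i.e.
lower-convex-hull) baseline correction, vector normalization to unit
Euclidean norm, and offset correction to a zero minimum, applied in that
order.  Each step is available both as a function on :class:`Spectrum`
objects and as a scikit-learn transformer operating on ``(n_spectra,
n_bands)`` matrices, so chains compose with ``sklearn.pipeline.Pipeline``.

Atmospheric correction is a template-subtraction operator: a non-negative
multiple of a water-vapor/CO2 template is removed from every pixel, with the
scale fitted by least squares on the template's support bands only, so
template-free bands are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .spectral_data import (
    SpectralImage,
    Spectrum,
    ValidationError,
    resample_to_axis,
)

__all__ = [
    "PreprocessConfig",
    "SavitzkyGolaySmoother",
    "RubberBandBaseline",
    "VectorNormalizer",
    "OffsetCorrector",
    "savitzky_golay",
    "rubber_band_baseline",
    "vector_normalize",
    "offset_correct",
    "preprocess_chain",
    "atmospheric_correct",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    The smoothing window of 7 points follows the protocol; the polynomial
    order is not specified there and defaults to 3 (the common OPUS-like
    choice).  ``renormalize_after_offset`` restores unit norm after the
    offset step, which otherwise breaks it; it is off by default to keep
    the printed step order verbatim.
    """

    sg_points: int = 7
    sg_order: int = 3
    baseline_method: str = "rubber_band"
    normalize: str = "vector_unit_l2"
    offset: str = "min_to_zero"
    renormalize_after_offset: bool = False

    def __post_init__(self):
        if self.sg_points % 2 == 0 or self.sg_points < 5:
            raise ValidationError(f"sg_points must be odd and >= 5, got {self.sg_points}")
        if not 0 <= self.sg_order < self.sg_points:
            raise ValidationError("sg_order must satisfy 0 <= order < points")
        if self.baseline_method != "rubber_band":
            raise ValidationError(f"unknown baseline method {self.baseline_method!r}")
        if self.normalize != "vector_unit_l2":
            raise ValidationError(f"unknown normalization {self.normalize!r}")
        if self.offset != "min_to_zero":
            raise ValidationError(f"unknown offset method {self.offset!r}")


# ---------------------------------------------------------------------------
# matrix-level transformers (scikit-learn API)


class SavitzkyGolaySmoother(TransformerMixin, BaseEstimator):
    """Savitzky-Golay convolution smoother along the band axis.

    Window ends are handled by refitting the polynomial on the truncated
    window (``mode='interp'``), never by zero padding.
    """

    def __init__(self, points: int = 7, order: int = 3):
        self.points = points
        self.order = order

    def fit(self, X, y=None):
        self._validate(np.asarray(X, dtype=float))
        return self

    def _validate(self, X):
        if self.points % 2 == 0 or self.points < 5:
            raise ValidationError(f"points must be odd and >= 5, got {self.points}")
        if not 0 <= self.order < self.points:
            raise ValidationError("order must satisfy 0 <= order < points")
        if X.shape[-1] < self.points:
            raise ValidationError(
                f"spectrum length {X.shape[-1]} shorter than window {self.points}"
            )

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        self._validate(X)
        return savgol_filter(X, self.points, self.order, axis=-1, mode="interp")


def _lower_hull_baseline(nu_asc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of (nu, y), evaluated by linear interpolation.

    Monotone-chain construction on an ascending abscissa; O(n).
    """
    hull: list[int] = []
    for i in range(nu_asc.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # pop i1 if it lies on or above the chord (i0, i)
            cross = (nu_asc[i1] - nu_asc[i0]) * (y[i] - y[i0]) - \
                    (y[i1] - y[i0]) * (nu_asc[i] - nu_asc[i0])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(nu_asc, nu_asc[hull], y[hull])


class RubberBandBaseline(TransformerMixin, BaseEstimator):
    """Elastic (rubber-band) baseline removal: subtract the lower convex hull.

    The corrected spectrum is nonnegative everywhere and zero at both ends.
    The hull is invariant under affine reparametrizations of the abscissa,
    so band indices stand in for wavenumbers on uniform grids; pass
    ``wavenumbers`` (any orientation) for non-uniform axes.
    """

    def __init__(self, wavenumbers=None):
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[-1]
        if n < 3:
            raise ValidationError("rubber-band baseline needs >= 3 points")
        if self.wavenumbers is None:
            nu = np.arange(n, dtype=float)
            order = slice(None)
        else:
            nu = np.asarray(self.wavenumbers, dtype=float)
            order = np.argsort(nu)
            nu = nu[order]
        out = np.empty_like(X)
        for i, row in enumerate(X):
            base = np.empty(n)
            base[order] = _lower_hull_baseline(nu, row[order])
            out[i] = row - base
        return out


class VectorNormalizer(TransformerMixin, BaseEstimator):
    """Scale each spectrum to unit Euclidean norm."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        norms = np.linalg.norm(X, axis=-1, keepdims=True)
        # numerically zero spectra (e.g. a constant after baseline removal)
        if np.any(norms < 1e-10):
            raise ValidationError("cannot vector-normalize a zero-norm spectrum")
        return X / norms


class OffsetCorrector(TransformerMixin, BaseEstimator):
    """Subtract each spectrum's minimum so min(output) = 0."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X - X.min(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# spectrum-level operations


def savitzky_golay(s: Spectrum, points: int = 7, order: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing of one spectrum (see the transformer)."""
    sm = SavitzkyGolaySmoother(points=points, order=order)
    return s.copy(absorbance=sm.transform(s.absorbance[None, :])[0])


def rubber_band_baseline(s: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Split a spectrum into (corrected, baseline) via the rubber-band hull."""
    rb = RubberBandBaseline(wavenumbers=s.axis.values)
    corrected = rb.transform(s.absorbance[None, :])[0]
    baseline = s.absorbance - corrected
    return s.copy(absorbance=corrected), s.copy(absorbance=baseline, label="baseline")


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm; raises on a zero-norm spectrum."""
    return s.copy(absorbance=VectorNormalizer().transform(s.absorbance[None, :])[0])


def offset_correct(s: Spectrum) -> Spectrum:
    """Subtract the spectrum minimum."""
    return s.copy(absorbance=OffsetCorrector().transform(s.absorbance[None, :])[0])


def preprocess_chain(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Full chain: smooth -> rubber-band -> vector-normalize -> offset."""
    cfg = cfg or PreprocessConfig()
    out = savitzky_golay(s, cfg.sg_points, cfg.sg_order)
    out, _ = rubber_band_baseline(out)
    out = vector_normalize(out)
    out = offset_correct(out)
    if cfg.renormalize_after_offset:
        out = vector_normalize(out)
    return out


def preprocess_matrix(X: np.ndarray, wavenumbers: np.ndarray,
                      cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Vectorized chain over an ``(n_spectra, n_bands)`` matrix."""
    cfg = cfg or PreprocessConfig()
    X = SavitzkyGolaySmoother(cfg.sg_points, cfg.sg_order).transform(X)
    X = RubberBandBaseline(wavenumbers=wavenumbers).transform(X)
    X = VectorNormalizer().transform(X)
    X = OffsetCorrector().transform(X)
    if cfg.renormalize_after_offset:
        X = VectorNormalizer().transform(X)
    return X


# ---------------------------------------------------------------------------
# atmospheric correction


def atmospheric_correct(img: SpectralImage, vapor_template: Spectrum,
                        support_rel_threshold: float = 1e-3,
                        detrend_points: int = 7,
                        detrend_order: int = 2) -> SpectralImage:
    """Remove a non-negative multiple of a vapor template from every pixel.

    The scale ``alpha >= 0`` is fitted per pixel by least squares restricted
    to the template's support bands (|template| above ``support_rel_threshold``
    times its maximum); ``alpha * template`` is then subtracted over the full
    axis.  Bands outside the support are untouched because the template is
    zero there.

    Vapor/CO2 lines are far narrower than tissue bands, so both pixel and
    template are detrended with a short Savitzky-Golay smooth before the
    fit; the broad tissue bands cancel in the detrended residual and do not
    bias ``alpha``.  Because the smoother reproduces polynomials up to
    ``detrend_order`` exactly, the fit is exact for polynomial backgrounds.
    """
    if vapor_template.axis != img.axis:
        vapor_template = resample_to_axis(vapor_template, img.axis)
    t = vapor_template.absorbance
    tmax = np.max(np.abs(t))
    if tmax == 0:
        raise ValidationError("vapor template has zero norm")
    support = np.abs(t) > support_rel_threshold * tmax
    t_hp = t - savgol_filter(t, detrend_points, detrend_order, mode="interp")
    ts = t_hp[support]
    denom = float(ts @ ts)
    if denom == 0:
        raise ValidationError("vapor template has no narrow-line content")
    flat = img.cube.reshape(-1, img.n_bands)
    flat_hp = flat - savgol_filter(flat, detrend_points, detrend_order,
                                   axis=-1, mode="interp")
    alpha = np.maximum(0.0, flat_hp[:, support] @ ts / denom)
    corrected = flat - alpha[:, None] * t[None, :]
    return img.with_cube(corrected.reshape(img.cube.shape))
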