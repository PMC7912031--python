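"""Windowed PCA of region-mean spectra with 95% confidence ellipses.

Mean spectra are extracted from small zones of labeled structures, run
through the standard preprocessing chain, cropped to an analysis window
(full fingerprint 1800-900 cm^-1 or the sulfation window 1350-1190 cm^-1),
column-mean-centered and decomposed by SVD.  Score plots are summarized by
per-group chi-square confidence ellipses (sqrt(chi2_2(0.95)) = 2.448 times
the covariance eigen-axes), and group pairs are reported as separated or
overlapping according to whether their ellipses intersect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .preprocess import PreprocessConfig, preprocess_matrix
from .spectral_data import (
    LabelMap,
    SpectralImage,
    SpectralWindow,
    Spectrum,
    ValidationError,
    WavenumberAxis,
)

__all__ = [
    "SpectrumSet",
    "PCAResult",
    "Ellipse95",
    "WindowedPCA",
    "region_mean_spectra",
    "run_pca",
    "confidence_ellipse",
    "ellipses_overlap",
    "separation_report",
]


@dataclass
class SpectrumSet:
    """Spectra on a common axis with one categorical group label each."""

    spectra: list[Spectrum]
    group: list[str]

    def __post_init__(self):
        if len(self.spectra) != len(self.group):
            raise ValidationError("spectra and group lengths differ")
        if self.spectra:
            axis = self.spectra[0].axis
            if any(s.axis != axis for s in self.spectra[1:]):
                raise ValidationError("spectra must share a common axis")

    @property
    def axis(self) -> WavenumberAxis:
        return self.spectra[0].axis

    def to_matrix(self) -> np.ndarray:
        return np.stack([s.absorbance for s in self.spectra])

    def extend(self, other: "SpectrumSet") -> "SpectrumSet":
        return SpectrumSet(self.spectra + other.spectra, self.group + other.group)


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions for one window."""

    scores: np.ndarray          # (n_samples, n_components)
    loadings: np.ndarray        # (n_components, n_bands), rows orthonormal
    evr: np.ndarray             # explained-variance fractions, descending
    window: SpectralWindow | None
    group: list[str]
    axis: WavenumberAxis | None = None


@dataclass
class Ellipse95:
    """Confidence ellipse in 2-D score space."""

    center: tuple[float, float]
    r1: float                   # major semi-axis
    r2: float                   # minor semi-axis
    angle: float                # radians, major axis vs x

    def boundary(self, n: int = 360) -> np.ndarray:
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        pts = np.stack([self.r1 * np.cos(t), self.r2 * np.sin(t)])
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return (rot @ pts).T + np.asarray(self.center)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        u = pts @ np.array([c, s])
        v = pts @ np.array([-s, c])
        return (u / self.r1) ** 2 + (v / self.r2) ** 2 <= 1.0


class WindowedPCA(TransformerMixin, BaseEstimator):
    """PCA restricted to a wavenumber window, scikit-learn style.

    Fits on an ``(n_samples, n_bands)`` matrix whose columns follow
    ``wavenumbers``; optionally applies the standard preprocessing chain to
    each (mean) spectrum after cropping.  A deterministic sign convention is
    imposed: the largest-magnitude element of every loading is positive.

    Attributes (fitted): ``loadings_``, ``evr_``, ``mean_``, ``keep_``.
    """

    def __init__(self, wavenumbers=None, window: SpectralWindow | None = None,
                 n_components: int = 2, preprocess: bool = True,
                 preprocess_config: PreprocessConfig | None = None):
        self.wavenumbers = wavenumbers
        self.window = window
        self.n_components = n_components
        self.preprocess = preprocess
        self.preprocess_config = preprocess_config

    def _prepare(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        nu = None if self.wavenumbers is None else np.asarray(self.wavenumbers, float)
        if self.window is not None:
            if nu is None:
                raise ValidationError("window cropping requires wavenumbers")
            keep = self.window.member_mask(WavenumberAxis(nu))
            if not keep.any():
                raise ValidationError("window does not intersect the axis")
            X = X[:, keep]
            nu = nu[keep]
        else:
            keep = np.ones(X.shape[1], dtype=bool)
        if self.preprocess:
            X = preprocess_matrix(X, nu if nu is not None else np.arange(X.shape[1]),
                                  self.preprocess_config)
        return X, nu, keep

    def fit(self, X, y=None):
        Xw, nu, keep = self._prepare(X)
        if self.n_components < 2:
            raise ValidationError("n_components must be >= 2")
        if Xw.shape[0] < self.n_components:
            raise ValidationError(
                f"{Xw.shape[0]} samples < {self.n_components} components"
            )
        pca = PCA(n_components=min(self.n_components, Xw.shape[1]),
                  svd_solver="full")
        pca.fit(Xw)
        loadings = pca.components_.copy()
        flip = np.sign(loadings[np.arange(loadings.shape[0]),
                                np.argmax(np.abs(loadings), axis=1)])
        loadings *= flip[:, None]
        self.loadings_ = loadings
        self.evr_ = pca.explained_variance_ratio_.copy()
        self.mean_ = pca.mean_.copy()
        self.keep_ = keep
        self.nu_ = nu
        return self

    def transform(self, X):
        Xw, _, _ = self._prepare(X)
        return (Xw - self.mean_) @ self.loadings_.T


def region_mean_spectra(img: SpectralImage, labels: LabelMap,
                        structures: list[str], group_by: str = "structure",
                        phase: str | None = None, zone_size: int | None = None,
                        n_zones: int = 1, rng=None) -> SpectrumSet:
    """Mean spectra of labeled regions, optionally from random small zones.

    With ``zone_size=None`` one mean over the whole masked-in region is
    returned per structure.  With a ``zone_size`` (square half-width in
    pixels), ``n_zones`` means over randomly centered small zones inside
    each region are returned, emulating operator-picked regions of interest.
    Groups are structure names, or the image's phase tag when
    ``group_by='phase'``.
    """
    if labels.shape != img.shape:
        raise ValidationError(
            f"label map shape {labels.shape} != image shape {img.shape}"
        )
    rng = np.random.default_rng(rng)
    spectra: list[Spectrum] = []
    groups: list[str] = []
    missing: list[str] = []
    for structure in structures:
        region = labels.mask_of(structure) & img.mask
        n_px = int(region.sum())
        if n_px == 0:
            missing.append(structure)
            continue
        if n_px < 5:
            raise ValidationError(
                f"structure {structure!r} has only {n_px} masked-in pixels (< 5)"
            )
        rr, cc = np.nonzero(region)
        picks = []
        if zone_size is None:
            picks.append(np.arange(n_px))
        else:
            for _ in range(n_zones):
                j = rng.integers(n_px)
                r0, c0 = rr[j], cc[j]
                inside = (np.abs(rr - r0) <= zone_size) & (np.abs(cc - c0) <= zone_size)
                picks.append(np.nonzero(inside)[0])
        for idx in picks:
            mean = img.cube[rr[idx], cc[idx], :].mean(axis=0)
            spectra.append(Spectrum(img.axis, mean, label=structure))
            groups.append(structure if group_by == "structure" else (phase or ""))
    if missing:
        raise ValidationError(f"structures absent from label map: {missing}")
    return SpectrumSet(spectra, groups)


def run_pca(spectrum_set: SpectrumSet, window: SpectralWindow | None,
            n_components: int = 2, preprocess: bool = True) -> PCAResult:
    """Windowed PCA of a spectrum set (crop, preprocess, center, SVD)."""
    est = WindowedPCA(wavenumbers=spectrum_set.axis.values, window=window,
                      n_components=n_components, preprocess=preprocess)
    X = spectrum_set.to_matrix()
    est.fit(X)
    scores = est.transform(X)
    axis = WavenumberAxis(est.nu_) if est.nu_ is not None else None
    return PCAResult(scores=scores, loadings=est.loadings_, evr=est.evr_,
                     window=window, group=list(spectrum_set.group), axis=axis)


def confidence_ellipse(scores2d: np.ndarray, level: float = 0.95) -> Ellipse95:
    """Chi-square covariance ellipse of a 2-D score cloud.

    Semi-axes are ``sqrt(chi2_2(level) * eigenvalue)`` of the sample
    covariance; at the default level the scale factor is sqrt(5.991).
    A singular covariance yields a degenerate ellipse with a tiny minor axis.
    """
    pts = np.atleast_2d(np.asarray(scores2d, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValidationError("confidence ellipse needs an (n >= 3, 2) score array")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    scale = chi2.ppf(level, df=2)
    evals = np.maximum(evals, 0.0)
    r_minor, r_major = np.sqrt(scale * evals)
    major = evecs[:, 1]
    angle = float(np.arctan2(major[1], major[0]))
    if angle < 0:  # direction is sign-ambiguous; report in [0, pi)
        angle += np.pi
    eps = 1e-12 * max(r_major, 1.0)
    return Ellipse95(center=(float(center[0]), float(center[1])),
                     r1=float(max(r_major, eps)), r2=float(max(r_minor, eps)),
                     angle=angle)


def ellipses_overlap(e1: Ellipse95, e2: Ellipse95, n_boundary: int = 360) -> bool:
    """Intersection test by boundary sampling and point-in-ellipse checks."""
    if e2.contains(np.array([e1.center]))[0] or e1.contains(np.array([e2.center]))[0]:
        return True
    return bool(e2.contains(e1.boundary(n_boundary)).any()
                or e1.contains(e2.boundary(n_boundary)).any())


def separation_report(res: PCAResult, pcs: tuple[int, int] = (1, 2),
                      level: float = 0.95) -> dict[tuple[str, str], str]:
    """Label every group pair 'separated' or 'overlapping' by ellipse test.

    ``pcs`` are 1-based principal-component indices.
    """
    i, j = pcs
    if max(i, j) > res.scores.shape[1]:
        raise ValidationError(f"PC pair {pcs} exceeds {res.scores.shape[1]} components")
    pts = res.scores[:, [i - 1, j - 1]]
    groups = np.asarray(res.group)
    ellipses = {}
    for g in dict.fromkeys(res.group):  # preserve first-seen order
        ellipses[g] = confidence_ellipse(pts[groups == g], level=level)
    names = list(ellipses)
    report = {}
    for a_idx in range(len(names)):
        for b_idx in range(a_idx + 1, len(names)):
            a, b = names[a_idx], names[b_idx]
            overlap = ellipses_overlap(ellipses[a], ellipses[b])
            report[(a, b)] = "overlapping" if overlap else "separated"
    return report
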