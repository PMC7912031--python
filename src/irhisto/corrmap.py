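"""Pixel-wise Pearson correlation maps against reference spectra.

Each masked-in pixel spectrum is correlated with a reference spectrum of a
standard compound (heparan sulfate, glypican-1, hyaluronic acid, OCT) over a
wavenumber window; the per-pixel Pearson r is clipped to the displayed
[0, 1] scale (negative correlations map to 0) unless signed values are
requested for diagnostics.  Pearson r is invariant to per-pixel gain and
offset, which makes the maps robust to the thickness/scatter effects EMSC
normalizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .spectral_data import (
    LabelMap,
    SpectralImage,
    SpectralWindow,
    Spectrum,
    ValidationError,
    crop_to_window,
    resample_to_axis,
)

__all__ = ["CorrelationMap", "correlate_image", "structure_profile", "render_map"]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMap:
    """Per-pixel correlation against one reference spectrum."""

    values: np.ndarray              # (rows, cols), 0 on masked-out pixels
    reference_label: str
    window: SpectralWindow | None
    signed: bool = False


def correlate_image(img: SpectralImage, ref: Spectrum,
                    window: SpectralWindow | None = None,
                    signed: bool = False) -> CorrelationMap:
    """Pearson correlation of every masked-in pixel with a reference.

    The reference is resampled to the image axis if needed.  Pixels (or a
    reference) with zero variance over the window get value 0; their count
    is logged.  Masked-out pixels are 0.
    """
    if ref.axis != img.axis:
        ref = resample_to_axis(ref, img.axis)
    if window is not None:
        window = window.clamp_to(img.axis)
        img_w = crop_to_window(img, window)
        ref_w = crop_to_window(ref, window)
    else:
        img_w, ref_w = img, ref
    if len(ref_w) < 8:
        raise ValidationError(f"window keeps only {len(ref_w)} bands (< 8)")
    r_vec = ref_w.absorbance - ref_w.absorbance.mean()
    r_norm = np.linalg.norm(r_vec)
    values = np.zeros(img.shape)
    X, idx = img_w.as_matrix()
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(Xc, axis=1)
    degenerate = (x_norm == 0) | (r_norm == 0)
    n_deg = int(degenerate.sum()) if r_norm > 0 else X.shape[0]
    if n_deg:
        logger.info("correlate_image: %d zero-variance pixel(s) set to 0", n_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ r_vec) / (x_norm * r_norm)
    r[degenerate] = 0.0
    if not signed:
        r = np.clip(r, 0.0, 1.0)
    else:
        r = np.clip(r, -1.0, 1.0)
    values[idx[:, 0], idx[:, 1]] = r
    return CorrelationMap(values=values, reference_label=ref.label,
                          window=window, signed=signed)


def structure_profile(cmap: CorrelationMap, labels: LabelMap,
                      mask: np.ndarray | None = None
                      ) -> dict[str, tuple[float, float]]:
    """Per-structure (mean, sd) of correlation over masked-in pixels."""
    if labels.shape != cmap.values.shape:
        raise ValidationError(
            f"label shape {labels.shape} != map shape {cmap.values.shape}"
        )
    if mask is None:
        mask = np.ones(cmap.values.shape, dtype=bool)
    out = {}
    for name in dict.fromkeys(labels.legend.values()):
        sel = labels.mask_of(name) & mask
        if not sel.any():
            continue
        vals = cmap.values[sel]
        out[name] = (float(vals.mean()), float(vals.std()))
    return out


def render_map(cmap: CorrelationMap, path) -> None:
    """Write the map as a grayscale PNG (0 -> black, 1 -> white, linear)."""
    scaled = np.clip(cmap.values, 0.0, 1.0) * 255.0
    Image.fromarray(np.round(scaled).astype(np.uint8), mode="L").save(path)
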