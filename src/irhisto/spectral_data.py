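"""Core data model for mid-infrared spectra and hyperspectral image cubes.

The canonical axis orientation throughout the package is *descending*
wavenumbers (e.g. 1800 -> 900 cm^-1), matching the convention of FTIR
instruments and spectral plots.  Readers accept either orientation and flip
to descending on ingest; every downstream module may assume it.

Spectral windows are closed intervals ``[lo, hi]`` in cm^-1; band membership
is inclusive at both edges.  Spatial coordinates are ``(row, col)``, 0-based,
row 0 at the top of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "STRUCTURES",
    "SpectralDataError",
    "FormatError",
    "ValidationError",
    "WindowError",
    "WavenumberAxis",
    "SpectralWindow",
    "Spectrum",
    "SpectralImage",
    "LabelMap",
    "crop_to_window",
    "resample_to_axis",
]

#: Closed vocabulary of hair-follicle structure names used by label maps.
#: Order fixes the deterministic tie-break rule for cluster annotation.
STRUCTURES = (
    "CTS",
    "germinative_matrix",
    "differentiation_zone",
    "IRS",
    "ORS",
    "hair_shaft",
    "OCT",
    "background",
)


class SpectralDataError(ValueError):
    """Base class for data-model violations."""


class FormatError(SpectralDataError):
    """A file did not conform to its declared dialect."""


class ValidationError(SpectralDataError):
    """An object violated a structural invariant."""


class WindowError(SpectralDataError):
    """A spectral window did not intersect the axis it was applied to."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotonic wavenumber axis in cm^-1, stored descending.

    Parameters
    ----------
    values
        Wavenumber positions.  Must be strictly monotonic, all positive and
        of length >= 8.  Ascending input is accepted and flipped.
    """

    values: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.values, "wavenumber axis")
        if arr.size < 8:
            raise ValidationError(f"axis needs >= 8 points, got {arr.size}")
        if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
            raise ValidationError("axis values must be finite and > 0")
        d = np.diff(arr)
        if np.all(d > 0):
            arr = arr[::-1]
        elif not np.all(d < 0):
            raise ValidationError("axis must be strictly monotonic")
        object.__setattr__(self, "values", np.ascontiguousarray(arr))
        self.values.setflags(write=False)

    @classmethod
    def from_range(cls, hi: float, lo: float, step: float) -> "WavenumberAxis":
        """Uniform descending axis from ``hi`` down to ``lo`` (inclusive)."""
        if not (hi > lo > 0 and step > 0):
            raise ValidationError("need hi > lo > 0 and step > 0")
        n = int(round((hi - lo) / step)) + 1
        return cls(hi - step * np.arange(n))

    @property
    def step(self) -> float:
        """Nominal spacing in cm^-1 (median absolute difference)."""
        return float(np.median(np.abs(np.diff(self.values))))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash(self.values.tobytes())


@dataclass(frozen=True)
class SpectralWindow:
    """Closed wavenumber interval ``[lo, hi]`` in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(f"window needs lo < hi, got [{self.lo}, {self.hi}]")

    def member_mask(self, axis: WavenumberAxis) -> np.ndarray:
        """Boolean mask of axis bands inside the closed window."""
        v = axis.values
        return (v >= self.lo) & (v <= self.hi)

    def clamp_to(self, axis: WavenumberAxis) -> "SpectralWindow":
        """Intersect the window with the axis extent (raises if empty)."""
        lo = max(self.lo, float(axis.values.min()))
        hi = min(self.hi, float(axis.values.max()))
        if lo >= hi:
            raise WindowError(
                f"window [{self.lo}, {self.hi}] does not intersect axis extent "
                f"[{axis.values.min()}, {axis.values.max()}]"
            )
        return SpectralWindow(lo, hi)


# Fingerprint and sulfation analysis windows used throughout.
FINGERPRINT_WINDOW = SpectralWindow(900.0, 1800.0)
SULFATION_WINDOW = SpectralWindow(1190.0, 1350.0)


@dataclass
class Spectrum:
    """One wavenumber axis plus one absorbance vector (AU)."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self):
        arr = _as_float_array(self.absorbance, "absorbance")
        if arr.size != len(self.axis):
            raise ValidationError(
                f"absorbance length {arr.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("absorbance contains non-finite values")
        self.absorbance = arr

    def __len__(self) -> int:
        return len(self.axis)

    @classmethod
    def from_arrays(cls, wavenumbers, absorbance, label: str = "") -> "Spectrum":
        """Build a spectrum from raw arrays, reordering jointly to descending."""
        nu = _as_float_array(wavenumbers, "wavenumbers")
        ab = _as_float_array(absorbance, "absorbance")
        if nu.size != ab.size:
            raise ValidationError("wavenumber and absorbance lengths differ")
        if nu.size >= 2 and nu[0] < nu[-1]:
            nu, ab = nu[::-1], ab[::-1]
        return cls(WavenumberAxis(nu), np.array(ab), label=label)

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.absorbance = np.array(out.absorbance, dtype=float)
        return out


@dataclass
class SpectralImage:
    """Hyperspectral cube ``rows x cols x n_wavenumbers`` in absorbance units.

    ``mask`` marks analyzable pixels (True = in).  Masked-in pixels must be
    finite; masked-out pixels are ignored everywhere.
    """

    axis: WavenumberAxis
    cube: np.ndarray
    pixel_size: float = 6.25
    mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        cube = np.asarray(self.cube, dtype=float)
        if cube.ndim != 3:
            raise ValidationError(f"cube must be 3-D, got shape {cube.shape}")
        if cube.shape[0] < 4 or cube.shape[1] < 4:
            raise ValidationError(f"cube spatial dims must be >= 4x4, got {cube.shape[:2]}")
        if cube.shape[2] != len(self.axis):
            raise ValidationError(
                f"cube has {cube.shape[2]} bands but axis has {len(self.axis)}"
            )
        if self.mask is None:
            mask = np.ones(cube.shape[:2], dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != cube.shape[:2]:
                raise ValidationError(
                    f"mask shape {mask.shape} != spatial shape {cube.shape[:2]}"
                )
        if not np.all(np.isfinite(cube[mask])):
            raise ValidationError("masked-in pixels contain non-finite values")
        self.cube = cube
        self.mask = mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.cube.shape[2]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.cube[row, col].copy(), label=f"({row},{col})")

    def as_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Masked-in pixels as an ``(n_pixels, n_bands)`` matrix.

        Returns
        -------
        X : ndarray
            Spectra of masked-in pixels, row-major pixel order.
        index : ndarray
            ``(n_pixels, 2)`` array of (row, col) coordinates.
        """
        rr, cc = np.nonzero(self.mask)
        return self.cube[rr, cc, :], np.column_stack([rr, cc])

    def with_cube(self, cube: np.ndarray, **changes) -> "SpectralImage":
        kw = dict(axis=self.axis, cube=cube, pixel_size=self.pixel_size,
                  mask=self.mask.copy(), name=self.name)
        kw.update(changes)
        return SpectralImage(**kw)


@dataclass
class LabelMap:
    """Integer structure-label image with a legend into the closed vocabulary."""

    labels: np.ndarray
    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("labels must be a 2-D integer array")
        legend = dict(self.legend)
        present = set(np.unique(labels).tolist())
        missing = present - set(legend)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} missing from legend")
        bad = [name for name in legend.values() if name not in STRUCTURES]
        if bad:
            raise ValidationError(f"legend names outside vocabulary: {bad}")
        self.labels = labels
        self.legend = legend

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask_of(self, structure: str) -> np.ndarray:
        """Boolean mask of pixels labeled with ``structure``."""
        ids = [i for i, name in self.legend.items() if name == structure]
        return np.isin(self.labels, ids)

    def structure_names(self) -> np.ndarray:
        """Per-pixel structure-name array (object dtype)."""
        lut = {i: name for i, name in self.legend.items()}
        out = np.empty(self.labels.shape, dtype=object)
        for i, name in lut.items():
            out[self.labels == i] = name
        return out


def crop_to_window(obj, window: SpectralWindow):
    """Restrict a :class:`Spectrum` or :class:`SpectralImage` to a window.

    Bands with ``lo <= nu <= hi`` are retained in their original order.
    Raises :class:`WindowError` when the intersection is empty.
    """
    axis = obj.axis
    keep = window.member_mask(axis)
    if not keep.any():
        raise WindowError(
            f"window [{window.lo}, {window.hi}] has empty intersection with axis "
            f"extent [{axis.values.min()}, {axis.values.max()}]"
        )
    new_axis = WavenumberAxis(axis.values[keep])
    if isinstance(obj, Spectrum):
        return Spectrum(new_axis, obj.absorbance[keep], label=obj.label)
    if isinstance(obj, SpectralImage):
        return SpectralImage(new_axis, obj.cube[:, :, keep], pixel_size=obj.pixel_size,
                             mask=obj.mask.copy(), name=obj.name)
    raise TypeError(f"cannot crop object of type {type(obj).__name__}")


def resample_to_axis(s: Spectrum, target: WavenumberAxis) -> Spectrum:
    """Linear interpolation of a spectrum onto ``target`` wavenumbers.

    Extrapolation is refused: the target extent must lie within the source
    extent.  Exact where target points coincide with source points.
    """
    src = s.axis.values
    tgt = target.values
    if tgt.min() < src.min() - 1e-9 or tgt.max() > src.max() + 1e-9:
        raise WindowError(
            f"target extent [{tgt.min()}, {tgt.max()}] exceeds source extent "
            f"[{src.min()}, {src.max()}]; extrapolation is not supported"
        )
    # np.interp needs ascending abscissa; both axes are stored descending.
    vals = np.interp(tgt[::-1], src[::-1], s.absorbance[::-1])[::-1]
    return Spectrum(target, vals, label=s.label)
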