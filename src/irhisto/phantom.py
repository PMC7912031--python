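"""Synthetic hair-follicle phantom generator with ground-truth labels.

No instrument data accompanies the study this package operationalizes, so
every analysis stage is exercised on phantoms: hyperspectral images of a
longitudinal hair-follicle section embedded in OCT compound, with known
per-structure spectral signatures and known instrument-like degradations
(multiplicative scatter/thickness factors, polynomial baselines, additive
noise, a water-vapor interference comb, and outlier pixels).

Band positions and heights beyond the sulfation anchor at 1248 cm^-1 are
synthetic design values consistent with generic protein/carbohydrate mid-IR
spectra; they are config-overridable and never claimed to match any measured
tissue spectrum.  The follicle-phase dependence is confined to the
heparan-sulfate-like band heights of the outer and inner root sheaths: HS is
concentrated in the ORS during anagen and extends into the IRS during
catagen and telogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_data import (
    STRUCTURES,
    LabelMap,
    SpectralImage,
    Spectrum,
    ValidationError,
    WavenumberAxis,
)

__all__ = [
    "PHASES",
    "BandSpec",
    "StructureSignature",
    "PhantomConfig",
    "PhantomTruth",
    "default_signatures",
    "render_template",
    "generate",
    "reference_spectra",
]

PHASES = ("anagen", "catagen", "telogen")

#: Default phantom axis: fingerprint region, 4 cm^-1 spacing (226 bands).
DEFAULT_AXIS = WavenumberAxis.from_range(1800.0, 900.0, 4.0)

#: Label ids used by the follicle template (paper-style numbering 1..5).
TEMPLATE_LEGEND = {
    0: "OCT",
    1: "germinative_matrix",
    2: "differentiation_zone",
    3: "IRS",
    4: "ORS",
    5: "hair_shaft",
    6: "CTS",
}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (cm^-1), sigma (cm^-1), peak (AU)."""

    center: float
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValidationError(f"band width must be > 0, got {self.width}")
        if self.height < 0:
            raise ValidationError(f"band height must be >= 0, got {self.height}")

    def evaluate(self, nu: np.ndarray) -> np.ndarray:
        return self.height * np.exp(-0.5 * ((nu - self.center) / self.width) ** 2)


@dataclass
class StructureSignature:
    """Pure (noise-free) signature of one structure as a sum of Gaussians."""

    structure: str
    bands: list[BandSpec]

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValidationError(f"unknown structure {self.structure!r}")
        if not self.bands:
            raise ValidationError("signature needs at least one band")

    def evaluate(self, axis: WavenumberAxis) -> Spectrum:
        nu = axis.values
        total = np.zeros_like(nu)
        for band in self.bands:
            total += band.evaluate(nu)
        return Spectrum(axis, total, label=self.structure)


# Shared protein backbone of every tissue structure: amide I, amide II and
# amide III, scaled per structure by its protein density.  OCT (a
# water-soluble glycol/resin embedding medium) has no amide bands, only
# broad C-O/C-C features.
_AMIDE_BANDS = ((1655.0, 28.0, 1.00),   # amide I
                (1545.0, 22.0, 0.55),   # amide II
                (1310.0, 14.0, 0.22))   # amide III

_CARB_CENTERS = ((1080.0, 18.0), (1030.0, 16.0))  # C-O / C-O-C stretches
_SULF_BAND = (1248.0, 10.0)  # anti-symmetric S=O stretch of sulfated GAGs

# (protein scale, carb 1080, carb 1030, sulfation) peak heights per
# structure.  The germinative matrix and the differentiation zone are
# identical apart from a small sulfation offset: distinguishable in the
# 1350-1190 window but nearly degenerate over the full fingerprint region,
# mirroring the bulb-level overlap seen in real follicle sections.
_TISSUE_HEIGHTS = {
    "CTS":                  (0.85, 0.12, 0.28, 0.10),
    "germinative_matrix":   (1.05, 0.20, 0.16, 0.15),
    "differentiation_zone": (1.05, 0.20, 0.16, 0.12),
    "IRS":                  (0.90, 0.45, 0.40, 0.04),
    "ORS":                  (1.00, 0.30, 0.28, 0.22),
    "hair_shaft":           (1.20, 0.10, 0.06, 0.08),
}

# Shape (not just scale) contrasts against the epithelial backbone:
# collagen-like amide III' / CH2-wag bands for the connective tissue sheath,
# and a cysteic-acid-like band for the keratin-dense hair shaft.
_EXTRA_BANDS = {
    "CTS": (BandSpec(1204.0, 12.0, 0.15), BandSpec(1338.0, 12.0, 0.10)),
    "hair_shaft": (BandSpec(1175.0, 12.0, 0.18),),
}

# Phase overrides of the HS-like sulfation height only (ORS and IRS): HS
# appears in the IRS, and slightly more strongly in the ORS, once the
# follicle leaves anagen.  The shifts are kept below the between-structure
# contrasts so one common clustering still groups structures across phases.
_PHASE_SULFATION = {
    "anagen": {},
    "catagen": {"ORS": 0.26, "IRS": 0.09},
    "telogen": {"ORS": 0.26, "IRS": 0.09},
}

_OCT_BANDS = [BandSpec(1090.0, 30.0, 0.48), BandSpec(952.0, 28.0, 0.33)]


def default_signatures(phase: str = "anagen") -> dict[str, StructureSignature]:
    """Per-structure pure signatures for one hair-growth phase.

    All six tissue structures share the protein amide bands; sulfation at
    1248 cm^-1 and carbohydrate bands at 1080/1030 cm^-1 vary by structure.
    Only the HS-like sulfation heights of the ORS and IRS change with phase.
    """
    if phase not in PHASES:
        raise ValidationError(f"unknown phase {phase!r}; expected one of {PHASES}")
    sulf_override = _PHASE_SULFATION[phase]
    out: dict[str, StructureSignature] = {}
    for structure, (protein, h1080, h1030, h_sulf) in _TISSUE_HEIGHTS.items():
        h_sulf = sulf_override.get(structure, h_sulf)
        bands = [BandSpec(c, w, protein * h) for c, w, h in _AMIDE_BANDS]
        bands.append(BandSpec(*_CARB_CENTERS[0], h1080))
        bands.append(BandSpec(*_CARB_CENTERS[1], h1030))
        if h_sulf > 0:
            bands.append(BandSpec(*_SULF_BAND, h_sulf))
        bands.extend(_EXTRA_BANDS.get(structure, ()))
        out[structure] = StructureSignature(structure, bands)
    out["OCT"] = StructureSignature("OCT", list(_OCT_BANDS))
    return out


@dataclass
class PhantomConfig:
    """Generator configuration.

    Degradation defaults emulate a well-purged transmission measurement of a
    cryosection: ~15% log-scale thickness/scatter spread, mild curved
    baselines, 0.01 AU detector noise, a faint residual water-vapor comb in
    the 1800-1400 cm^-1 region, and 1% artifact pixels.
    """

    axis: WavenumberAxis = field(default_factory=lambda: DEFAULT_AXIS)
    shape: tuple[int, int] = (128, 64)
    template: str = "follicle_longitudinal"
    phase: str = "anagen"
    signatures: dict[str, StructureSignature] | None = None
    scatter_sigma: float = 0.15
    baseline_coeffs_sd: tuple[float, float, float] = (0.02, 0.01, 0.005)
    noise_sd: float = 0.01
    vapor_line_density: float = 2.0     # lines per 100 cm^-1 in 1800-1400
    vapor_amp: float = 0.01
    outlier_fraction: float = 0.01
    seed: int = 0
    pixel_size: float = 6.25

    def __post_init__(self):
        if self.template != "follicle_longitudinal":
            raise ValidationError(f"unknown template {self.template!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if min(self.shape) < 16:
            raise ValidationError(f"shape must be >= 16x16, got {self.shape}")
        if not 0 <= self.outlier_fraction < 0.2:
            raise ValidationError("outlier_fraction must be in [0, 0.2)")
        for name in ("scatter_sigma", "noise_sd", "vapor_amp", "vapor_line_density"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.baseline_coeffs_sd):
            raise ValidationError("baseline_coeffs_sd must be >= 0")


@dataclass
class PhantomTruth:
    """A generated phantom with its full ground truth."""

    image: SpectralImage
    labels: LabelMap
    pure: dict[str, Spectrum]
    applied_b: np.ndarray
    outlier_mask: np.ndarray
    vapor: Spectrum | None = None


def render_template(shape: tuple[int, int],
                    template: str = "follicle_longitudinal") -> LabelMap:
    """Deterministic structure layout of a longitudinal follicle section.

    OCT fills the background.  A vertically elongated follicle runs down the
    image center with concentric hair-shaft / IRS / ORS / CTS columns; the
    bulb at the bottom holds the germinative matrix (lower half, around the
    papilla base) under the differentiation zone.
    """
    if template != "follicle_longitudinal":
        raise ValidationError(f"unknown template {template!r}")
    rows, cols = shape
    if rows < 16 or cols < 16:
        raise ValidationError(f"template needs shape >= 16x16, got {shape}")
    labels = np.zeros(shape, dtype=int)  # 0 = OCT
    cx = (cols - 1) / 2.0
    col_scale = cols / 64.0
    half_widths = {  # nested concentric half-widths, outermost first
        "CTS": 21.0 * col_scale,
        "ORS": 13.0 * col_scale,
        "IRS": 8.0 * col_scale,
        "hair_shaft": 4.0 * col_scale,
    }
    name_to_id = {name: i for i, name in TEMPLATE_LEGEND.items()}
    bulb_r0 = 0.80 * rows
    bulb_a = 0.14 * rows   # semi-axis along rows
    bulb_b = 0.24 * cols   # semi-axis along cols
    col_top = int(round(bulb_r0 - bulb_a))  # columnar part ends at bulb top
    rr, cc = np.mgrid[0:rows, 0:cols]
    dc = np.abs(cc - cx)
    columnar = rr < col_top
    for name in ("CTS", "ORS", "IRS", "hair_shaft"):
        labels[columnar & (dc <= half_widths[name])] = name_to_id[name]
    in_bulb = ((rr - bulb_r0) / bulb_a) ** 2 + ((cc - cx) / bulb_b) ** 2 <= 1.0
    labels[in_bulb & (rr <= bulb_r0)] = name_to_id["differentiation_zone"]
    labels[in_bulb & (rr > bulb_r0)] = name_to_id["germinative_matrix"]
    lm = LabelMap(labels, dict(TEMPLATE_LEGEND))
    counts = {name: int(lm.mask_of(name).sum()) for name in TEMPLATE_LEGEND.values()}
    thin = [n for n, c in counts.items() if c < 0.02 * rows * cols]
    if thin:
        raise ValidationError(f"template structures below 2% coverage: {thin}")
    return lm


def generate(config: PhantomConfig) -> PhantomTruth:
    """Generate one degraded phantom cube with full ground truth.

    Per pixel p with structure s::

        cube[p] = b_p * pure_s + baseline_p(nu) + vapor(nu) + eps

    with ``b_p`` log-normal (median 1), ``baseline_p`` a random polynomial of
    order <= 2 on the affinely rescaled axis, ``vapor`` a per-image comb of
    narrow lines in 1800-1400 cm^-1, and ``eps`` i.i.d. Gaussian noise.  A
    fraction of pixels is replaced by artifact spectra (scale spikes with
    heavy shape noise, or pure noise) and recorded in ``outlier_mask``.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.axis
    nu = axis.values
    labels = render_template(config.shape, config.template)
    signatures = config.signatures or default_signatures(config.phase)
    pure = {name: sig.evaluate(axis) for name, sig in signatures.items()}
    for name, spec in pure.items():
        if np.any(spec.absorbance < 0):
            raise ValidationError(f"pure signature of {name} is negative")

    rows, cols = config.shape
    cube = np.zeros((rows, cols, len(axis)))
    names = labels.structure_names()
    for name in np.unique(names):
        cube[names == name] = pure[str(name)].absorbance

    b = np.exp(rng.normal(0.0, config.scatter_sigma, size=(rows, cols)))
    cube *= b[..., None]

    nu_t = 2.0 * (nu - nu.min()) / (nu.max() - nu.min()) - 1.0
    design = np.stack([np.ones_like(nu_t), nu_t, nu_t**2], axis=-1)
    coeffs = rng.normal(0.0, 1.0, size=(rows, cols, 3)) * np.array(config.baseline_coeffs_sd)
    cube += coeffs @ design.T

    vapor_spec = None
    n_lines = int(round(config.vapor_line_density * 4.0))  # comb in 1800-1400
    if config.vapor_amp > 0 and n_lines > 0:
        centers = rng.uniform(1400.0, 1800.0, size=n_lines)
        widths = rng.uniform(0.8, 2.0, size=n_lines)
        amps = rng.normal(0.0, 1.0, size=n_lines) * config.vapor_amp
        vapor = np.zeros_like(nu)
        for c, w, a in zip(centers, widths, amps):
            vapor += a * np.exp(-0.5 * ((nu - c) / w) ** 2)
        cube += vapor
        vapor_spec = Spectrum(axis, vapor, label="water_vapor")

    if config.noise_sd > 0:
        cube += rng.normal(0.0, config.noise_sd, size=cube.shape)

    outlier_mask = np.zeros((rows, cols), dtype=bool)
    n_out = int(round(config.outlier_fraction * rows * cols))
    if n_out > 0:
        flat = rng.choice(rows * cols, size=n_out, replace=False)
        orr, occ = np.unravel_index(flat, (rows, cols))
        outlier_mask[orr, occ] = True
        kinds = rng.random(n_out) < 0.5
        noise_floor = max(config.noise_sd, 1e-3)
        for (r, c), is_spike in zip(zip(orr, occ), kinds):
            if is_spike:
                # saturation-like spike: x5 amplitude plus strong shape noise
                base = pure[str(names[r, c])].absorbance
                cube[r, c] = 5.0 * b[r, c] * base + rng.normal(
                    0.0, 10.0 * noise_floor, size=nu.size)
            else:
                # detector-glitch pixel: broadband noise at band-height scale
                cube[r, c] = rng.normal(0.0, 0.5, size=nu.size)

    image = SpectralImage(axis, cube, pixel_size=config.pixel_size,
                          name=f"phantom_{config.phase}_seed{config.seed}")
    return PhantomTruth(image=image, labels=labels, pure=pure, applied_b=b,
                        outlier_mask=outlier_mask, vapor=vapor_spec)


# ---------------------------------------------------------------------------
# reference spectra of standard compounds

_REFERENCE_BANDS = {
    # heparan sulfate: dominant sulfation band, carbohydrate backbone, and
    # the moderate N-acetyl/N-sulfo amide bands real GAG standards show
    "HS": [BandSpec(1248.0, 10.0, 0.50), BandSpec(1655.0, 28.0, 0.40),
           BandSpec(1545.0, 22.0, 0.25), BandSpec(1080.0, 18.0, 0.28),
           BandSpec(1030.0, 16.0, 0.24), BandSpec(1425.0, 20.0, 0.10)],
    # glypican-1 core protein: amide-dominant with weak sulfation
    "GPC1": [BandSpec(1655.0, 28.0, 1.00), BandSpec(1545.0, 22.0, 0.55),
             BandSpec(1310.0, 14.0, 0.25), BandSpec(1248.0, 10.0, 0.08),
             BandSpec(1080.0, 18.0, 0.10)],
    # hyaluronic acid: non-sulfated carbohydrate (no 1248 cm^-1 band)
    "HA": [BandSpec(1080.0, 18.0, 0.50), BandSpec(1035.0, 16.0, 0.45),
           BandSpec(1410.0, 22.0, 0.15), BandSpec(1615.0, 25.0, 0.20)],
}


def reference_spectra(axis: WavenumberAxis | None = None) -> dict[str, Spectrum]:
    """Noise-free reference spectra of HS, GPC1, HA and OCT.

    HA carries no sulfation band (its absorbance at 1248 cm^-1 is zero to
    numerical precision), mirroring its non-sulfated chemistry.
    """
    axis = axis or DEFAULT_AXIS
    out = {}
    all_bands = dict(_REFERENCE_BANDS, OCT=list(_OCT_BANDS))
    for name, bands in all_bands.items():
        total = np.zeros_like(axis.values)
        for band in bands:
            total += band.evaluate(axis.values)
        out[name] = Spectrum(axis, total, label=name)
    return out
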