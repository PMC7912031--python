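"""Readers and writers for cubes, reference spectra and label maps.

Three cube dialects are supported:

``hdf5-cube``
    One HDF5 file with datasets ``/cube`` (rows x cols x bands),
    ``/wavenumbers``, optional ``/mask``, and attributes ``pixel_size_um``
    and ``name``.  Lossless round trip.
``envi``
    Standard ENVI flat-binary image (BSQ/BIL/BIP) next to a text ``.hdr``
    header carrying the wavelength vector in cm^-1.
``long-table``
    Comma-separated text, one row per ``(row, col, wavenumber, absorbance)``,
    header required.  Lowest-common-denominator exchange format.

Reference spectra are read from two-column text or JCAMP-DX.  Only AFFN
``(X++(Y..Y))`` XYDATA is supported; SQZ/DIF/PAC-compressed files are
rejected explicitly.
"""

from __future__ import annotations

import os
import re

import h5py
import numpy as np
import pandas as pd

from .spectral_data import (
    FormatError,
    LabelMap,
    SpectralImage,
    Spectrum,
    ValidationError,
    WavenumberAxis,
)

__all__ = [
    "read_cube",
    "write_cube",
    "read_reference_spectrum",
    "write_jcamp",
    "write_label_map",
    "read_label_map",
]

CUBE_DIALECTS = ("hdf5-cube", "envi", "long-table")

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_ENVI_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _orient_descending(nu: np.ndarray, cube: np.ndarray):
    """Flip band order so wavenumbers are descending; cube last axis follows."""
    nu = np.asarray(nu, dtype=float)
    if nu.size >= 2 and nu[0] < nu[-1]:
        nu = nu[::-1]
        cube = cube[..., ::-1]
    return nu, np.ascontiguousarray(cube)


# ---------------------------------------------------------------------------
# cubes


def read_cube(path: str | os.PathLike, dialect: str) -> SpectralImage:
    """Read a hyperspectral cube in the given dialect.

    The returned image always carries a descending axis; ascending input is
    flipped band-wise on ingest.
    """
    if dialect not in CUBE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {CUBE_DIALECTS}")
    if dialect == "hdf5-cube":
        return _read_hdf5(path)
    if dialect == "envi":
        return _read_envi(path)
    return _read_long_table(path)


def write_cube(img: SpectralImage, path: str | os.PathLike, dialect: str) -> None:
    """Write a cube so that :func:`read_cube` recovers it.

    hdf5-cube round trips bit-exactly; the text/flat dialects round trip to
    within 1e-6 AU.
    """
    if dialect not in CUBE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {CUBE_DIALECTS}")
    if dialect == "hdf5-cube":
        _write_hdf5(img, path)
    elif dialect == "envi":
        _write_envi(img, path)
    else:
        _write_long_table(img, path)


def _read_hdf5(path) -> SpectralImage:
    with h5py.File(path, "r") as f:
        for ds in ("cube", "wavenumbers"):
            if ds not in f:
                raise FormatError(f"hdf5-cube file missing dataset /{ds}")
        cube = f["cube"][...]
        nu = f["wavenumbers"][...]
        if cube.ndim != 3:
            raise FormatError(f"/cube must be 3-D, got shape {cube.shape}")
        if nu.shape[0] != cube.shape[2]:
            raise FormatError(
                f"/wavenumbers length {nu.shape[0]} != cube bands {cube.shape[2]}"
            )
        mask = f["mask"][...].astype(bool) if "mask" in f else None
        pixel_size = float(f.attrs.get("pixel_size_um", 6.25))
        name = str(f.attrs.get("name", ""))
    nu, cube = _orient_descending(nu, cube)
    return SpectralImage(WavenumberAxis(nu), cube, pixel_size=pixel_size,
                         mask=mask, name=name)


def _write_hdf5(img: SpectralImage, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=img.cube)
        f.create_dataset("wavenumbers", data=img.axis.values)
        f.create_dataset("mask", data=img.mask.astype(np.uint8))
        f.attrs["pixel_size_um"] = img.pixel_size
        f.attrs["name"] = img.name


def _envi_header_path(path) -> str:
    return str(path) + ".hdr"


def _read_envi(path) -> SpectralImage:
    hdr_path = _envi_header_path(path)
    if not os.path.exists(hdr_path):
        raise FormatError(f"ENVI header {hdr_path} not found")
    fields = _parse_envi_header(hdr_path)
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].strip().lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field {exc.args[0]!r}") from None
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"ENVI data type {dtype_code} not supported")
    if "wavelength" not in fields:
        raise FormatError("ENVI header missing field 'wavelength'")
    nu = np.array([float(t) for t in fields["wavelength"].split(",") if t.strip()])
    if nu.size != bands:
        raise FormatError(f"ENVI wavelength count {nu.size} != bands {bands}")
    raw = np.fromfile(path, dtype=_ENVI_DTYPES[dtype_code])
    if raw.size != rows * cols * bands:
        raise FormatError(
            f"ENVI binary has {raw.size} values, header implies {rows * cols * bands}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise FormatError(f"ENVI interleave {interleave!r} not supported")
    nu, cube = _orient_descending(nu, cube.astype(float))
    return SpectralImage(WavenumberAxis(nu), cube)


def _parse_envi_header(hdr_path) -> dict:
    with open(hdr_path) as fh:
        text = fh.read()
    if not text.strip().upper().startswith("ENVI"):
        raise FormatError("ENVI header must start with the magic word 'ENVI'")
    fields: dict[str, str] = {}
    # Join brace-delimited multi-line values, then split on '='.
    body = re.sub(r"\{([^}]*)\}", lambda m: m.group(1).replace("\n", " "), text)
    for line in body.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _write_envi(img: SpectralImage, path) -> None:
    cube = img.cube.astype(np.float64)
    rows, cols, bands = cube.shape
    cube.transpose(2, 0, 1).tofile(path)  # BSQ
    wl = ", ".join(f"{v:.6f}" for v in img.axis.values)
    with open(_envi_header_path(path), "w") as fh:
        fh.write(
            "ENVI\n"
            f"samples = {cols}\n"
            f"lines = {rows}\n"
            f"bands = {bands}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            f"data type = {_ENVI_DTYPE_CODES[cube.dtype]}\n"
            "interleave = bsq\n"
            "byte order = 0\n"
            "wavelength units = cm-1\n"
            f"wavelength = {{ {wl} }}\n"
        )


def _read_long_table(path) -> SpectralImage:
    df = pd.read_csv(path)
    required = ["row", "col", "wavenumber", "absorbance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"long-table header missing column(s) {missing}")
    nu = np.sort(df["wavenumber"].unique())[::-1]
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    n_bands = nu.size
    counts = df.groupby(["row", "col"]).size()
    if len(counts) != rows * cols or (counts != n_bands).any():
        expected = {(r, c) for r in range(rows) for c in range(cols)}
        bad = sorted(expected - set(counts[counts == n_bands].index))
        raise ValidationError(f"long-table incomplete at pixel(s) {bad[:20]}")
    band_index = {v: i for i, v in enumerate(nu)}
    cube = np.full((rows, cols, n_bands), np.nan)
    cube[df["row"].to_numpy(), df["col"].to_numpy(),
         df["wavenumber"].map(band_index).to_numpy()] = df["absorbance"].to_numpy()
    return SpectralImage(WavenumberAxis(nu), cube)


def _write_long_table(img: SpectralImage, path) -> None:
    rows, cols, bands = img.cube.shape
    rr, cc, bb = np.meshgrid(np.arange(rows), np.arange(cols), np.arange(bands),
                             indexing="ij")
    pd.DataFrame({
        "row": rr.ravel(),
        "col": cc.ravel(),
        "wavenumber": img.axis.values[bb.ravel()],
        "absorbance": img.cube.ravel(),
    }).to_csv(path, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# reference spectra

_COMPRESSION_CHARS = re.compile(r"[@%A-DF-Ia-df-iJ-Rj-r]")


def read_reference_spectrum(path: str | os.PathLike, dialect: str) -> Spectrum:
    """Read a single reference spectrum (``jcamp-dx`` or ``two-column``)."""
    if dialect == "two-column":
        data = np.loadtxt(path, comments=("#", ";"))
        if data.ndim != 2 or data.shape[1] < 2:
            raise FormatError("two-column file must have (wavenumber, absorbance) pairs")
        if data.shape[0] < 8:
            raise ValidationError(f"reference spectrum needs >= 8 points, got {data.shape[0]}")
        label = os.path.splitext(os.path.basename(path))[0]
        return Spectrum.from_arrays(data[:, 0], data[:, 1], label=label)
    if dialect == "jcamp-dx":
        return _read_jcamp(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'jcamp-dx' or 'two-column'")


def _read_jcamp(path) -> Spectrum:
    labels: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    in_xydata = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                labels[key] = value.strip()
                if key == "XYDATA":
                    if "X++(Y..Y)" not in value.replace(" ", ""):
                        raise FormatError(
                            f"unsupported XYDATA variant {value.strip()!r}; "
                            "only (X++(Y..Y)) is supported"
                        )
                    in_xydata = True
                elif key == "END":
                    in_xydata = False
                continue
            if not in_xydata:
                continue
            tokens = line.split()
            try:
                values = [float(t) for t in tokens]
            except ValueError:
                if any(_COMPRESSION_CHARS.search(t.rstrip("Ee+-0123456789."))
                       or not _is_affn(t) for t in tokens):
                    raise FormatError(
                        "JCAMP-DX XYDATA uses SQZ/DIF/PAC compression, which is "
                        "not supported; only AFFN is accepted"
                    ) from None
                raise
            if len(values) < 2:
                raise FormatError("XYDATA line with fewer than 2 values")
            x0 = values[0]
            xs.append(x0)
            ys.extend(values[1:])
            # remaining abscissas are reconstructed from FIRSTX/LASTX below
    if "XYDATA" not in labels:
        raise FormatError("JCAMP-DX file has no ##XYDATA record")
    try:
        npoints = int(float(labels["NPOINTS"]))
        firstx = float(labels["FIRSTX"])
        lastx = float(labels["LASTX"])
    except KeyError as exc:
        raise FormatError(f"JCAMP-DX missing required label ##{exc.args[0]}") from None
    xfactor = float(labels.get("XFACTOR", 1.0))
    yfactor = float(labels.get("YFACTOR", 1.0))
    if len(ys) != npoints:
        raise FormatError(f"JCAMP-DX NPOINTS={npoints} but {len(ys)} ordinates read")
    if npoints < 8:
        raise ValidationError(f"reference spectrum needs >= 8 points, got {npoints}")
    nu = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    label = labels.get("TITLE") or os.path.splitext(os.path.basename(path))[0]
    return Spectrum.from_arrays(nu, np.array(ys) * yfactor, label=label)


def _is_affn(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_jcamp(s: Spectrum, path: str | os.PathLike, title: str | None = None) -> None:
    """Write a spectrum as AFFN ``(X++(Y..Y))`` JCAMP-DX on a uniform grid."""
    nu = s.axis.values
    steps = np.diff(nu)
    if not np.allclose(steps, steps[0], atol=1e-9):
        raise ValidationError("JCAMP-DX XYDATA export requires a uniform axis")
    with open(path, "w") as fh:
        fh.write(f"##TITLE={title or s.label or 'spectrum'}\n")
        fh.write("##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
        fh.write("##XFACTOR=1\n##YFACTOR=1\n")
        fh.write(f"##FIRSTX={nu[0]:.6f}\n##LASTX={nu[-1]:.6f}\n")
        fh.write(f"##NPOINTS={nu.size}\n##XYDATA=(X++(Y..Y))\n")
        per_line = 6
        for i in range(0, nu.size, per_line):
            block = s.absorbance[i:i + per_line]
            fh.write(f"{nu[i]:.6f} " + " ".join(f"{y:.8g}" for y in block) + "\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------------------
# label maps


def write_label_map(lm: LabelMap, csv_path: str | os.PathLike) -> None:
    """Write a label map as CSV with a ``# legend:`` comment line."""
    legend = ";".join(f"{i}={name}" for i, name in sorted(lm.legend.items()))
    with open(csv_path, "w") as fh:
        fh.write(f"# legend: {legend}\n")
        np.savetxt(fh, lm.labels, fmt="%d", delimiter=",")


def read_label_map(csv_path: str | os.PathLike) -> LabelMap:
    with open(csv_path) as fh:
        first = fh.readline()
        if not first.startswith("# legend:"):
            raise FormatError("label-map CSV missing '# legend:' header line")
        legend = {}
        for item in first.partition(":")[2].split(";"):
            item = item.strip()
            if item:
                i, _, name = item.partition("=")
                legend[int(i)] = name
        labels = np.loadtxt(fh, dtype=int, delimiter=",")
    return LabelMap(np.atleast_2d(labels), legend)
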