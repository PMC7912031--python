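"""Data model and I/O: axes, windows, cropping, resampling, cube dialects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irhisto import (
    FormatError,
    SpectralImage,
    SpectralWindow,
    Spectrum,
    ValidationError,
    WavenumberAxis,
    WindowError,
    crop_to_window,
    read_cube,
    read_reference_spectrum,
    resample_to_axis,
    write_cube,
    write_jcamp,
)
from irhisto.io import read_label_map, write_label_map
from irhisto.spectral_data import LabelMap


class TestWavenumberAxis:
    def test_ascending_input_is_stored_descending(self):
        ax = WavenumberAxis(np.arange(900.0, 1800.0, 4.0))
        assert ax.values[0] > ax.values[-1]
        assert ax.step == 4.0

    @pytest.mark.parametrize("bad", [
        np.arange(1.0, 6.0),                       # too short
        np.array([8, 7, 6, 5, 4, 3, 2, 0.0]),      # non-positive value
        np.array([1, 2, 3, 3, 4, 5, 6, 7.0]),      # not strictly monotonic
    ])
    def test_invalid_axes_rejected(self, bad):
        with pytest.raises(ValidationError):
            WavenumberAxis(bad)


class TestCropToWindow:
    def test_sulfation_window_band_count_matches_enumeration(self, default_axis):
        # independent oracle: count grid wavenumbers inside the closed window
        expected = sum(1 for v in default_axis.values if 1190 <= v <= 1350)
        s = Spectrum(default_axis, np.zeros(len(default_axis)))
        cropped = crop_to_window(s, SpectralWindow(1190, 1350))
        assert len(cropped) == expected == 40

    def test_full_extent_window_is_identity(self, default_axis):
        s = Spectrum(default_axis, np.linspace(0, 1, len(default_axis)))
        out = crop_to_window(s, SpectralWindow(900, 1800))
        assert out.axis == default_axis
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_disjoint_window_raises(self, default_axis):
        s = Spectrum(default_axis, np.zeros(len(default_axis)))
        with pytest.raises(WindowError):
            crop_to_window(s, SpectralWindow(100, 200))

    @settings(derandomize=True, max_examples=30)
    @given(lo=st.floats(900, 1700), width=st.floats(50, 800))
    def test_crop_is_idempotent(self, lo, width, default_axis):
        w = SpectralWindow(lo, lo + width)
        s = Spectrum(default_axis, np.sin(default_axis.values / 37.0))
        once = crop_to_window(s, w)
        twice = crop_to_window(once, w)
        np.testing.assert_array_equal(once.absorbance, twice.absorbance)


class TestResample:
    def test_identity_on_same_axis(self, default_axis):
        s = Spectrum(default_axis, np.sin(default_axis.values / 10))
        out = resample_to_axis(s, default_axis)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-12)

    def test_exact_on_affine_spectra(self, default_axis):
        s = Spectrum(default_axis, 0.1 + 0.002 * default_axis.values)
        target = WavenumberAxis.from_range(1798, 902, 4)  # midpoints
        out = resample_to_axis(s, target)
        np.testing.assert_allclose(out.absorbance, 0.1 + 0.002 * target.values,
                                   atol=1e-12)

    def test_gaussian_resampled_matches_direct_evaluation(self):
        fine = WavenumberAxis.from_range(1800, 900, 2)
        coarse = WavenumberAxis.from_range(1800, 900, 4)
        g = lambda nu: 0.8 * np.exp(-0.5 * ((nu - 1300) / 25) ** 2)
        out = resample_to_axis(Spectrum(fine, g(fine.values)), coarse)
        np.testing.assert_allclose(out.absorbance, g(coarse.values), atol=1e-3)

    def test_extrapolation_refused(self, default_axis):
        s = Spectrum(default_axis, np.zeros(len(default_axis)))
        with pytest.raises(WindowError):
            resample_to_axis(s, WavenumberAxis.from_range(2000, 1000, 4))


def _small_image():
    axis = WavenumberAxis(np.array([1800, 1796, 1792, 1788, 1784, 1780, 1776, 1772.0]))
    rng = np.random.default_rng(0)
    return SpectralImage(axis, rng.random((4, 4, 8)), pixel_size=6.25, name="tiny")


class TestCubeRoundTrips:
    def test_hdf5_round_trip_is_bit_exact(self, tmp_path):
        img = _small_image()
        path = tmp_path / "cube.h5"
        write_cube(img, path, "hdf5-cube")
        back = read_cube(path, "hdf5-cube")
        assert np.max(np.abs(back.cube - img.cube)) == 0.0
        assert back.axis == img.axis
        assert back.pixel_size == img.pixel_size

    def test_envi_round_trip(self, tmp_path):
        img = _small_image()
        path = tmp_path / "cube.raw"
        write_cube(img, path, "envi")
        back = read_cube(path, "envi")
        np.testing.assert_allclose(back.cube, img.cube, atol=1e-6)
        np.testing.assert_allclose(back.axis.values, img.axis.values, atol=1e-6)

    def test_envi_ascending_axis_flipped_on_read(self, tmp_path):
        img = _small_image()
        # hand-written ENVI file with ascending wavelengths and matching bands
        flipped = img.cube[:, :, ::-1]
        asc = img.axis.values[::-1]
        path = tmp_path / "asc.raw"
        flipped.transpose(2, 0, 1).astype(np.float64).tofile(path)
        wl = ", ".join(f"{v:.6f}" for v in asc)
        (tmp_path / "asc.raw.hdr").write_text(
            "ENVI\nsamples = 4\nlines = 4\nbands = 8\ndata type = 5\n"
            f"interleave = bsq\nbyte order = 0\nwavelength = {{ {wl} }}\n")
        back = read_cube(path, "envi")
        assert back.axis.values[0] == 1800.0
        np.testing.assert_allclose(back.cube, img.cube, atol=1e-6)

    def test_long_table_row_count_and_round_trip(self, tmp_path):
        axis = WavenumberAxis(np.array([1800, 1796, 1792, 1788, 1784, 1780, 1776, 1772.0]))
        img = SpectralImage(axis, np.random.default_rng(1).random((4, 4, 8)))
        path = tmp_path / "cube.csv"
        write_cube(img, path, "long-table")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4 * 4 * 8 + 1  # data rows plus header
        back = read_cube(path, "long-table")
        np.testing.assert_allclose(back.cube, img.cube, atol=1e-6)

    def test_long_table_missing_pixel_reports_coordinates(self, tmp_path):
        img = _small_image()
        path = tmp_path / "cube.csv"
        write_cube(img, path, "long-table")
        lines = path.read_text().splitlines()
        # drop every band row of pixel (1, 2)
        kept = [lines[0]] + [l for l in lines[1:] if not l.startswith("1,2,")]
        path.write_text("\n".join(kept) + "\n")
        with pytest.raises(ValidationError, match=r"\(1, 2\)"):
            read_cube(path, "long-table")

    def test_missing_hdf5_dataset_is_format_error(self, tmp_path):
        import h5py
        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=np.zeros((4, 4, 8)))
        with pytest.raises(FormatError, match="wavenumbers"):
            read_cube(path, "hdf5-cube")


class TestReferenceSpectra:
    def test_two_column_read(self, tmp_path):
        nu = np.linspace(1800, 1000, 10)
        a = np.linspace(0, 1, 10)
        path = tmp_path / "ref.txt"
        np.savetxt(path, np.column_stack([nu, a]))
        s = read_reference_spectrum(path, "two-column")
        assert len(s) == 10
        assert s.label == "ref"

    def test_jcamp_round_trip(self, tmp_path, default_axis):
        s = Spectrum(default_axis,
                     np.exp(-0.5 * ((default_axis.values - 1248) / 10) ** 2),
                     label="HS")
        path = tmp_path / "hs.jdx"
        write_jcamp(s, path)
        back = read_reference_spectrum(path, "jcamp-dx")
        np.testing.assert_allclose(back.absorbance, s.absorbance, atol=1e-6)
        np.testing.assert_allclose(back.axis.values, s.axis.values, atol=1e-6)
        assert back.label == "HS"

    def test_jcamp_compression_rejected(self, tmp_path):
        path = tmp_path / "sqz.jdx"
        path.write_text(
            "##TITLE=t\n##JCAMP-DX=4.24\n##FIRSTX=1800\n##LASTX=1764\n"
            "##NPOINTS=10\n##XYDATA=(X++(Y..Y))\n"
            "1800 A123B45C67\n##END=\n")
        with pytest.raises(FormatError, match="SQZ|compress"):
            read_reference_spectrum(path, "jcamp-dx")

    def test_too_few_points_rejected(self, tmp_path):
        path = tmp_path / "tiny.txt"
        np.savetxt(path, np.column_stack([[1800, 1700, 1600], [0.1, 0.2, 0.3]]))
        with pytest.raises(ValidationError):
            read_reference_spectrum(path, "two-column")


class TestLabelMap:
    def test_csv_round_trip(self, tmp_path):
        lm = LabelMap(np.array([[0, 1], [2, 0]]),
                      {0: "OCT", 1: "ORS", 2: "IRS"})
        path = tmp_path / "labels.csv"
        write_label_map(lm, path)
        back = read_label_map(path)
        np.testing.assert_array_equal(back.labels, lm.labels)
        assert back.legend == lm.legend

    def test_unknown_structure_name_rejected(self):
        with pytest.raises(ValidationError):
            LabelMap(np.array([[0]]), {0: "dermis"})

    def test_label_missing_from_legend_rejected(self):
        with pytest.raises(ValidationError):
            LabelMap(np.array([[0, 3]]), {0: "OCT"})
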