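"""ENVI cube I/O, reflectance calibration, ROI means, trims and tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blendspec import (
    Hypercube,
    calibrate_reflectance,
    extract_roi_spectrum,
    read_envi_cube,
    read_spectra_table,
    trim_wavelengths,
    write_envi_cube,
    write_spectra_table,
)
from blendspec.hsi_io import roi_mask_from_threshold

from conftest import make_block

WL3 = np.array([500.0, 600.0, 700.0])


def small_cube(dtype=np.float64):
    data = np.arange(2 * 2 * 3, dtype=dtype).reshape(2, 2, 3) + 1
    return Hypercube(data=data, wavelengths=WL3, interleave="bil")


def _write_raw_envi(tmp_path, arr, interleave, wavelengths):
    """Independent fixture writer: lays out bytes by hand, no package code."""
    lines, samples, bands = arr.shape
    if interleave == "bip":
        flat = arr
    elif interleave == "bil":
        flat = np.transpose(arr, (0, 2, 1))
    else:  # bsq
        flat = np.transpose(arr, (2, 0, 1))
    binary = tmp_path / f"cube_{interleave}.img"
    np.ascontiguousarray(flat).astype(np.float64).tofile(binary)
    header = tmp_path / f"cube_{interleave}.hdr"
    header.write_text(
        "ENVI\n"
        f"samples = {samples}\nlines = {lines}\nbands = {bands}\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength = { " + ", ".join(str(w) for w in wavelengths) + " }\n"
    )
    return header


class TestEnviIO:
    def test_round_trip_bil(self, tmp_path):
        cube = small_cube()
        write_envi_cube(cube, tmp_path / "cube.hdr")
        back = read_envi_cube(tmp_path / "cube.hdr")
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)

    def test_interleave_invariance(self, tmp_path, rng):
        """BIL/BIP/BSQ layouts of one array read back identically."""
        arr = rng.random((3, 4, 5))
        wl = np.linspace(500, 900, 5)
        cubes = [
            read_envi_cube(_write_raw_envi(tmp_path, arr, il, wl))
            for il in ("bil", "bip", "bsq")
        ]
        for cube in cubes:
            np.testing.assert_allclose(cube.data, arr)

    def test_band_count_mismatch_errors(self, tmp_path):
        header = tmp_path / "bad.hdr"
        (tmp_path / "bad.img").write_bytes(np.zeros(2 * 2 * 4).tobytes())
        header.write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 4\ndata type = 5\n"
            "interleave = bip\nwavelength = { 1, 2, 3 }\n"
        )
        with pytest.raises(ValueError, match="wavelength"):
            read_envi_cube(header)

    def test_missing_header_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_envi_cube(tmp_path / "absent.hdr")

    def test_unsupported_dtype_errors(self, tmp_path):
        header = tmp_path / "bad.hdr"
        (tmp_path / "bad.img").write_bytes(b"\0" * 48)
        header.write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 3\ndata type = 99\n"
            "interleave = bip\nwavelength = { 1, 2, 3 }\n"
        )
        with pytest.raises(ValueError, match="data type"):
            read_envi_cube(header)


class TestCalibration:
    @pytest.mark.parametrize(
        "mix,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)]
    )
    def test_known_reflectance(self, mix, expected):
        """I_raw interpolating dark->white gives R equal to the mix weight."""
        dark = np.full((2, 3), 100.0)
        white = np.full((2, 3), 900.0)
        raw = dark + mix * (white - dark)
        cube = Hypercube(
            data=np.broadcast_to(raw, (2, 2, 3)).copy(),
            wavelengths=WL3,
            dark=dark,
            white=white,
        )
        out = calibrate_reflectance(cube)
        np.testing.assert_allclose(out.data, expected)

    def test_gain_invariance(self, rng):
        """Scaling raw, dark and white by a common gain leaves R unchanged."""
        dark = rng.uniform(50, 100, (2, 3))
        white = rng.uniform(500, 900, (2, 3))
        data = rng.uniform(100, 500, (4, 2, 3))
        cube = Hypercube(data=data, wavelengths=WL3, dark=dark, white=white)
        scaled = Hypercube(
            data=3.7 * data, wavelengths=WL3, dark=3.7 * dark, white=3.7 * white
        )
        np.testing.assert_allclose(
            calibrate_reflectance(cube).data,
            calibrate_reflectance(scaled).data,
            atol=1e-12,
        )

    def test_white_equals_dark_names_band(self):
        dark = np.full((2, 3), 100.0)
        white = np.full((2, 3), 900.0)
        white[0, 1] = 100.0  # saturated reference at band index 1
        cube = Hypercube(
            data=np.ones((2, 2, 3)), wavelengths=WL3, dark=dark, white=white
        )
        with pytest.raises(ValueError, match="band index 1"):
            calibrate_reflectance(cube)

    def test_missing_references_error(self):
        with pytest.raises(ValueError, match="dark and white"):
            calibrate_reflectance(small_cube())


class TestROI:
    def test_uniform_cube_any_mask(self):
        spec = np.array([0.2, 0.5, 0.9])
        cube = Hypercube(
            data=np.broadcast_to(spec, (3, 4, 3)).copy(), wavelengths=WL3
        )
        mask = np.zeros((3, 4), dtype=bool)
        mask[1, 2] = mask[0, 0] = True
        np.testing.assert_allclose(extract_roi_spectrum(cube, mask), spec)

    def test_single_pixel_mask(self, rng):
        cube = Hypercube(data=rng.random((3, 4, 3)), wavelengths=WL3)
        mask = np.zeros((3, 4), dtype=bool)
        mask[2, 1] = True
        np.testing.assert_array_equal(
            extract_roi_spectrum(cube, mask), cube.data[2, 1]
        )

    def test_two_pixel_mean_matches_hand_sum(self, rng):
        cube = Hypercube(data=rng.random((2, 2, 3)), wavelengths=WL3)
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        expected = (cube.data[0, 0] + cube.data[1, 1]) / 2
        np.testing.assert_allclose(extract_roi_spectrum(cube, mask), expected)

    def test_empty_mask_and_shape_mismatch(self):
        cube = small_cube()
        with pytest.raises(ValueError, match="empty"):
            extract_roi_spectrum(cube, np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            extract_roi_spectrum(cube, np.ones((3, 3), dtype=bool))

    def test_threshold_mask_splits_sample_from_background(self):
        data = np.full((2, 3, 3), 0.05)
        data[0, 1] = 0.6  # bright sample pixel on dark background
        cube = Hypercube(data=data, wavelengths=WL3)
        mask = roi_mask_from_threshold(cube, threshold=0.15)
        assert mask.sum() == 1 and mask[0, 1]


class TestTrim:
    def test_count_matches_linear_scan(self):
        block = make_block(
            np.zeros((2, 120)), np.linspace(400.0, 1020.0, 120)
        )
        trimmed = trim_wavelengths(block, 460.0, 1020.0)
        expected = sum(1 for w in block.wavelengths if 460.0 <= w <= 1020.0)
        assert trimmed.n_wavelengths == expected

    def test_full_interval_is_identity(self, random_block):
        out = trim_wavelengths(
            random_block,
            random_block.wavelengths[0],
            random_block.wavelengths[-1],
        )
        np.testing.assert_array_equal(out.values, random_block.values)

    def test_empty_result_errors(self, random_block):
        with pytest.raises(ValueError, match="no wavelengths"):
            trim_wavelengths(random_block, 2000.0, 2100.0)

    def test_reversed_interval_errors(self, random_block):
        with pytest.raises(ValueError, match="must be <"):
            trim_wavelengths(random_block, 900.0, 500.0)

    @given(
        lo=st.floats(min_value=500, max_value=650),
        hi=st.floats(min_value=700, max_value=900),
        lo2=st.floats(min_value=560, max_value=640),
        hi2=st.floats(min_value=710, max_value=880),
    )
    def test_nested_trims_compose(self, lo, hi, lo2, hi2):
        """trim∘trim with nested intervals equals one trim at the inner."""
        lam = np.linspace(500.0, 900.0, 80)
        block = make_block(np.outer(np.ones(3), lam / 900.0), lam)
        inner_lo, inner_hi = max(lo, lo2), min(hi, hi2)
        twice = trim_wavelengths(trim_wavelengths(block, lo, hi), inner_lo, inner_hi)
        once = trim_wavelengths(block, inner_lo, inner_hi)
        np.testing.assert_array_equal(twice.values, once.values)


class TestSpectraTable:
    def test_round_trip(self, tmp_path, rng):
        block = make_block(rng.random((3, 5)), np.linspace(500, 700, 5))
        write_spectra_table(block, tmp_path / "t.csv")
        back = read_spectra_table(tmp_path / "t.csv")
        np.testing.assert_allclose(back.values, block.values)
        assert back.sample_ids == block.sample_ids
        np.testing.assert_allclose(back.wavelengths, block.wavelengths)

    def test_fused_round_trip_keeps_provenance(self, tmp_path, rng):
        from blendspec import fuse_blocks

        a = make_block(rng.random((3, 4)), np.linspace(500, 700, 4), tag="VisNIR")
        b = make_block(rng.random((3, 3)), np.linspace(975, 1100, 3), tag="NIR")
        fused = fuse_blocks([a, b])
        write_spectra_table(fused, tmp_path / "f.csv")
        back = read_spectra_table(tmp_path / "f.csv")
        assert back.range_tag == "Fused"
        assert list(back.block_map) == list(fused.block_map)
        np.testing.assert_allclose(back.values, fused.values)

    def test_duplicate_sample_id_errors(self, tmp_path):
        (tmp_path / "d.csv").write_text(
            "sample_id,500,600\na,1,2\na,3,4\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra_table(tmp_path / "d.csv")

    def test_decreasing_headers_error_names_columns(self, tmp_path):
        (tmp_path / "o.csv").write_text(
            "sample_id,500,700,600\na,1,2,3\n"
        )
        with pytest.raises(ValueError, match="'700' -> '600'"):
            read_spectra_table(tmp_path / "o.csv")

    def test_non_numeric_header_errors(self, tmp_path):
        (tmp_path / "n.csv").write_text("sample_id,500,abc\na,1,2\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_spectra_table(tmp_path / "n.csv")
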