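"""ENVI I/O, absorbance conversion, bad-pixel repair and band cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cocoahsi as chs
from cocoahsi.hypercube_io import ABSORBANCE_AT_FLOOR

from conftest import random_cube


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    @pytest.mark.parametrize("dtype", [np.float32, np.float64, np.uint16, np.int32])
    def test_round_trip_exact(self, tmp_path, interleave, dtype):
        rng = np.random.default_rng(1)
        cube = random_cube(rng, dtype=np.float64)
        if np.issubdtype(dtype, np.integer):
            cube = chs.Hypercube((cube.data * 100 + 500).astype(dtype), cube.wavelengths)
        else:
            cube = chs.Hypercube(cube.data.astype(dtype), cube.wavelengths)
        hdr, dat = tmp_path / "c.hdr", tmp_path / "c.raw"
        chs.write_envi(cube, hdr, dat, interleave=interleave)
        back = chs.read_envi(hdr, dat)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths)

    def test_single_pixel_cube(self, tmp_path):
        cube = chs.Hypercube(np.array([[[0.1, 0.2, 0.3]]]), [1000.0, 1500.0, 2000.0])
        hdr, dat = tmp_path / "p.hdr", tmp_path / "p.raw"
        chs.write_envi(cube, hdr, dat)
        back = chs.read_envi(hdr, dat)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths, [1000.0, 1500.0, 2000.0])

    @settings(max_examples=25, deadline=None)
    @given(
        lines=st.integers(1, 4), samples=st.integers(1, 4), bands=st.integers(1, 5),
        interleave=st.sampled_from(["bil", "bip", "bsq"]),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_property(self, tmp_path_factory, lines, samples, bands,
                                 interleave, seed):
        rng = np.random.default_rng(seed)
        cube = random_cube(rng, lines, samples, bands)
        d = tmp_path_factory.mktemp("envi")
        chs.write_envi(cube, d / "c.hdr", d / "c.raw", interleave=interleave)
        back = chs.read_envi(d / "c.hdr", d / "c.raw")
        np.testing.assert_array_equal(back.data, cube.data)

    def test_wavelength_count_mismatch_rejected(self, tmp_path):
        cube = random_cube(np.random.default_rng(0), bands=4)
        hdr, dat = tmp_path / "c.hdr", tmp_path / "c.raw"
        chs.write_envi(cube, hdr, dat)
        text = hdr.read_text().replace("bands = 4", "bands = 5")
        hdr.write_text(text)
        with pytest.raises(ValueError, match="5 bands.*4 wavelengths"):
            chs.read_envi(hdr, dat)

    def test_unknown_interleave_rejected(self, tmp_path):
        cube = random_cube(np.random.default_rng(0))
        hdr, dat = tmp_path / "c.hdr", tmp_path / "c.raw"
        chs.write_envi(cube, hdr, dat)
        hdr.write_text(hdr.read_text().replace("interleave = bil", "interleave = foo"))
        with pytest.raises(ValueError, match="interleave"):
            chs.read_envi(hdr, dat)
        with pytest.raises(ValueError, match="interleave"):
            chs.write_envi(cube, hdr, dat, interleave="foo")


class TestComputeAbsorbance:
    def _frames(self, samples=4, bands=3):
        white = np.full((samples, bands), 1000.0)
        dark = np.full((samples, bands), 100.0)
        wl = np.array([1000.0, 1100.0, 1200.0][:bands])
        return white, dark, wl

    def test_raw_equals_white_gives_zero(self):
        white, dark, wl = self._frames()
        raw = np.broadcast_to(white, (2, 4, 3)).copy()
        cube = chs.compute_absorbance(raw, white, dark, wavelengths=wl)
        np.testing.assert_allclose(cube.data, 0.0, atol=1e-12)

    def test_ten_percent_reflectance_gives_unit_absorbance(self):
        white, dark, wl = self._frames()
        raw = np.full((2, 4, 3), 190.0)  # R = 90/900 = 0.1
        cube = chs.compute_absorbance(raw, white, dark, wavelengths=wl)
        np.testing.assert_allclose(cube.data, 1.0, atol=1e-12)

    def test_negative_reflectance_clamped_and_flagged(self):
        white, dark, wl = self._frames()
        raw = np.full((2, 4, 3), 50.0)  # raw < dark
        cube = chs.compute_absorbance(raw, white, dark, wavelengths=wl)
        np.testing.assert_allclose(cube.data, ABSORBANCE_AT_FLOOR)
        assert cube.data[0, 0, 0] == pytest.approx(4.0)
        assert cube.metadata["n_clamped_pixels"] == 24

    def test_white_not_above_dark_rejected(self):
        white, dark, wl = self._frames()
        white[1, 2] = dark[1, 2]
        raw = np.full((2, 4, 3), 500.0)
        with pytest.raises(ValueError, match=r"sample 1, band 2"):
            chs.compute_absorbance(raw, white, dark, wavelengths=wl)


class TestRemoveBadPixels:
    def test_planted_dead_column_detected(self, noisy_scene):
        cube = chs.compute_absorbance(noisy_scene.raw, noisy_scene.white,
                                      noisy_scene.dark,
                                      wavelengths=noisy_scene.wavelengths)
        cleaned, report = chs.remove_bad_pixels(cube)
        found = set(map(tuple, report.table[["sample", "band", "reason"]].values))
        for s, b, kind in noisy_scene.bad_pixels:
            assert (s, b, kind) in found
        # repaired columns no longer sit at the clamp value
        s, b, _ = noisy_scene.bad_pixels[0]
        assert np.all(cleaned.data[:, s, b] < ABSORBANCE_AT_FLOOR - 1e-6)

    def test_clean_cube_unchanged(self, noiseless_scene):
        cube = chs.compute_absorbance(noiseless_scene.raw, noiseless_scene.white,
                                      noiseless_scene.dark,
                                      wavelengths=noiseless_scene.wavelengths)
        cleaned, report = chs.remove_bad_pixels(cube)
        assert report.empty
        np.testing.assert_array_equal(cleaned.data, cube.data)

    def test_planted_spike_removed(self, noisy_scene):
        cube = chs.compute_absorbance(noisy_scene.raw, noisy_scene.white,
                                      noisy_scene.dark,
                                      wavelengths=noisy_scene.wavelengths)
        cube, _ = chs.remove_bad_pixels(cube)
        spiked = chs.Hypercube(cube.data.copy(), cube.wavelengths)
        line, sample, band = 10, 20, 100
        spiked.data[line, sample, band] += 10.0
        cleaned, report = chs.remove_bad_pixels(spiked)
        assert ("spike" in report.table.reason.values)
        assert abs(cleaned.data[line, sample, band] - cube.data[line, sample, band]) < 0.2

    def test_idempotent(self, noisy_scene):
        cube = chs.compute_absorbance(noisy_scene.raw, noisy_scene.white,
                                      noisy_scene.dark,
                                      wavelengths=noisy_scene.wavelengths)
        once, first = chs.remove_bad_pixels(cube)
        twice, second = chs.remove_bad_pixels(once)
        assert second.empty
        np.testing.assert_array_equal(twice.data, once.data)

    def test_unusable_scene_rejected(self):
        wl = np.linspace(1000, 1100, 10)
        data = np.random.default_rng(0).normal(1.0, 0.01, (5, 10, 10))
        data[:, :5, :] = ABSORBANCE_AT_FLOOR  # half the detector dead
        with pytest.raises(ValueError, match="unusable"):
            chs.remove_bad_pixels(chs.Hypercube(data, wl))


class TestCropBands:
    def test_crop_below_minimum(self):
        cube = chs.Hypercube(np.zeros((2, 2, 3)), [980.0, 1000.0, 1500.0])
        out = chs.crop_bands(cube, 990.0)
        np.testing.assert_array_equal(out.wavelengths, [1000.0, 1500.0])
        assert out.data.shape == (2, 2, 2)

    def test_min_below_axis_is_identity(self):
        cube = chs.Hypercube(np.zeros((2, 2, 3)), [1000.0, 1100.0, 1200.0])
        out = chs.crop_bands(cube, 900.0)
        assert out.data.shape == cube.data.shape

    def test_removing_all_bands_rejected(self):
        cube = chs.Hypercube(np.zeros((2, 2, 3)), [1000.0, 1100.0, 1200.0])
        with pytest.raises(ValueError, match="removes all bands"):
            chs.crop_bands(cube, 5000.0)
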