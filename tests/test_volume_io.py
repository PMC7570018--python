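import numpy as np
import pytest

from mtmesh.volume import (
    InconsistentPagesError,
    PointSpreadFunction,
    UnsupportedSampleFormatError,
    VolumeError,
    VoxelVolume,
    gaussian_psf,
    read_sidecar,
    read_stack,
    rescale_to_8bit,
    resample,
    richardson_lucy,
    write_stack,
)


class TestStackRoundTrip:
    @pytest.mark.parametrize("dtype,depth", [(np.uint8, 8), (np.uint16, 16)])
    def test_write_read_identity(self, tmp_path, dtype, depth):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 2**depth - 1, (3, 4, 4)).astype(dtype)
        vol = VoxelVolume(data=data, spacing=(0.1, 0.06, 0.06), bit_depth=depth)
        path = tmp_path / "v.tif"
        write_stack(vol, path)
        back = read_stack(path, spacing=(0.1, 0.06, 0.06))
        assert back.data.shape == (3, 4, 4)
        assert back.bit_depth == depth
        np.testing.assert_array_equal(back.data, data)
        assert read_sidecar(path)["spacing_um_zyx"] == [0.1, 0.06, 0.06]

    def test_single_page_gets_z_extent_one(self, tmp_path):
        import tifffile

        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.full((4, 4), 7, dtype=np.uint8))
        vol = read_stack(path, spacing=(0.1, 0.06, 0.06))
        assert vol.data.shape == (1, 4, 4)

    def test_double_write_is_byte_identical(self, tmp_path):
        data = np.arange(48, dtype=np.uint8).reshape(3, 4, 4)
        vol = VoxelVolume(data=data, spacing=(0.1,) * 3, bit_depth=8)
        p1, p2 = tmp_path / "a.tif", tmp_path / "b.tif"
        write_stack(vol, p1)
        write_stack(read_stack(p1, spacing=(0.1,) * 3), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_float_tiff_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "f.tif"
        tifffile.imwrite(path, np.zeros((4, 4), dtype=np.float32))
        with pytest.raises(UnsupportedSampleFormatError):
            read_stack(path, spacing=(0.1,) * 3)

    def test_inconsistent_pages_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "bad.tif"
        with tifffile.TiffWriter(path) as tw:
            tw.write(np.zeros((4, 4), dtype=np.uint8))
            tw.write(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(InconsistentPagesError):
            read_stack(path, spacing=(0.1,) * 3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(VolumeError):
            read_stack(tmp_path / "nope.tif", spacing=(0.1,) * 3)


class TestRescale:
    def test_endpoint_mapping(self):
        vol = VoxelVolume(
            data=np.array([[[10, 15, 20]]], dtype=np.uint16), spacing=(1, 1, 1)
        )
        out = rescale_to_8bit(vol)
        assert out.bit_depth == 8
        assert out.data.min() == 0 and out.data.max() == 255

    def test_identity_range_unchanged_up_to_rounding(self):
        data = np.arange(256, dtype=np.uint8).reshape(1, 16, 16)
        out = rescale_to_8bit(VoxelVolume(data=data, spacing=(1, 1, 1), bit_depth=8))
        np.testing.assert_array_equal(out.data, data)

    def test_exhaustive_rank_preservation_on_ramp(self):
        # all 256 levels sampled from the 16-bit range: order never inverts
        levels = np.linspace(0, 65535, 256).astype(np.uint16)
        vol = VoxelVolume(data=levels.reshape(1, 16, 16), spacing=(1, 1, 1))
        out = rescale_to_8bit(vol).data.ravel().astype(int)
        inp = levels.astype(int)
        for i in range(256):
            assert np.all(out[inp >= inp[i]] >= out[i])

    def test_constant_volume_warns_and_zeros(self):
        vol = VoxelVolume(data=np.full((2, 2, 2), 9, dtype=np.uint8), spacing=(1, 1, 1), bit_depth=8)
        with pytest.warns(UserWarning):
            out = rescale_to_8bit(vol)
        assert not out.data.any()


class TestResample:
    def test_identity_spacing_is_identity(self, ramp_volume):
        out = resample(ramp_volume, ramp_volume.spacing)
        np.testing.assert_allclose(out.data, ramp_volume.data, atol=1e-9)

    def test_constant_volume_stays_constant(self):
        vol = VoxelVolume(data=np.full((5, 6, 7), 42, dtype=np.uint8), spacing=(0.06, 0.06, 0.1), bit_depth=8)
        out = resample(vol, (0.12, 0.12, 0.12))
        np.testing.assert_allclose(out.data, 42.0, atol=1e-9)

    def test_extent_roughly_halves_at_double_spacing(self):
        vol = VoxelVolume(data=np.zeros((21, 41, 41), dtype=np.uint8), spacing=(0.1, 0.06, 0.06), bit_depth=8)
        out = resample(vol, (0.12, 0.12, 0.12))
        assert out.data.shape == (17, 21, 21)
        for e_in, e_out in zip(vol.extent, out.extent):
            assert e_out <= e_in + 1e-9

    def test_linear_ramp_matches_analytic_interpolation(self):
        # ramp along x: value = 100 * x_um; exact under trilinear interpolation
        nx = 33
        data = np.tile(100 * 0.06 * np.arange(nx), (4, 4, 1))
        vol = VoxelVolume(data=data, spacing=(0.06, 0.06, 0.06), bit_depth=16)
        out = resample(vol, (0.06, 0.06, 0.12))
        expected = 100 * 0.12 * np.arange(out.data.shape[2])
        np.testing.assert_allclose(out.data[2, 2], expected, atol=1e-6)

    def test_too_coarse_target_rejected(self):
        vol = VoxelVolume(data=np.zeros((2, 2, 2), dtype=np.uint8), spacing=(0.1,) * 3, bit_depth=8)
        with pytest.raises(VolumeError):
            resample(vol, (0.1, 0.1, -1.0))


class TestRichardsonLucy:
    def _delta_psf(self):
        k = np.zeros((3, 3, 3))
        k[1, 1, 1] = 1.0
        return PointSpreadFunction(data=k, spacing=(0.1,) * 3)

    @pytest.mark.parametrize("iterations", [1, 5])
    def test_delta_psf_is_identity(self, iterations):
        rng = np.random.default_rng(1)
        data = rng.integers(1, 200, (8, 8, 8)).astype(np.uint16)
        vol = VoxelVolume(data=data, spacing=(0.1,) * 3)
        out = richardson_lucy(vol, self._delta_psf(), iterations)
        np.testing.assert_allclose(out.data, data, rtol=1e-7, atol=1e-6)

    def test_all_zero_volume_stays_zero(self):
        vol = VoxelVolume(data=np.zeros((6, 6, 6), dtype=np.uint16), spacing=(0.1,) * 3)
        out = richardson_lucy(vol, self._delta_psf(), 3)
        assert not out.data.any()

    def test_deblur_raises_contrast_and_conserves_flux(self):
        from scipy.signal import fftconvolve

        truth = np.zeros((24, 24, 24))
        truth[8:16, 10:14, 10:14] = 1000.0
        psf = gaussian_psf((0.15, 0.15), (0.1, 0.1, 0.1))
        blurred = fftconvolve(truth, psf.data, mode="same")
        vol = VoxelVolume(data=np.clip(blurred, 0, 65535), spacing=(0.1,) * 3)
        out = richardson_lucy(vol, psf, 20)
        contrast_in = vol.data.max() / (vol.data.mean() + 1e-12)
        contrast_out = out.data.max() / (out.data.mean() + 1e-12)
        assert contrast_out > contrast_in
        assert out.data.min() >= 0.0
        assert abs(out.data.sum() - vol.data.sum()) / vol.data.sum() < 0.01

    def test_oversized_psf_rejected(self):
        vol = VoxelVolume(data=np.ones((4, 4, 4), dtype=np.uint8), spacing=(0.1,) * 3, bit_depth=8)
        big = PointSpreadFunction(data=np.full((9, 9, 9), 1 / 729), spacing=(0.1,) * 3)
        with pytest.raises(VolumeError):
            richardson_lucy(vol, big, 1)


def test_psf_must_normalize():
    bad = PointSpreadFunction(data=np.ones((3, 3, 3)), spacing=(0.1,) * 3)
    with pytest.raises(VolumeError):
        bad.validate()
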