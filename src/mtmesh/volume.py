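"""Volume stack I/O, normalization, resampling and Richardson-Lucy deconvolution.

Volumes are confocal z-stacks stored as grayscale multi-page TIFFs (one page
per z slice, 8- or 16-bit unsigned).  Physical voxel spacing is always
supplied by the caller and carried in a sidecar JSON, never parsed from TIFF
resolution tags — tag dialects are too unreliable to trust silently.
Axis order is fixed as (z, y, x) with the page index as z.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile
from scipy import ndimage
from scipy.signal import fftconvolve


class VolumeError(ValueError):
    pass


class VolumeReadError(VolumeError):
    """The file could not be read as a volume stack."""


class UnsupportedSampleFormatError(VolumeError):
    """Pages are not 8/16-bit unsigned integer grayscale."""


class InconsistentPagesError(VolumeError):
    """Pages of a multi-page TIFF do not share one shape."""


@dataclass
class VoxelVolume:
    """A 3D intensity grid with per-axis physical spacing.

    ``data`` is indexed (z, y, x); ``spacing`` gives the physical voxel pitch
    per axis in um, in the same (z, y, x) order.  ``bit_depth`` declares the
    intensity range convention (0 .. 2**bit_depth - 1); the array itself may
    be float-valued (e.g. after resampling or deconvolution).
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    channel: str = "filament"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)

    def validate(self) -> None:
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeError(f"expected a non-empty 3D grid, got {self.data.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.bit_depth not in (8, 16):
            raise VolumeError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        dmin, dmax = float(self.data.min()), float(self.data.max())
        if dmin < 0 or dmax > 2**self.bit_depth - 1:
            raise VolumeError(
                f"intensities [{dmin}, {dmax}] outside 0..{2 ** self.bit_depth - 1}"
            )

    @property
    def intensity_range(self) -> Tuple[float, float]:
        return float(self.data.min()), float(self.data.max())

    @property
    def extent(self) -> Tuple[float, float, float]:
        """Physical size (center-to-center) per axis in um."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))


@dataclass
class PointSpreadFunction:
    """A normalized 3D blur kernel with physical spacing."""

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise VolumeError("PSF must be a 3D kernel")
        if np.any(self.data < 0):
            raise VolumeError("PSF entries must be >= 0")
        if abs(float(self.data.sum()) - 1.0) > 1e-6:
            raise VolumeError(f"PSF must sum to 1, sums to {float(self.data.sum())}")


def gaussian_psf(
    sigma: Tuple[float, float], spacing: Tuple[float, float, float], truncate: float = 4.0
) -> PointSpreadFunction:
    """Anisotropic Gaussian PSF surrogate: sigma = (lateral, axial) in um."""
    lat, ax = sigma
    sig_vox = np.array([ax / spacing[0], lat / spacing[1], lat / spacing[2]])
    half = np.maximum(np.ceil(truncate * sig_vox), 1).astype(int)
    zz, yy, xx = np.meshgrid(
        *(np.arange(-h, h + 1) for h in half), indexing="ij"
    )
    k = np.exp(
        -0.5
        * (
            (zz / sig_vox[0]) ** 2
            + (yy / sig_vox[1]) ** 2
            + (xx / sig_vox[2]) ** 2
        )
    )
    k /= k.sum()
    return PointSpreadFunction(data=k, spacing=spacing)


# ---------------------------------------------------------------------------


def read_stack(path, spacing: Tuple[float, float, float], channel: str = "filament") -> VoxelVolume:
    """Read a single- or multi-page grayscale TIFF as a VoxelVolume.

    ``spacing`` is the (z, y, x) voxel pitch in um, supplied by the caller.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise InconsistentPagesError(
                    f"{path}: pages have differing shapes {sorted(shapes)}"
                )
            data = tf.asarray()
    except (InconsistentPagesError,):
        raise
    except (FileNotFoundError, OSError, ValueError, tifffile.TiffFileError) as e:
        raise VolumeReadError(f"{path}: cannot read TIFF ({e})") from e
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise VolumeReadError(f"{path}: expected 2D pages, got array {data.shape}")
    if data.dtype == np.uint8:
        depth = 8
    elif data.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedSampleFormatError(
            f"{path}: unsupported sample format {data.dtype} (need uint8/uint16)"
        )
    vol = VoxelVolume(data=data, spacing=spacing, channel=channel, bit_depth=depth)
    vol.validate()
    return vol


def sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_stack(volume: VoxelVolume, path, sidecar: bool = True) -> None:
    """Write a multi-page TIFF (one page per z slice), bit depth preserved.

    A sidecar JSON with spacing/channel/bit_depth is written next to it.
    """
    volume.validate()
    dtype = np.uint8 if volume.bit_depth == 8 else np.uint16
    data = np.round(volume.data).astype(dtype)
    try:
        tifffile.imwrite(str(path), data, photometric="minisblack")
    except OSError as e:
        raise VolumeError(f"{path}: cannot write TIFF ({e})") from e
    if sidecar:
        with open(sidecar_path(path), "w") as fh:
            json.dump(
                {
                    "spacing_um_zyx": list(volume.spacing),
                    "channel": volume.channel,
                    "bit_depth": volume.bit_depth,
                    "units": "um",
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def read_sidecar(tiff_path) -> dict:
    with open(sidecar_path(tiff_path)) as fh:
        return json.load(fh)


def rescale_to_8bit(volume: VoxelVolume) -> VoxelVolume:
    """Linearly map [min, max] -> [0, 255] (monotone; ties preserved)."""
    volume.validate()
    lo, hi = volume.intensity_range
    if hi == lo:
        warnings.warn(
            "constant-intensity volume: rescale_to_8bit produces all zeros",
            stacklevel=2,
        )
        data = np.zeros(volume.data.shape, dtype=np.uint8)
    else:
        scaled = (volume.data.astype(np.float64) - lo) * (255.0 / (hi - lo))
        data = np.round(scaled).astype(np.uint8)
    return VoxelVolume(
        data=data, spacing=volume.spacing, channel=volume.channel, bit_depth=8
    )


def resample(volume: VoxelVolume, target_spacing: Tuple[float, float, float]) -> VoxelVolume:
    """Trilinear resampling onto a new grid covering the same physical extent.

    Voxel centers sit at ``index * spacing`` on both grids (shared origin);
    the output grid is the largest that stays inside the input extent.
    """
    volume.validate()
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise VolumeError(f"target spacing must be positive, got {target}")
    new_shape = []
    for n, s_in, s_out in zip(volume.data.shape, volume.spacing, target):
        n_out = int(np.floor((n - 1) * s_in / s_out + 1e-9)) + 1
        if n_out < 1:
            raise VolumeError("target grid would have < 1 voxel on an axis")
        new_shape.append(n_out)
    coords = np.meshgrid(
        *(
            np.arange(n_out) * (s_out / s_in)
            for n_out, s_in, s_out in zip(new_shape, volume.spacing, target)
        ),
        indexing="ij",
    )
    data = ndimage.map_coordinates(
        volume.data.astype(np.float64), np.array(coords), order=1, mode="nearest"
    )
    return VoxelVolume(
        data=data, spacing=target, channel=volume.channel, bit_depth=volume.bit_depth
    )


def richardson_lucy(
    volume: VoxelVolume, psf: PointSpreadFunction, iterations: int = 10
) -> VoxelVolume:
    """Standard multiplicative Richardson-Lucy deconvolution.

    The estimate is updated as ``e <- e * (K* . (v / (K . e)))`` with the
    normalized kernel K; non-negativity is preserved and total intensity is
    conserved (within ~1% for signals supported away from the borders).
    """
    volume.validate()
    psf.validate()
    if iterations < 1:
        raise VolumeError("iterations must be >= 1")
    if any(k > v for k, v in zip(psf.data.shape, volume.data.shape)):
        raise VolumeError(
            f"PSF {psf.data.shape} larger than volume {volume.data.shape}"
        )
    img = volume.data.astype(np.float64)
    if img.max() == 0.0:
        return replace(volume, data=np.zeros_like(img))
    kernel = psf.data.astype(np.float64)
    mirror = kernel[::-1, ::-1, ::-1]
    est = np.full_like(img, img.mean())
    eps = 1e-12
    for _ in range(iterations):
        blurred = fftconvolve(est, kernel, mode="same")
        ratio = img / np.maximum(blurred, eps)
        est *= fftconvolve(ratio, mirror, mode="same")
        np.clip(est, 0.0, None, out=est)
    limit = 2**volume.bit_depth - 1
    np.clip(est, 0.0, limit, out=est)
    return replace(volume, data=est)
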