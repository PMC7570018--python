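"""Render known cylinder networks into confocal-like two-channel volumes.

This is the testing ground for the whole reconstruction pipeline: a network
model with known geometry is rasterized as solid cylinders (anti-aliased over
one voxel), blurred with an anisotropic Gaussian PSF surrogate, scaled to a
chosen signal-to-noise ratio over a Poisson + Gaussian-read-noise background,
and quantized to 16 bits.  The second channel carries Gaussian blobs at every
joint and linker anchor, emulating the localized dye signal of the DNA-origami
binding regions.

What the renderer deliberately does *not* emulate: a physically rigorous
(vectorial, aberrated) PSF, photobleaching, and the Brownian jitter between
successive z slices seen in live acquisitions.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .model import (
    Filament,
    FilamentNetworkModel,
    KinesinHead,
    KinesinMultimer,
    ModelValidationError,
    build_aster_network,
    build_motility_element,
)
from .volume import VoxelVolume

DEFAULT_SPACING = (0.12, 0.12, 0.12)  # um, the working analysis grid
DEFAULT_PSF_SIGMA = (0.1, 0.25)  # (lateral, axial) um
DEFAULT_BACKGROUND = 20.0  # mean background photon count
READ_NOISE_SIGMA = 2.0  # additive Gaussian read noise, counts
MAX_RENDER_VOXELS = 64_000_000


class RenderError(ValueError):
    pass


def _cylinder_signed_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray, radius: float
) -> np.ndarray:
    """Signed distance of each point (n,3) to a flat-capped cylinder a->b.

    Negative inside.  Exact on the lateral surface and the caps; the edge
    circle uses the max-combination (adequate for one-voxel anti-aliasing).
    """
    ab = b - a
    length = float(np.linalg.norm(ab))
    if length < 1e-30:
        return np.linalg.norm(points - a, axis=-1) - radius
    u = ab / length
    rel = points - a
    proj = rel @ u
    radial = np.linalg.norm(rel - np.outer(proj, u), axis=-1)
    d_radial = radial - radius
    d_axial = np.maximum(-proj, proj - length)
    return np.maximum(d_radial, d_axial)


def _grid_bounds(model: FilamentNetworkModel, margin: float) -> Tuple[np.ndarray, np.ndarray]:
    pts = []
    for f in model.filaments:
        pts += [f.end_minus - f.radius, f.end_minus + f.radius]
        pts += [f.end_plus - f.radius, f.end_plus + f.radius]
    for lk in model.linkers:
        pts.append(lk.hub)
        pts += [h.point for h in lk.heads]
    for j in model.joints:
        pts.append(j.point)
    pts = np.asarray(pts)
    return pts.min(axis=0) - margin, pts.max(axis=0) + margin


def render_network(
    model: FilamentNetworkModel,
    spacing: Tuple[float, float, float] = DEFAULT_SPACING,
    psf_sigma: Tuple[float, float] = DEFAULT_PSF_SIGMA,
    snr: float = 10.0,
    seed: int = 0,
    origin: Optional[np.ndarray] = None,
    shape: Optional[Tuple[int, int, int]] = None,
    background: float = DEFAULT_BACKGROUND,
    max_voxels: int = MAX_RENDER_VOXELS,
) -> Tuple[VoxelVolume, VoxelVolume]:
    """Render (filament channel, linker channel) volumes for a model.

    ``spacing`` is (z, y, x) in um; model coordinates are (x, y, z) in um.
    ``psf_sigma`` is (lateral, axial); sigmas of 0 skip the blur.  ``snr`` is
    the ratio of the peak signal amplitude to the background noise standard
    deviation (Poisson + read noise); ``snr=inf`` renders noiselessly.
    Deterministic for a fixed seed.  ``origin``/``shape`` pin the grid
    explicitly (model units, (z, y, x) for shape; origin is the physical
    position of voxel (0, 0, 0) in (x, y, z)).
    """
    if model.units != "um":
        raise RenderError("render_network expects a model in um units")
    if not model.filaments:
        raise RenderError("model has no filaments to render")
    if any(s <= 0 for s in spacing) or snr <= 0 or any(s < 0 for s in psf_sigma):
        raise RenderError("spacing and snr must be > 0; psf sigmas >= 0")
    sz, sy, sx = spacing
    lat, ax = psf_sigma
    margin = 3.0 * max(lat, ax) + max(f.radius for f in model.filaments) + 2 * max(spacing)
    if origin is None or shape is None:
        lo, hi = _grid_bounds(model, margin)
        origin = lo
        shape = tuple(
            int(math.ceil((hi - lo)[2 - k] / spacing[k])) + 1 for k in range(3)
        )  # shape is (z,y,x); model axes are (x,y,z)
    origin = np.asarray(origin, dtype=float)
    nz, ny, nx = shape
    if nz * ny * nx > max_voxels:
        raise RenderError(
            f"render grid {shape} exceeds {max_voxels} voxels; "
            "shrink the model or coarsen the spacing"
        )
    zc = origin[2] + np.arange(nz) * sz
    yc = origin[1] + np.arange(ny) * sy
    xc = origin[0] + np.arange(nx) * sx

    fil = np.zeros((nz, ny, nx))
    edge = 0.5 * min(spacing)  # one-voxel anti-aliased rim
    for f in model.filaments:
        # rasterize on a local sub-grid around the cylinder for speed
        lo = np.minimum(f.end_minus, f.end_plus) - (f.radius + 3 * edge)
        hi = np.maximum(f.end_minus, f.end_plus) + (f.radius + 3 * edge)
        iz = np.searchsorted(zc, [lo[2], hi[2]])
        iy = np.searchsorted(yc, [lo[1], hi[1]])
        ix = np.searchsorted(xc, [lo[0], hi[0]])
        sl = (slice(max(iz[0] - 1, 0), iz[1] + 1),
              slice(max(iy[0] - 1, 0), iy[1] + 1),
              slice(max(ix[0] - 1, 0), ix[1] + 1))
        zz, yy, xx = np.meshgrid(zc[sl[0]], yc[sl[1]], xc[sl[2]], indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=-1)
        sd = _cylinder_signed_distance(pts, f.end_minus, f.end_plus, f.radius)
        occ = np.clip(-sd / (2 * edge) + 0.5, 0.0, 1.0)
        sub = fil[sl]
        np.maximum(sub, occ.reshape(sub.shape), out=sub)

    link = np.zeros((nz, ny, nx))
    blob_sigma = (max(lat, edge), max(ax, edge))  # blob sigma defaults to the PSF sigma
    anchors = [j.point for j in model.joints]
    for lk in model.linkers:
        anchors.append(lk.hub)
        anchors += [h.point for h in lk.heads]
    for p in anchors:
        lo = p - 4 * max(blob_sigma)
        hi = p + 4 * max(blob_sigma)
        iz = np.searchsorted(zc, [lo[2], hi[2]])
        iy = np.searchsorted(yc, [lo[1], hi[1]])
        ix = np.searchsorted(xc, [lo[0], hi[0]])
        sl = (slice(max(iz[0] - 1, 0), iz[1] + 1),
              slice(max(iy[0] - 1, 0), iy[1] + 1),
              slice(max(ix[0] - 1, 0), ix[1] + 1))
        zz, yy, xx = np.meshgrid(zc[sl[0]], yc[sl[1]], xc[sl[2]], indexing="ij")
        g = np.exp(
            -0.5 * (
                ((xx - p[0]) / blob_sigma[0]) ** 2
                + ((yy - p[1]) / blob_sigma[0]) ** 2
                + ((zz - p[2]) / blob_sigma[1]) ** 2
            )
        )
        link[sl] += g

    sig_vox = (ax / sz, lat / sy, lat / sx)
    if max(psf_sigma) > 0:
        fil = ndimage.gaussian_filter(fil, sigma=sig_vox)
        link = ndimage.gaussian_filter(link, sigma=sig_vox)

    rng = np.random.default_rng(seed)
    out = []
    for raw, channel in ((fil, "filament"), (link, "linker")):
        peak = raw.max() if raw.max() > 0 else 1.0
        if math.isinf(snr):
            counts = raw / peak * 1000.0
        else:
            noise_sd = math.sqrt(background + READ_NOISE_SIGMA**2)
            amplitude = snr * noise_sd
            expected = raw / peak * amplitude + background
            counts = rng.poisson(expected).astype(np.float64)
            counts += rng.normal(0.0, READ_NOISE_SIGMA, counts.shape)
        counts = np.clip(np.round(counts), 0, 65535).astype(np.uint16)
        out.append(
            VoxelVolume(data=counts, spacing=spacing, channel=channel, bit_depth=16)
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Fixture networks
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("two_parallel", "motility_element", "aster3", "crossing")


def make_fixture_network(kind: str, seed: int = 0) -> FilamentNetworkModel:
    """Named test networks in um units (filament radius 0.25, lengths 4/7.5).

    ``seed`` applies a random rigid rotation + translation to the whole scene
    (seed 0 leaves the canonical pose), so repeated seeds probe the pipeline
    at many orientations.
    """
    if kind == "two_parallel":
        model = FilamentNetworkModel(
            filaments=[
                Filament("F0", np.array([0.0, 0.0, 0.0]), np.array([4.0, 0.0, 0.0]), 0.25),
                Filament("F1", np.array([0.0, 1.0, 0.0]), np.array([4.0, 1.0, 0.0]), 0.25),
            ],
            units="um",
        )
    elif kind == "motility_element":
        model = build_motility_element(
            separation=1.0, overlap=1.0, length=4.0, radius=0.25, units="um"
        )
    elif kind == "aster3":
        model = build_aster_network(
            3, "closed", separation=1.0, overlap=1.0, length=4.0, radius=0.25, units="um"
        )
    elif kind == "crossing":
        # two filaments crossing at a slant angle, as tangled meshes do
        c, s = math.cos(math.radians(35)), math.sin(math.radians(35))
        model = FilamentNetworkModel(
            filaments=[
                Filament("F0", np.array([-2.0, 0.0, 0.0]), np.array([2.0, 0.0, 0.0]), 0.25),
                Filament(
                    "F1",
                    np.array([-2.0 * c, -2.0 * s, 0.0]),
                    np.array([2.0 * c, 2.0 * s, 0.0]),
                    0.25,
                ),
            ],
            units="um",
        )
    else:
        raise ModelValidationError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        )
    if seed != 0:
        model = _random_rigid_motion(model, seed)
    model.validate()
    return model


def make_recovery_scene(
    seed: int,
    lengths: Tuple[float, ...] = (4.0, 7.5),
    separation: float = 1.2,
    radius: float = 0.25,
) -> FilamentNetworkModel:
    """Non-intersecting parallel filaments of mixed lengths at a random pose.

    The standard scene for closure studies: one filament per entry of
    ``lengths``, parallel, ``separation`` um apart, then rigidly rotated and
    translated by the seed.
    """
    fils = []
    for i, L in enumerate(lengths):
        y = i * separation
        fils.append(
            Filament(
                f"F{i}",
                np.array([-L / 2.0, y, 0.0]),
                np.array([L / 2.0, y, 0.0]),
                radius,
            )
        )
    model = FilamentNetworkModel(filaments=fils, units="um")
    return _random_rigid_motion(model, seed)


def _random_rigid_motion(model: FilamentNetworkModel, seed: int) -> FilamentNetworkModel:
    rng = np.random.default_rng(seed)
    # uniform random rotation from a normalized quaternion
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.uniform(-1.0, 1.0, size=3)

    def mv(p):
        return rot @ p + shift

    from dataclasses import replace

    fils = [
        replace(f, end_minus=mv(f.end_minus), end_plus=mv(f.end_plus))
        for f in model.filaments
    ]
    linkers = [
        replace(
            lk,
            hub=mv(lk.hub),
            heads=[replace(h, point=mv(h.point)) for h in lk.heads],
        )
        for lk in model.linkers
    ]
    joints = [replace(j, point=mv(j.point)) for j in model.joints]
    out = FilamentNetworkModel(
        filaments=fils, linkers=linkers, joints=joints, units=model.units
    )
    out.validate()
    return out
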