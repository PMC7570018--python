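"""Isosurface extraction and STL exchange.

Meshes are extracted with marching cubes (Lewiner variant) at a caller-chosen
intensity level — iso levels are always free parameters here, as they are in
interactive volume viewers — and written as binary STL for import into
external 3D tools.  STL stores no units; this package writes um and records
that in the sidecar convention of the volume module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage import measure

from .volume import VoxelVolume


class MeshError(ValueError):
    pass


class IsoLevelError(MeshError):
    """The requested iso level is outside the volume's intensity range."""


@dataclass
class SurfaceMesh:
    """Triangle mesh in physical units (um)."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int
    iso_level: Optional[float] = None  # absent for imported meshes

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError(f"triangles must be (m, 3), got {self.triangles.shape}")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinates")
        if len(self.triangles):
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise MeshError("triangle indices out of range")
            v = self.vertices[self.triangles]
            degenerate = np.all(v[:, 0] == v[:, 1], axis=1) & np.all(
                v[:, 1] == v[:, 2], axis=1
            )
            if degenerate.any():
                raise MeshError(f"{int(degenerate.sum())} degenerate triangles")

    @property
    def area(self) -> float:
        """Total surface area (um^2)."""
        return float(
            measure.mesh_surface_area(self.vertices, self.triangles)
        )

    def connected_component_count(self) -> int:
        n = len(self.vertices)
        if n == 0:
            return 0
        i = np.concatenate([self.triangles[:, 0], self.triangles[:, 1], self.triangles[:, 2]])
        j = np.concatenate([self.triangles[:, 1], self.triangles[:, 2], self.triangles[:, 0]])
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=False)
        return int(n_comp)


def extract_isosurface(volume: VoxelVolume, iso_level: float) -> SurfaceMesh:
    """Marching-cubes surface at ``iso_level``, in physical coordinates.

    Vertex coordinates are voxel index x spacing, in (z, y, x) order matching
    the volume's axis convention.  Faces are consistently oriented with
    outward (descending-gradient) normals.
    """
    volume.validate()
    lo, hi = volume.intensity_range
    if not lo < iso_level < hi:
        raise IsoLevelError(
            f"iso level {iso_level} outside the open intensity range ({lo}, {hi})"
        )
    verts, faces, _, _ = measure.marching_cubes(
        volume.data.astype(np.float64), level=iso_level, spacing=volume.spacing
    )
    # marching cubes occasionally emits collapsed (zero-area) facets when the
    # level coincides with voxel values; drop them
    v = verts[faces]
    collapsed = np.all(v[:, 0] == v[:, 1], axis=1) & np.all(v[:, 1] == v[:, 2], axis=1)
    faces = faces[~collapsed]
    mesh = SurfaceMesh(vertices=verts, triangles=faces, iso_level=float(iso_level))
    mesh.validate()
    return mesh


def write_stl(mesh: SurfaceMesh, path) -> None:
    """Binary STL, one facet per triangle, normals recomputed from winding."""
    mesh.validate()
    if len(mesh.triangles) == 0:
        raise MeshError("refusing to write an empty mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(str(path), file_type="stl")


def read_stl(path) -> SurfaceMesh:
    """Read binary or ASCII STL; repeated facet vertices are deduplicated."""
    try:
        tm = trimesh.load(str(path), file_type="stl", process=True)
    except Exception as e:  # trimesh raises a mix of exception types
        raise MeshError(f"{path}: cannot parse STL ({e})") from e
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshError(f"{path}: no triangles found")
    mesh = SurfaceMesh(vertices=np.asarray(tm.vertices), triangles=np.asarray(tm.faces))
    mesh.validate()
    return mesh
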