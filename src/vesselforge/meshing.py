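"""Iso-surface extraction and printability validation of the model mask.

The {0, 255} model mask is surfaced with marching cubes at iso-level 128 —
the midpoint of the binary scale, so the surface bisects every voxel edge
between a 0 and a 255 voxel.  Vertices are scaled by the per-axis voxel
spacing and offset by the grid origin, giving millimetre coordinates (STL
is unitless; slicers assume mm).  The mask is padded with one background
voxel on every side before extraction so surfaces touching the grid edge
still close: watertightness is non-negotiable for printing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .grid import BinaryMask

__all__ = ["MeshConfig", "MeshReport", "extract_surface", "validate_mesh", "mesh_summary"]


@dataclass
class MeshConfig:
    """Surface-extraction parameters.

    ``iso_level`` lives on the 0–255 mask scale (default 128, the
    midpoint); ``pad_voxels`` is the background border added before
    extraction; ``smoothing_iterations`` applies optional Taubin
    smoothing (off by default — layer steps are accepted, as in the
    original fabrication workflow).
    """

    iso_level: float = 128.0
    pad_voxels: int = 1
    smoothing_iterations: int = 0

    def __post_init__(self):
        if not (0.0 < self.iso_level < 255.0):
            raise ValueError(
                f"iso_level must lie strictly inside (0, 255), got {self.iso_level}"
            )
        if self.pad_voxels < 0:
            raise ValueError("pad_voxels must be >= 0")
        if self.smoothing_iterations < 0:
            raise ValueError("smoothing_iterations must be >= 0")


@dataclass
class MeshReport:
    """Printability and geometry summary of a triangle mesh."""

    watertight: bool
    manifold: bool
    consistently_oriented: bool
    component_count: int
    enclosed_volume_mm3: float
    surface_area_mm2: float
    bounding_box_mm: tuple[float, float, float]
    triangle_count: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bounding_box_mm"] = list(self.bounding_box_mm)
        return d


def extract_surface(mask: BinaryMask, cfg: MeshConfig | None = None) -> trimesh.Trimesh:
    """Marching-cubes surface of a {0,255} mask in physical mm coordinates.

    Returns a watertight, consistently outward-oriented
    :class:`trimesh.Trimesh` with vertices in (x, y, z) mm.
    """
    cfg = cfg or MeshConfig()
    if mask.count() == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    pad = int(cfg.pad_voxels)
    field = np.pad(mask.data.astype(np.float32), pad, constant_values=0.0)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=float(cfg.iso_level), spacing=mask.spacing
    )
    # back to physical coordinates: undo the padding offset, add the origin,
    # and reorder (z, y, x) -> (x, y, z); the axis swap mirrors the mesh, so
    # the winding is flipped to restore outward orientation
    verts = verts - pad * np.asarray(mask.spacing) + np.asarray(mask.origin)
    verts = verts[:, ::-1]
    faces = faces[:, ::-1]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    if cfg.smoothing_iterations > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=cfg.smoothing_iterations)
    return mesh


def validate_mesh(mesh: trimesh.Trimesh) -> MeshReport:
    """Edge-manifoldness, orientation, components, signed volume, area.

    The enclosed volume is the divergence-theorem signed volume; it is
    meaningful (and non-negative for an outward-oriented solid) only when
    the mesh is watertight and consistently oriented — the report carries
    the flags rather than raising.
    """
    if len(mesh.faces) == 0:
        raise ValueError("cannot validate an empty mesh")
    edges = mesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    manifold = bool(np.all(counts == 2))
    extents = mesh.extents if len(mesh.vertices) else np.zeros(3)
    return MeshReport(
        watertight=bool(mesh.is_watertight),
        manifold=manifold,
        consistently_oriented=bool(mesh.is_winding_consistent),
        component_count=int(mesh.body_count),
        enclosed_volume_mm3=float(mesh.volume),
        surface_area_mm2=float(mesh.area),
        bounding_box_mm=tuple(float(e) for e in extents),
        triangle_count=int(len(mesh.faces)),
    )


def mesh_summary(
    mesh: trimesh.Trimesh, pitch_mm: float | None = None
) -> tuple[float, tuple[float, float, float]]:
    """Largest inscribed-sphere-style diameter and axis-aligned extents (mm).

    The diameter is estimated by voxelizing the watertight solid and taking
    twice the maximum interior Euclidean distance to the surface; for a
    non-watertight mesh it falls back to the largest bounding-box extent.
    """
    if len(mesh.faces) == 0:
        raise ValueError("cannot summarise an empty mesh")
    extents = tuple(float(e) for e in mesh.extents)
    if not mesh.is_watertight or mesh.volume <= 0:
        return max(extents), extents
    if pitch_mm is None:
        pitch_mm = max(max(extents) / 64.0, 0.25)
    vox = mesh.voxelized(pitch=pitch_mm).fill()
    interior = np.asarray(vox.matrix, dtype=bool)
    if not interior.any():
        return max(extents), extents
    dist = ndimage.distance_transform_edt(
        np.pad(interior, 1, constant_values=False), sampling=pitch_mm
    )
    # voxel centres sit up to half a pitch from the true surface
    diameter = 2.0 * float(dist.max()) + pitch_mm
    return diameter, extents
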