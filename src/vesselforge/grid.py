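"""Common voxel-grid containers.

Axis convention (used everywhere in this package): array axis 0 is the
slice direction (scanner z), axes 1 and 2 are the in-plane row (y) and
column (x) directions.  ``spacing`` and ``origin`` follow the same
(slice, row, column) order, in millimetres.  The physical position of
voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Mapping of array axes to physical directions, fixed package-wide.
AXIS_ORDER = ("slice (z)", "row (y)", "column (x)")


class GridError(ValueError):
    """Raised when a volume or mask violates a grid invariant."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3:
        raise GridError(f"spacing must have 3 components, got {len(s)}")
    if any(not np.isfinite(v) or v <= 0 for v in s):
        raise GridError(f"spacing components must be finite and > 0, got {s}")
    return s


def _as_origin(origin) -> tuple[float, float, float]:
    o = tuple(float(v) for v in origin)
    if len(o) != 3:
        raise GridError(f"origin must have 3 components, got {len(o)}")
    if any(not np.isfinite(v) for v in o):
        raise GridError(f"origin components must be finite, got {o}")
    return o


@dataclass
class ImageVolume:
    """A 3D scalar image in Hounsfield units on a regular anisotropic grid.

    Parameters
    ----------
    data :
        3D array of HU values, axis order (slice, row, column).
    spacing :
        Voxel size in mm per axis, same order as ``data`` axes.
    origin :
        Physical position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise GridError("volume data contains non-finite values")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def physical_coordinates(self, index) -> np.ndarray:
        """Physical position (mm) of voxel ``index`` = origin + index * spacing."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-centre physical coordinates (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def same_grid(self, other: "ImageVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class BinaryMask:
    """A {0, 255} occupancy mask sharing the grid of its source volume.

    255 marks occupied voxels (lumen or printable solid), 0 background —
    the two-level convention the downstream surface renderer consumes,
    with iso-level 128 as its midpoint.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise GridError(f"mask data must be 3D, got shape {arr.shape}")
        if not np.isin(arr, (0, 255)).all():
            bad = np.unique(arr[~np.isin(arr, (0, 255))])[:5]
            raise GridError(f"mask values must be 0 or 255, found {bad}")
        self.data = arr.astype(np.uint8)
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @classmethod
    def from_bool(cls, occupancy: np.ndarray, like: "ImageVolume | BinaryMask") -> "BinaryMask":
        """Build a mask from a boolean array on the grid of ``like``."""
        occupancy = np.asarray(occupancy, dtype=bool)
        if occupancy.shape != like.shape:
            raise GridError(
                f"occupancy shape {occupancy.shape} != grid shape {like.shape}"
            )
        return cls(
            data=np.where(occupancy, 255, 0).astype(np.uint8),
            spacing=like.spacing,
            origin=like.origin,
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def bool_array(self) -> np.ndarray:
        return self.data == 255

    def count(self) -> int:
        """Number of occupied (255) voxels."""
        return int(np.count_nonzero(self.data))

    def volume_mm3(self) -> float:
        return self.count() * self.voxel_volume_mm3

    def same_grid(self, other: "ImageVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "ImageVolume | BinaryMask") -> None:
        if not self.same_grid(other):
            raise GridError(
                f"grid mismatch: shape {self.shape} spacing {self.spacing} origin "
                f"{self.origin} vs shape {other.shape} spacing {other.spacing} "
                f"origin {other.origin}"
            )
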