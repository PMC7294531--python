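"""Turn a lumen mask into a printable hollow model.

The paper-faithful construction is the *block complement*: binarize the
lumen, invert it, and bound the result to a solid block around the lumen —
a printable brick whose internal cavity reproduces the vessel and aneurysm.
A thin *shell* mode (a wall of fixed physical thickness grown around the
lumen by Euclidean distance transform) is provided as the common
alternative.  Ports then open the cavity to the exterior so a sheath can
be connected and the model filled with saline; a sealed channel is
unprintable and unusable, so at least one port is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, GridError

__all__ = [
    "HollowConfig",
    "Port",
    "invert_mask",
    "make_block_complement",
    "make_shell",
    "open_ports",
    "conform_mask",
]

_AXIS_BY_NAME = {"z": 0, "y": 1, "x": 2}


@dataclass(frozen=True)
class Port:
    """An opening of the cavity to the exterior.

    ``seed`` is a voxel index on the lumen; ``direction`` is an axis-aligned
    direction string (``"+z"``, ``"-z"``, ``"+y"``, ``"-y"``, ``"+x"``,
    ``"-x"``) along which the local lumen cross-section is extruded to the
    outer face of the solid.
    """

    seed: tuple[int, int, int]
    direction: str

    def __post_init__(self):
        object.__setattr__(self, "seed", tuple(int(v) for v in self.seed))
        d = self.direction.lower().strip()
        if len(d) != 2 or d[0] not in "+-" or d[1] not in _AXIS_BY_NAME:
            raise ValueError(
                f"port direction must be one of +z -z +y -y +x -x, got {self.direction!r}"
            )
        object.__setattr__(self, "direction", d)

    @property
    def axis(self) -> int:
        return _AXIS_BY_NAME[self.direction[1]]

    @property
    def sign(self) -> int:
        return 1 if self.direction[0] == "+" else -1


@dataclass
class HollowConfig:
    """Hollow-model construction parameters.

    ``block_complement`` (the default, margin 5 mm) is the literal
    inversion of the binarized lumen bounded to a printable block;
    ``shell`` grows a wall of ``wall_thickness_mm`` around the lumen.
    """

    mode: str = "block_complement"
    block_margin_mm: float = 5.0
    wall_thickness_mm: float = 2.0
    ports: tuple[Port, ...] = ()

    def __post_init__(self):
        if self.mode not in ("block_complement", "shell"):
            raise ValueError(f"unknown hollowing mode {self.mode!r}")
        if self.block_margin_mm < 0:
            raise ValueError("block_margin_mm must be >= 0")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be > 0")
        ports = tuple(
            p if isinstance(p, Port) else Port(**p) for p in self.ports
        )
        if len(ports) == 0:
            raise ValueError(
                "at least one port is required: a sealed internal channel "
                "cannot be cleaned of support material or connected to a sheath"
            )
        self.ports = ports


def invert_mask(mask: BinaryMask) -> BinaryMask:
    """Swap 0 and 255 voxel-wise (an involution)."""
    return BinaryMask(
        data=(255 - mask.data).astype(np.uint8),
        spacing=mask.spacing,
        origin=mask.origin,
    )


def _lumen_bbox(lumen: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    occ = lumen.bool_array()
    if not occ.any():
        raise ValueError("lumen mask is empty; nothing to hollow")
    idx = np.nonzero(occ)
    lo = np.array([int(i.min()) for i in idx])
    hi = np.array([int(i.max()) for i in idx])
    return lo, hi


def make_block_complement(lumen: BinaryMask, cfg: HollowConfig) -> BinaryMask:
    """Solid block = (lumen bounding box expanded by the margin) minus lumen.

    If the margin pushes the box past the grid the grid is padded (origin
    shifted accordingly), never truncated.  Mass balance holds exactly:
    |solid| + |lumen| = |expanded box| in voxel counts.
    """
    if cfg.mode != "block_complement":
        raise ValueError(f"config mode is {cfg.mode!r}, not 'block_complement'")
    lo, hi = _lumen_bbox(lumen)
    margin_vox = np.array(
        [int(np.ceil(cfg.block_margin_mm / s)) for s in lumen.spacing]
    )
    box_lo = lo - margin_vox
    box_hi = hi + margin_vox  # inclusive
    shape = np.asarray(lumen.shape)
    pad_before = np.maximum(-box_lo, 0)
    pad_after = np.maximum(box_hi - (shape - 1), 0)
    occ = lumen.bool_array()
    if pad_before.any() or pad_after.any():
        occ = np.pad(
            occ,
            tuple((int(b), int(a)) for b, a in zip(pad_before, pad_after)),
            constant_values=False,
        )
        origin = tuple(
            lumen.origin[a] - pad_before[a] * lumen.spacing[a] for a in range(3)
        )
        box_lo = box_lo + pad_before
        box_hi = box_hi + pad_before
    else:
        origin = lumen.origin
    solid = np.zeros(occ.shape, dtype=bool)
    sl = tuple(slice(int(l), int(h) + 1) for l, h in zip(box_lo, box_hi))
    solid[sl] = True
    solid &= ~occ
    return BinaryMask(
        data=np.where(solid, 255, 0).astype(np.uint8),
        spacing=lumen.spacing,
        origin=origin,
    )


def make_shell(lumen: BinaryMask, cfg: HollowConfig) -> BinaryMask:
    """Wall of ``wall_thickness_mm`` grown around the lumen.

    The dilation is a Euclidean distance-transform threshold with the voxel
    spacing as sampling, so anisotropic voxels still give a physically
    uniform wall in every direction.
    """
    if cfg.mode != "shell":
        raise ValueError(f"config mode is {cfg.mode!r}, not 'shell'")
    if cfg.wall_thickness_mm < max(lumen.spacing):
        warnings.warn(
            f"wall thickness {cfg.wall_thickness_mm} mm is below the largest "
            f"voxel spacing {max(lumen.spacing)} mm; the wall may be "
            "discontinuous",
            stacklevel=2,
        )
    occ = lumen.bool_array()
    if not occ.any():
        raise ValueError("lumen mask is empty; nothing to hollow")
    dist = ndimage.distance_transform_edt(~occ, sampling=lumen.spacing)
    shell = (dist > 0) & (dist <= cfg.wall_thickness_mm)
    return BinaryMask.from_bool(shell, like=lumen)


def conform_mask(mask: BinaryMask, like: BinaryMask) -> BinaryMask:
    """Embed ``mask`` into the (possibly padded) grid of ``like``.

    Grids must share spacing and differ only by a whole-voxel origin shift;
    used to carry the lumen onto the padded grid of a block complement.
    """
    if not np.allclose(mask.spacing, like.spacing):
        raise GridError("conform_mask requires identical spacing")
    offset_f = (np.asarray(mask.origin) - np.asarray(like.origin)) / np.asarray(
        mask.spacing
    )
    offset = np.round(offset_f).astype(int)
    if not np.allclose(offset_f, offset, atol=1e-6):
        raise GridError("grids are not aligned by a whole-voxel shift")
    out = np.zeros(like.shape, dtype=bool)
    sl_out, sl_in = [], []
    for a in range(3):
        lo = int(offset[a])
        hi = lo + mask.shape[a]
        if lo < 0 or hi > like.shape[a]:
            raise GridError("mask does not fit inside the target grid")
        sl_out.append(slice(lo, hi))
    out[tuple(sl_out)] = mask.bool_array()
    return BinaryMask.from_bool(out, like=like)


def _port_cross_section(lumen2d: np.ndarray, seed2d: tuple[int, int]) -> np.ndarray:
    """8-connected in-plane lumen region containing the seed."""
    labels, _ = ndimage.label(lumen2d, structure=np.ones((3, 3), dtype=bool))
    lab = labels[seed2d]
    if lab == 0:
        raise ValueError(f"port seed {seed2d} is not on lumen in its slice")
    return labels == lab


def open_ports(solid: BinaryMask, lumen: BinaryMask, cfg: HollowConfig) -> BinaryMask:
    """Extrude the lumen cross-section at each port seed to the outer face.

    Voxels along the extrusion are cleared from the solid, so an
    exterior-connected flood fill reaches the cavity.  Connectivity is
    verified and a failure raises.
    """
    solid.require_same_grid(lumen)
    out = solid.bool_array().copy()
    lum = lumen.bool_array()
    for port in cfg.ports:
        seed = port.seed
        if any(not (0 <= seed[a] < lumen.shape[a]) for a in range(3)):
            raise GridError(f"port seed {seed} outside grid {lumen.shape}")
        if not lum[seed]:
            raise ValueError(f"port seed {seed} is not inside the lumen")
        axis = port.axis
        plane = [slice(None)] * 3
        plane[axis] = seed[axis]
        seed2d = tuple(seed[a] for a in range(3) if a != axis)
        section = _port_cross_section(lum[tuple(plane)], seed2d)
        if port.sign > 0:
            span = range(seed[axis], solid.shape[axis])
        else:
            span = range(seed[axis], -1, -1)
        for pos in span:
            sl = [slice(None)] * 3
            sl[axis] = pos
            view = out[tuple(sl)]
            view[section] = False
    result = BinaryMask.from_bool(out, like=solid)
    _verify_exterior_connectivity(result, cfg)
    return result


def _verify_exterior_connectivity(solid: BinaryMask, cfg: HollowConfig) -> None:
    """Flood fill from outside the solid must reach every port seed."""
    free = ~solid.bool_array()
    padded = np.pad(free, 1, constant_values=True)
    labels, _ = ndimage.label(padded, structure=np.ones((3, 3, 3), dtype=bool))
    exterior = labels[0, 0, 0]
    for port in cfg.ports:
        s = tuple(np.asarray(port.seed) + 1)
        if labels[s] != exterior:
            raise ValueError(
                f"port at {port.seed} failed to connect the cavity to the "
                "exterior (direction never reaches the outer face?)"
            )
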