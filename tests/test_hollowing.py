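"""Inversion, block-complement and shell hollowing, port opening."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from vesselforge import (
    BinaryMask,
    HollowConfig,
    ImageVolume,
    Port,
    generate_phantom,
    invert_mask,
    make_block_complement,
    make_shell,
    open_ports,
)
from vesselforge.hollowing import conform_mask

DUMMY_PORT = Port(seed=(0, 0, 0), direction="+x")


def _mask(occ, spacing=(1.0, 1.0, 1.0)):
    vol = ImageVolume(np.zeros(occ.shape), spacing=spacing)
    return BinaryMask.from_bool(np.asarray(occ, dtype=bool), like=vol)


class TestInvert:
    def test_involution_on_random_masks(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            mask = _mask(rng.random((4, 5, 4)) < rng.uniform(0.1, 0.9))
            back = invert_mask(invert_mask(mask))
            np.testing.assert_array_equal(back.data, mask.data)

    def test_all_occupied_inverts_to_empty(self):
        mask = _mask(np.ones((3, 3, 3), dtype=bool))
        assert invert_mask(mask).count() == 0

    def test_counting_identity(self):
        rng = np.random.default_rng(3)
        mask = _mask(rng.random((5, 5, 5)) < 0.4)
        assert invert_mask(mask).count() == mask.data.size - mask.count()

    def test_codomain(self):
        mask = _mask(np.zeros((2, 2, 2), dtype=bool))
        assert set(np.unique(invert_mask(mask).data)) <= {0, 255}


class TestBlockComplement:
    def test_solid_and_lumen_are_disjoint(self):
        rng = np.random.default_rng(4)
        lumen = _mask(rng.random((8, 8, 8)) < 0.2)
        cfg = HollowConfig(block_margin_mm=2.0, ports=(DUMMY_PORT,))
        solid = make_block_complement(lumen, cfg)
        lumen_c = conform_mask(lumen, solid)
        assert not (solid.bool_array() & lumen_c.bool_array()).any()

    def test_single_voxel_zero_margin(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        cfg = HollowConfig(block_margin_mm=0.0, ports=(DUMMY_PORT,))
        solid = make_block_complement(_mask(occ), cfg)
        # box degenerates to the single lumen voxel: solid is empty
        assert solid.count() == 0

    def test_mass_balance(self):
        rng = np.random.default_rng(5)
        occ = np.zeros((10, 10, 10), dtype=bool)
        occ[3:7, 3:7, 3:7] = rng.random((4, 4, 4)) < 0.6
        occ[4, 4, 4] = True
        lumen = _mask(occ)
        cfg = HollowConfig(block_margin_mm=2.0, ports=(DUMMY_PORT,))
        solid = make_block_complement(lumen, cfg)
        lo = np.argwhere(occ).min(axis=0) - 2
        hi = np.argwhere(occ).max(axis=0) + 2
        box_count = int(np.prod(hi - lo + 1))
        assert solid.count() + lumen.count() == box_count

    def test_margin_pads_grid_instead_of_truncating(self):
        occ = np.zeros((4, 4, 4), dtype=bool)
        occ[0, 0, 0] = True
        lumen = _mask(occ)
        cfg = HollowConfig(block_margin_mm=3.0, ports=(DUMMY_PORT,))
        solid = make_block_complement(lumen, cfg)
        assert solid.shape == (7, 7, 7)
        assert solid.origin == (-3.0, -3.0, -3.0)
        assert solid.count() + lumen.count() == 7**3


class TestShell:
    def test_shell_disjoint_from_lumen_and_thickness(self):
        """Measured wall thickness (distance transform) within one voxel of
        the requested physical thickness on a straight tube."""
        occ = np.zeros((9, 21, 30), dtype=bool)
        zz, yy = np.mgrid[0:9, 0:21]
        tube2d = (zz - 4) ** 2 + (yy - 10) ** 2 <= 3.0**2
        occ[:, :, :] = tube2d[:, :, None]
        lumen = _mask(occ)
        cfg = HollowConfig(mode="shell", wall_thickness_mm=3.0, ports=(DUMMY_PORT,))
        shell = make_shell(lumen, cfg)
        assert not (shell.bool_array() & lumen.bool_array()).any()
        dist = ndimage.distance_transform_edt(~lumen.bool_array(), sampling=(1, 1, 1))
        covered = dist[shell.bool_array()]
        assert covered.max() <= 3.0
        # every lumen-boundary voxel has solid within thickness + 1 voxel
        boundary = lumen.bool_array() & ~ndimage.binary_erosion(lumen.bool_array())
        dist_to_shell = ndimage.distance_transform_edt(~shell.bool_array())
        assert dist_to_shell[boundary].max() <= 3.0 + 1.0

    def test_anisotropic_shell_is_physically_uniform(self):
        occ = np.zeros((15, 31, 20), dtype=bool)
        occ[7, 15, :] = True  # 1-voxel filament along x
        lumen = _mask(occ, spacing=(2.0, 1.0, 1.0))
        cfg = HollowConfig(mode="shell", wall_thickness_mm=6.0, ports=(DUMMY_PORT,))
        shell = make_shell(lumen, cfg)
        sl = shell.bool_array()[:, :, 10]
        z_extent = np.ptp(np.nonzero(sl.any(axis=1))[0]) * 2.0
        y_extent = np.ptp(np.nonzero(sl.any(axis=0))[0]) * 1.0
        assert abs(z_extent - y_extent) <= 2.0  # equal in mm within a voxel

    def test_thin_wall_warns(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        cfg = HollowConfig(mode="shell", wall_thickness_mm=0.4, ports=(DUMMY_PORT,))
        with pytest.warns(UserWarning, match="discontinuous"):
            make_shell(_mask(occ, spacing=(1.0, 1.0, 1.0)), cfg)


class TestConfig:
    def test_zero_ports_rejected(self):
        with pytest.raises(ValueError, match="at least one port"):
            HollowConfig(ports=())

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            Port(seed=(0, 0, 0), direction="up")

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            HollowConfig(mode="swiss_cheese", ports=(DUMMY_PORT,))


class TestOpenPorts:
    def _tube_setup(self):
        occ = np.zeros((11, 11, 20), dtype=bool)
        zz, yy = np.mgrid[0:11, 0:11]
        tube2d = (zz - 5) ** 2 + (yy - 5) ** 2 <= 2.5**2
        occ[:, :, 2:18] = tube2d[:, :, None]
        lumen = _mask(occ)
        cfg = HollowConfig(
            block_margin_mm=3.0,
            ports=(Port(seed=(5, 5, 2), direction="-x"),),
        )
        solid = make_block_complement(lumen, cfg)
        lumen_c = conform_mask(lumen, solid)
        # block pads the grid by the margin; shift the port seed to match
        offset = np.round(
            (np.asarray(lumen.origin) - np.asarray(solid.origin))
        ).astype(int)
        cfg2 = HollowConfig(
            block_margin_mm=3.0,
            ports=tuple(
                Port(seed=tuple(np.asarray(p.seed) + offset), direction=p.direction)
                for p in cfg.ports
            ),
        )
        return solid, lumen_c, cfg2

    def test_exterior_flood_fill_reaches_cavity(self):
        solid, lumen, cfg = self._tube_setup()
        opened = open_ports(solid, lumen, cfg)
        free = ~opened.bool_array()
        padded = np.pad(free, 1, constant_values=True)
        labels, _ = ndimage.label(padded, structure=np.ones((3, 3, 3), dtype=bool))
        exterior = labels[0, 0, 0]
        cavity = np.pad(lumen.bool_array(), 1)
        assert np.all(labels[cavity] == exterior), "sealed pocket remains"

    def test_sealed_block_has_no_exterior_path(self):
        solid, lumen, cfg = self._tube_setup()
        free = ~solid.bool_array()
        padded = np.pad(free, 1, constant_values=True)
        labels, _ = ndimage.label(padded, structure=np.ones((3, 3, 3), dtype=bool))
        exterior = labels[0, 0, 0]
        cavity = np.pad(lumen.bool_array(), 1)
        assert not np.any(labels[cavity] == exterior)

    def test_port_channel_cross_section_matches_lumen(self):
        solid, lumen, cfg = self._tube_setup()
        opened = open_ports(solid, lumen, cfg)
        seed = cfg.ports[0].seed
        section = lumen.bool_array()[:, :, seed[2]]
        for x in range(0, seed[2]):
            # every voxel of the extruded cross-section is free of solid
            assert not opened.bool_array()[:, :, x][section].any()
            # and nothing outside the cross-section was carved away
            carved = solid.bool_array()[:, :, x] & ~opened.bool_array()[:, :, x]
            assert not (carved & ~section).any()

    def test_seed_outside_lumen_rejected(self):
        solid, lumen, _ = self._tube_setup()
        bad = HollowConfig(ports=(Port(seed=(0, 0, 0), direction="-x"),))
        with pytest.raises(ValueError, match="not inside the lumen"):
            open_ports(solid, lumen, bad)


def test_phantom_block_model_has_connected_cavity(tube_spec):
    """End to end on a tube phantom: after opening ports the whole cavity
    is reachable from outside (no sealed pockets)."""
    spec = dataclasses.replace(tube_spec)
    _, truth = generate_phantom(spec)
    lumen = truth.lumen_mask
    seed = tuple(int(round(c)) for c in spec.centerline[0])
    cfg = HollowConfig(
        block_margin_mm=4.0,
        ports=(
            Port(seed=seed, direction="-x"),
            Port(seed=tuple(int(round(c)) for c in spec.centerline[-1]), direction="+x"),
        ),
    )
    solid = make_block_complement(lumen, cfg)
    lumen_c = conform_mask(lumen, solid)
    offset = np.round(
        (np.asarray(lumen.origin) - np.asarray(solid.origin)) / np.asarray(lumen.spacing)
    ).astype(int)
    cfg2 = HollowConfig(
        block_margin_mm=4.0,
        ports=tuple(
            Port(seed=tuple(np.asarray(p.seed) + offset), direction=p.direction)
            for p in cfg.ports
        ),
    )
    opened = open_ports(solid, lumen_c, cfg2)
    free = np.pad(~opened.bool_array(), 1, constant_values=True)
    labels, _ = ndimage.label(free, structure=np.ones((3, 3, 3), dtype=bool))
    exterior = labels[0, 0, 0]
    assert np.all(labels[np.pad(lumen_c.bool_array(), 1)] == exterior)
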