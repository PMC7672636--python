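"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

from rpe3d import (CompartmentKind, LabelTable, LabelVolume, VoxelSpacing,
                   PhantomSpec, generate_phantom)


def make_table(entries):
    """entries: {label: (cell_id, kind-name)}"""
    return LabelTable({lab: (cell, CompartmentKind(kind))
                       for lab, (cell, kind) in entries.items()})


@pytest.fixture(scope="session")
def em_spacing():
    """The acquisition-like anisotropic spacing: 8 nm in-plane, 50 nm sections."""
    return VoxelSpacing(dx=8.0, dy=8.0, dz=50.0)


@pytest.fixture(scope="session")
def iso50():
    return VoxelSpacing(50.0, 50.0, 50.0)


@pytest.fixture(scope="session")
def cuboid_pair(em_spacing):
    """Two 20(x)×20(y)×10(z)-voxel cuboids abutting on a flat x-facing
    interface: the analytic shared-area fixture (0.0800 µm² corrected)."""
    grid = np.zeros((10, 20, 40), dtype=np.uint16)
    grid[:, :, :20] = 1
    grid[:, :, 20:] = 2
    table = make_table({1: ("a", "cell_body"), 2: ("b", "cell_body")})
    return LabelVolume(grid=grid, spacing=em_spacing, table=table)


@pytest.fixture(scope="session")
def tiny_phantom_spec():
    """A one-cell phantom small enough for per-test use, with every object
    class present."""
    return PhantomSpec(
        n_cells_x=1, n_cells_z=1, cell_width=6.0, cell_body_height=4.0,
        nucleus_semiaxes=(1.5, 1.2, 1.5), rods_per_cell=6, os_per_cell=4,
        microvilli_length=3.0, os_length=3.5, os_lift=0.8,
        infold_pockets_per_cell=2, pocket_radius=0.4,
        mito_per_cell=20, mito_semiaxes=(0.3, 0.2, 0.2), seed=1)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_phantom_spec):
    return generate_phantom(tiny_phantom_spec)


@pytest.fixture(scope="session")
def row_phantom():
    """Three bare cuboidal cells in a row (no shear, no organelles):
    cell–cell interfaces are flat x-facing planes of analytic area h·w."""
    spec = PhantomSpec(
        n_cells_x=3, n_cells_z=1, cell_width=5.0, cell_body_height=4.0,
        shear_angle=0.0, nucleus_semiaxes=(1.2, 1.2, 1.2),
        rods_per_cell=0, os_per_cell=0, infold_pockets_per_cell=0,
        mito_per_cell=0, seed=3)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def grid_phantom():
    """A 2×2 monolayer of bare cells (edge-sharing adjacency only)."""
    spec = PhantomSpec(
        n_cells_x=2, n_cells_z=2, cell_width=5.0, cell_body_height=4.0,
        shear_angle=8.0, nucleus_semiaxes=(1.2, 1.2, 1.2),
        rods_per_cell=0, os_per_cell=0, infold_pockets_per_cell=0,
        mito_per_cell=0, seed=4)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def hex_volume(iso50):
    """Seven cells hexagonally packed in-plane (Voronoi prisms): the centre
    cell touches all six neighbours."""
    centers = [(0.0, 0.0)]
    r = 3.0
    for k in range(6):
        ang = np.pi / 3 * k
        centers.append((r * np.cos(ang), r * np.sin(ang)))
    nx_, nz = 200, 200
    xs = (np.arange(nx_) + 0.5) * 0.05 - 5.0
    zs = (np.arange(nz) + 0.5) * 0.05 - 5.0
    X, Z = np.meshgrid(xs, zs)  # (z, x)
    d2 = np.stack([(X - cx) ** 2 + (Z - cz) ** 2 for cx, cz in centers])
    nearest = np.argmin(d2, axis=0) + 1
    grid = np.zeros((nz, 12, nx_), dtype=np.uint16)
    grid[:, 2:10, :] = nearest[:, None, :].astype(np.uint16)
    table = make_table({i + 1: (f"c{i}", "cell_body") for i in range(7)})
    return LabelVolume(grid=grid, spacing=iso50, table=table)
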