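"""Shared fixtures: analytic shapes and small phantoms, session-cached."""

import numpy as np
import pytest
import trimesh

import fetalmorph as fm


def icosphere_mesh(radius=10.0, subdivisions=3) -> fm.SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return fm.SurfaceMesh(np.asarray(ico.vertices, float),
                          np.asarray(ico.faces, np.int64))


@pytest.fixture(scope="session")
def sphere10():
    """Icosphere R=10 mm, 3 subdivisions (642 vertices)."""
    return icosphere_mesh(10.0, 3)


@pytest.fixture(scope="session")
def sphere10_fine():
    """Icosphere R=10 mm, 4 subdivisions (2562 vertices)."""
    return icosphere_mesh(10.0, 4)


@pytest.fixture(scope="session")
def default_spec():
    return fm.PhantomSpec()


@pytest.fixture(scope="session")
def smooth_spec():
    """Unfolded ellipsoid phantom (analytic volume available)."""
    return fm.PhantomSpec(fold_amplitude=0.0, semi_axes=(30.0, 25.0, 20.0))


@pytest.fixture(scope="session")
def phantom_volume(default_spec):
    """Voxelized default phantom at 0.8 mm with its truth (slow; shared)."""
    return fm.generate_phantom(default_spec)


@pytest.fixture(scope="session")
def voxel_sphere():
    """Sphere r=10 mm voxelized at 0.5 mm as a LabelVolume."""
    spacing = 0.5
    n = int(np.ceil(24 / spacing))
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
    inside = (g ** 2).sum(-1) <= 100.0
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    affine[:3, 3] = ax[0]  # voxel (0,0,0) center at the grid corner
    return fm.LabelVolume(inside.astype(np.int16), affine,
                          {"background": 0, "unmyelinated_wm": 1})


@pytest.fixture(scope="session")
def phantom_pair():
    """Longitudinal phantom pair with ~10% volume growth and fold increase
    over 2 weeks; truth surfaces only (no voxelization)."""
    spec = fm.PhantomSpec(fold_amplitude=2.0, seed=11)
    truth0 = fm.generate_longitudinal_pair(
        spec, {"unmyelinated_wm": 3000.0, "ventricles": 300.0},
        fold_increase_per_week=0.25, delta_ga=2.0,
        subdivisions=3, voxelize=False)
    return truth0
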