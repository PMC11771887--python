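"""Shared fixtures: synthetic single-cell meshes and small generated shells."""

import numpy as np
import pytest

from organoidvm import shell_builder as sb


def make_cube_cell(origin=(0.0, 0.0, 0.0), scale=1.0):
    """A single cubic cell: top face apical, bottom basal, four lateral sides.

    All faces oriented outward from the cell.  Synthetic fixture: a real
    organoid cell is a spherical prism, but the cube's areas and volume are
    exact, which makes it the reference object for measure operations.
    """
    o = np.asarray(origin, dtype=float)
    verts = o + scale * np.array([
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ], dtype=float)
    faces = [
        np.array([4, 5, 6, 7]),   # apical (top, +z)
        np.array([0, 3, 2, 1]),   # basal (bottom, -z)
        np.array([0, 4, 7, 3]),   # lateral -x
        np.array([1, 2, 6, 5]),   # lateral +x
        np.array([0, 1, 5, 4]),   # lateral -y
        np.array([3, 7, 6, 2]),   # lateral +y
    ]
    return sb.OrganoidMesh(
        vertices=verts,
        vertex_layer=np.array(["apical"] * 8),
        faces=faces,
        face_type=np.array(["apical", "basal", "lateral", "lateral",
                            "lateral", "lateral"]),
        face_cells=[(0,)] * 6,
        cells=[np.arange(6)],
        cell_seed=np.array([0]),
        seed_directions=np.array([[0.0, 0.0, 1.0]]),
        lumen_point=verts.mean(axis=0),
    )


@pytest.fixture
def cube_cell():
    return make_cube_cell()


@pytest.fixture(scope="session")
def shell12():
    """Jitter-free 12-cell shell."""
    return sb.generate_organoid(sb.SeedConfig(
        n_seeds=12, jitter_sigma=0.0, rng_seed=0,
        radius_basal=100.0, thickness_ratio=0.2))


@pytest.fixture(scope="session")
def shell20():
    """Small jittered shell for energy/gradient checks."""
    return sb.generate_organoid(sb.SeedConfig(
        n_seeds=20, jitter_sigma=0.1, rng_seed=3,
        radius_basal=10.0, thickness_ratio=0.25))


@pytest.fixture(scope="session")
def shell50():
    """Mid-size jittered shell for pipeline-level checks."""
    return sb.generate_organoid(sb.SeedConfig(
        n_seeds=50, jitter_sigma=0.2, rng_seed=1,
        radius_basal=100.0, thickness_ratio=0.25))
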