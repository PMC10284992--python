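"""Shared fixtures: small deterministic meshes and the default synthetic run."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import Delaunay

from meshflow import (
    MeshDeformationModel,
    SyntheticScenario,
    TriangleMesh,
    generate_sequence,
)


def random_surface_mesh(seed: int, n: int = 25, z_scale: float = 0.3) -> TriangleMesh:
    """Random connected triangle mesh: Delaunay over random planar points
    with random depth (z ~ z_scale * extent, so neighbourhoods are 3D)."""
    rng = np.random.default_rng(seed)
    pts2 = rng.uniform(0, 10, size=(n, 2))
    tri = Delaunay(pts2)
    z = 100 + rng.uniform(-5, 5, size=n) * z_scale
    vertices = np.column_stack([pts2, z])
    return TriangleMesh(vertices, tri.simplices)


@pytest.fixture
def triangle_mesh() -> TriangleMesh:
    return TriangleMesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        np.array([[0, 1, 2]]),
    )


@pytest.fixture
def grid_mesh_small() -> TriangleMesh:
    from meshflow.synthetic import _grid_mesh

    return _grid_mesh(SyntheticScenario(nx=10, ny=10, n_frames=2))


@pytest.fixture(scope="session")
def default_sequence():
    """The default synthetic scenario (study conditions), generated once."""
    return generate_sequence(SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def default_recovery(default_sequence):
    """Full-method recovery of the default scenario."""
    model = MeshDeformationModel(default_sequence.mesh0)
    return model.run_sequence(default_sequence.frames)


@pytest.fixture(scope="session")
def raw_recovery(default_sequence):
    """Raw scene-flow update baseline on the default scenario."""
    model = MeshDeformationModel(default_sequence.mesh0)
    return model.run_sequence(default_sequence.frames, raw_update=True)
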