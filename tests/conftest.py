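"""Shared fixtures and small independent helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from foldbias.mesh import TriangleMesh
from foldbias.synth import FoldParameters, make_folded_sheet, make_uniform_mesh


def planar_grid_mesh(nx: int, ny: int, spacing: float = 1.0) -> TriangleMesh:
    """Non-periodic rectangular strip mesh (right-angle triangulation)."""
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    verts = np.column_stack(
        [ii.ravel() * spacing, jj.ravel() * spacing, np.zeros(nx * ny)]
    )
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v10 = (i + 1) * ny + j
            v01 = i * ny + j + 1
            v11 = (i + 1) * ny + j + 1
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    return TriangleMesh(verts, np.asarray(faces))


def random_bumpy_mesh(nx: int, ny: int, seed: int = 0) -> TriangleMesh:
    """Planar strip with jittered vertex positions (generic geometry)."""
    mesh = planar_grid_mesh(nx, ny)
    rng = np.random.default_rng(seed)
    verts = mesh.vertices + rng.uniform(-0.25, 0.25, mesh.vertices.shape)
    return TriangleMesh(verts, mesh.faces)


def weighted_pearson_oracle(x, y, w) -> float:
    """Independent weighted-correlation reference (direct formula)."""
    x, y, w = (np.asarray(a, dtype=float) for a in (x, y, w))
    mx = np.sum(w * x) / np.sum(w)
    my = np.sum(w * y) / np.sum(w)
    cov = np.sum(w * (x - mx) * (y - my)) / np.sum(w)
    vx = np.sum(w * (x - mx) ** 2) / np.sum(w)
    vy = np.sum(w * (y - my) ** 2) / np.sum(w)
    return cov / np.sqrt(vx * vy)


SMALL_PARAMS = FoldParameters(grid_n=24, seed=1)


@pytest.fixture(scope="session")
def small_folded():
    """576-vertex folded participant (fast; reused across tests)."""
    return make_folded_sheet(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_uniform():
    return make_uniform_mesh(SMALL_PARAMS)


@pytest.fixture(scope="session")
def default_folded():
    """Full-scale (4096-vertex) folded participant, default parameters."""
    return make_folded_sheet(FoldParameters(seed=1))


@pytest.fixture(scope="session")
def default_uniform():
    return make_uniform_mesh(FoldParameters(seed=1))
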