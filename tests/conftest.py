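"""Shared geometric fixtures: analytic surfaces with known curvature and
small handmade meshes with known topology."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from scipy.spatial import Delaunay

from curvalign import TriangleMesh
from curvalign.curvature import CurvatureField


def icosphere(subdivisions=3, radius=1.0) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def plane_grid(extent=10.0, n=21) -> TriangleMesh:
    gx, gy = np.meshgrid(np.linspace(0, extent, n), np.linspace(0, extent, n))
    pts = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=1)
    tri = Delaunay(pts[:, :2])
    return TriangleMesh(pts, tri.simplices)


def cylinder_grid(radius=1.0, height=8.0, n_theta=64, n_z=33) -> TriangleMesh:
    """Open cylinder with interior vertex rings and outward winding."""
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-height / 2, height / 2, n_z)
    T, Z = np.meshgrid(th, z)
    verts = np.stack(
        [radius * np.cos(T).ravel(), radius * np.sin(T).ravel(), Z.ravel()],
        axis=1,
    )
    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriangleMesh(verts, np.array(faces))


def strip_mesh_10() -> TriangleMesh:
    """Two-row, five-column triangulated strip (10 vertices, 8 faces).

    Vertex ids: top row 0-4 at y=1, bottom row 5-9 at y=0.
    """
    top = np.stack([np.arange(5.0), np.ones(5), np.zeros(5)], axis=1)
    bot = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
    verts = np.concatenate([top, bot])
    faces = []
    for c in range(4):
        faces.append([c, 5 + c, c + 1])
        faces.append([c + 1, 5 + c, 5 + c + 1])
    return TriangleMesh(verts, np.array(faces))


def two_peak_field():
    """Field on the 10-vertex strip with peaks 5 (vertex 1) and 3
    (vertex 3) joined through a pass of height 2 (vertex 2)."""
    mesh = strip_mesh_10()
    values = np.array([1.8, 5.0, 2.0, 3.0, 1.7, 1.5, 1.4, 1.3, 1.2, 1.1])
    return CurvatureField(mesh=mesh, radius=1.0, H=values)


def random_field_on(mesh: TriangleMesh, seed: int) -> CurvatureField:
    rng = np.random.default_rng(seed)
    return CurvatureField(
        mesh=mesh, radius=1.0, H=rng.standard_normal(mesh.n_vertices)
    )


@pytest.fixture(scope="session")
def ico3():
    return icosphere(3)


@pytest.fixture(scope="session")
def ico4():
    return icosphere(4)


@pytest.fixture(scope="session")
def plane():
    return plane_grid()


@pytest.fixture(scope="session")
def cylinder():
    return cylinder_grid()


@pytest.fixture(scope="session")
def strip10():
    return strip_mesh_10()


@pytest.fixture(scope="session")
def bumpy6():
    """Six-bump sphere with a generous curvature radius: the canonical
    end-to-end fixture (bump centers are known ground truth)."""
    from curvalign import synthetic

    return synthetic.bumpy_sphere(
        seed=7, radius=10.0, n_bumps=6, bump_height=1.5, bump_sigma=1.5,
        subdivision=3,
    )


@pytest.fixture(autouse=True)
def _quiet_small_radius_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="curvature radius .* spans fewer"
        )
        yield
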