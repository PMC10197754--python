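"""Shared fixtures and independent oracles for the vmesh test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import vmesh as vm
from vmesh import actors as A


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_square():
    """Planar mesh with one unit square, CCW winding."""
    m = vm.Mesh(dim=2)
    ids = [m.add_vertex(p) for p in [(0, 0), (1, 0), (1, 1), (0, 1)]]
    m.add_surface(ids)
    return m


@pytest.fixture
def two_squares():
    """Two unit squares sharing one edge."""
    return vm.generate_sheet(vm.SheetSpec("square", 1, 2))


@pytest.fixture
def unit_cube():
    return vm.generate_cube_lattice(vm.LatticeSpec(1, 1, 1))


def polygon_mesh(coords) -> vm.Mesh:
    """Planar mesh with one surface from a coordinate list."""
    m = vm.Mesh(dim=2)
    ids = [m.add_vertex(p) for p in coords]
    m.add_surface(ids)
    return m


def random_convex_polygon(rng: np.random.Generator, n_min=4, n_max=10) -> np.ndarray:
    """CCW vertices of a random convex polygon (convex hull of random points)."""
    while True:
        pts = rng.normal(0.0, 1.0, (rng.integers(n_min + 2, n_max + 6), 2))
        hull = ConvexHull(pts)
        if len(hull.vertices) >= n_min:
            return pts[hull.vertices]        # hull.vertices is CCW in 2D


def random_convex_polyhedron_mesh(rng: np.random.Generator):
    """Mesh of one body built from the triangular faces of a random hull.

    Returns (mesh, hull) so tests can compare against the hull's own volume
    and area — an oracle fully independent of the mesh triangulation code.
    """
    pts = rng.normal(0.0, 1.0, (12, 3))
    hull = ConvexHull(pts)
    m = vm.Mesh(dim=3)
    remap = {}
    for i in np.unique(hull.simplices):
        remap[int(i)] = m.add_vertex(pts[i])
    faces = [m.add_surface([remap[int(i)] for i in tri]) for tri in hull.simplices]
    m.add_body(faces)
    return m, hull


def fd_forces(mesh: vm.Mesh, table: A.BindingTable, h: float = 1e-7) -> np.ndarray:
    """Independent central-finite-difference force oracle on the total energy."""
    out = np.zeros((mesh.positions.shape[0], mesh.dim))
    pos = mesh.positions
    for vid in sorted(mesh.vertices):
        for k in range(mesh.dim):
            orig = pos[vid, k]
            pos[vid, k] = orig + h
            ep = A.total_energy(mesh, table)
            pos[vid, k] = orig - h
            em = A.total_energy(mesh, table)
            pos[vid, k] = orig
            out[vid, k] = -(ep - em) / (2.0 * h)
    return out


def assert_forces_match_fd(mesh, table, tol=1e-5, h=1e-7):
    f = A.accumulate_forces(mesh, table)
    g = fd_forces(mesh, table, h=h)
    scale = max(np.abs(g).max(), 1e-9)
    assert np.abs(f - g).max() / scale < tol


def four_cell_junction():
    """Four cells meeting along a short central vertical edge (T1 scenario).

    Returns (mesh, ids) where ids maps names v1, v2 (central edge), lt, lb,
    rt, rb (side corners), and the four surfaces left/right/top/bottom.
    """
    m = vm.Mesh(dim=2)
    v1 = m.add_vertex((0, 0.2))
    v2 = m.add_vertex((0, -0.2))
    lt = m.add_vertex((-1, 1))
    lb = m.add_vertex((-1, -1))
    rt = m.add_vertex((1, 1))
    rb = m.add_vertex((1, -1))
    tt = m.add_vertex((0, 2))
    bb = m.add_vertex((0, -2))
    ids = dict(v1=v1, v2=v2, lt=lt, lb=lb, rt=rt, rb=rb, tt=tt, bb=bb)
    ids["left"] = m.add_surface([lb, v2, v1, lt])
    ids["right"] = m.add_surface([rb, rt, v1, v2])
    ids["top"] = m.add_surface([v1, rt, tt, lt])
    ids["bottom"] = m.add_surface([v2, lb, bb, rb])
    return m, ids
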