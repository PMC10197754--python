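"""Primitive mesh generators: confluent polygon sheets and cube lattices.

Generators are deterministic (no RNG) and always produce meshes that pass
:func:`vmesh.mesh.validate_mesh`.  Adjacent cells share vertices (and, in the
cube lattice, faces), so the output is a confluent tissue rather than a soup
of disconnected polygons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh import Mesh

__all__ = ["SheetSpec", "LatticeSpec", "generate_sheet", "generate_cube_lattice"]


@dataclass
class SheetSpec:
    tiling: str = "square"          # "square" | "hexagonal"
    n_rows: int = 1
    n_cols: int = 1
    cell_area: float = 1.0          # area of each cell
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.tiling not in ("square", "hexagonal"):
            raise ValueError(f"unknown tiling {self.tiling!r}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")


@dataclass
class LatticeSpec:
    nx: int = 1
    ny: int = 1
    nz: int = 1
    edge: float = 1.0

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.edge <= 0:
            raise ValueError("edge length must be positive")


def generate_sheet(spec: SheetSpec) -> Mesh:
    """Confluent 2D sheet of square or hexagonal cells, one surface per cell.

    Every interior vertex of a square tiling is 4-valent; of a hexagonal
    tiling, 3-valent.  Cell cycles wind counter-clockwise so the implied
    surface normal is +z.
    """
    if spec.tiling == "square":
        return _square_sheet(spec)
    return _hex_sheet(spec)


def _square_sheet(spec: SheetSpec) -> Mesh:
    mesh = Mesh(dim=2)
    side = math.sqrt(spec.cell_area)
    ox, oy = spec.origin
    nc, nr = spec.n_cols, spec.n_rows
    vid = {}
    for j in range(nr + 1):
        for i in range(nc + 1):
            vid[(i, j)] = mesh.add_vertex((ox + i * side, oy + j * side))
    for j in range(nr):
        for i in range(nc):
            mesh.add_surface([vid[(i, j)], vid[(i + 1, j)],
                              vid[(i + 1, j + 1)], vid[(i, j + 1)]])
    return mesh


def _hex_sheet(spec: SheetSpec) -> Mesh:
    # pointy-top hexagons; circumradius chosen so each cell has cell_area
    R = math.sqrt(spec.cell_area * 2.0 / (3.0 * math.sqrt(3.0)))
    w = math.sqrt(3.0) * R          # center-to-center horizontal spacing
    mesh = Mesh(dim=2)
    ox, oy = spec.origin
    # vertex offsets, CCW starting from the top point
    offs = [(R * math.cos(math.pi / 2 + k * math.pi / 3),
             R * math.sin(math.pi / 2 + k * math.pi / 3)) for k in range(6)]
    welded: dict[tuple[int, int], int] = {}

    def vertex_at(x: float, y: float) -> int:
        key = (round(x * 1e9), round(y * 1e9))
        if key not in welded:
            welded[key] = mesh.add_vertex((x, y))
        return welded[key]

    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            cx = ox + c * w + (r % 2) * w / 2.0
            cy = oy + r * 1.5 * R
            # increasing angle = counter-clockwise winding
            cyc = [vertex_at(cx + dx, cy + dy) for dx, dy in offs]
            mesh.add_surface(cyc)
    return mesh


def generate_cube_lattice(spec: LatticeSpec) -> Mesh:
    """3D lattice of cubes; each shared face is a single surface with two bodies."""
    mesh = Mesh(dim=3)
    e = spec.edge
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    vid = {}
    for k in range(nz + 1):
        for j in range(ny + 1):
            for i in range(nx + 1):
                vid[(i, j, k)] = mesh.add_vertex((i * e, j * e, k * e))

    face_ids: dict[tuple, int] = {}

    def face(corners: list[tuple[int, int, int]]) -> int:
        key = tuple(sorted(corners))
        if key not in face_ids:
            face_ids[key] = mesh.add_surface([vid[c] for c in corners])
        return face_ids[key]

    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                # faces wound CCW as seen from outside the cube at (i, j, k);
                # a shared face keeps the winding of whichever cube made it
                # first (the orientation sign rule resolves the other side)
                faces = [
                    face([(i, j, k), (i, j, k + 1), (i, j + 1, k + 1), (i, j + 1, k)]),        # -x
                    face([(i + 1, j, k), (i + 1, j + 1, k), (i + 1, j + 1, k + 1), (i + 1, j, k + 1)]),  # +x
                    face([(i, j, k), (i + 1, j, k), (i + 1, j, k + 1), (i, j, k + 1)]),        # -y
                    face([(i, j + 1, k), (i, j + 1, k + 1), (i + 1, j + 1, k + 1), (i + 1, j + 1, k)]),  # +y
                    face([(i, j, k), (i, j + 1, k), (i + 1, j + 1, k), (i + 1, j, k)]),        # -z
                    face([(i, j, k + 1), (i + 1, j, k + 1), (i + 1, j + 1, k + 1), (i, j + 1, k + 1)]),  # +z
                ]
                mesh.add_body(faces)
    return mesh
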