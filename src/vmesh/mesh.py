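"""Vertex-model mesh: vertices, surfaces (vertex cycles) and bodies (surface sets).

The mesh is the central container of the vertex-model formalism.  A *vertex*
represents a region of space; a *surface* is an ordered cycle of three or more
vertices (edges are implicit between consecutive cycle entries); a *body* is an
unordered set of four or more surfaces enclosing a connected volume.  All
higher-level properties (areas, volumes, drags) resolve to per-vertex
quantities through a triangulation of each surface fanned about its centroid,
so that forces defined on surfaces and bodies translate consistently into
forces on vertices.

Geometry conventions
--------------------
* A surface with cycle ``(v0, v1, ..., v_{n-1})`` is triangulated into ``n``
  triangles ``(v_k, v_{k+1}, C)`` where ``C`` is the centroid (vertex mean).
* In planar-2D mode positions are 2-vectors; normals are reported as
  3-vectors with the implied normal along +z for counter-clockwise winding.
* Surfaces are assumed flat and convex; the geometric operations do not verify
  this (the flat/convex constraint actors enforce it dynamically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Mesh",
    "Vertex",
    "Surface",
    "Body",
    "MeshError",
    "DegenerateGeometryError",
    "surface_centroid",
    "triangle_geometry",
    "surface_measures",
    "SurfaceMeasures",
    "vertex_area",
    "vertex_area_contribution",
    "body_measures",
    "BodyMeasures",
    "orientation_sign",
    "vertex_volume",
    "vertex_volume_contribution",
    "vertex_drag",
    "neighbors_and_shared_edges",
    "validate_mesh",
]


class MeshError(ValueError):
    """Invalid mesh construction or query."""


class DegenerateGeometryError(MeshError):
    """Geometry is degenerate in a way that forbids the requested measure."""


@dataclass
class Vertex:
    id: int
    surface_ids: list[int] = field(default_factory=list)


@dataclass
class Surface:
    id: int
    cycle: list[int]
    type_id: int = 0
    body_ids: list[int] = field(default_factory=list)
    #: per-area drag density rho for variable-drag planar models
    drag_density: float | None = None


@dataclass
class Body:
    id: int
    surface_ids: set[int]
    type_id: int = 0
    drag_density: float | None = None


class Mesh:
    """Id-indexed stores of vertices, surfaces and bodies with dense positions.

    Vertex positions live in a single ``(capacity, dim)`` float array indexed
    by vertex id; ids are never reused, so rows of removed vertices simply go
    stale.  ``dim`` is 2 (planar-2D mode) or 3.
    """

    def __init__(self, dim: int = 2, domain_box: np.ndarray | None = None):
        if dim not in (2, 3):
            raise MeshError(f"dim must be 2 or 3, got {dim}")
        self.dim = dim
        self.vertices: dict[int, Vertex] = {}
        self.surfaces: dict[int, Surface] = {}
        self.bodies: dict[int, Body] = {}
        self._positions = np.zeros((16, dim), dtype=float)
        self._next_vertex_id = 0
        self._next_surface_id = 0
        self._next_body_id = 0
        #: bumped on every structural change; derived caches key off it
        self.topology_version = 0
        #: axis-aligned bounds, shape (2, dim) as [lo, hi]; None = unbounded
        self.domain_box = None if domain_box is None else np.asarray(domain_box, float)

    # ------------------------------------------------------------------
    # construction / mutation
    # ------------------------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        """Raw position storage; valid rows are the ids in ``self.vertices``."""
        return self._positions[: self._next_vertex_id]

    def position(self, vid: int) -> np.ndarray:
        self._require_vertex(vid)
        return self._positions[vid]

    def set_position(self, vid: int, value) -> None:
        self._require_vertex(vid)
        self._positions[vid] = value

    def add_vertex(self, position) -> int:
        vid = self._next_vertex_id
        if vid >= self._positions.shape[0]:
            grown = np.zeros((2 * self._positions.shape[0], self.dim))
            grown[: self._positions.shape[0]] = self._positions
            self._positions = grown
        pos = np.asarray(position, dtype=float)
        if pos.shape != (self.dim,):
            raise MeshError(f"position must have shape ({self.dim},), got {pos.shape}")
        self._positions[vid] = pos
        self.vertices[vid] = Vertex(vid)
        self._next_vertex_id += 1
        self.topology_version += 1
        return vid

    def add_surface(self, cycle: Iterable[int], type_id: int = 0) -> int:
        cyc = [int(v) for v in cycle]
        if len(cyc) < 3:
            raise MeshError(f"surface cycle needs >= 3 vertices, got {len(cyc)}")
        if len(set(cyc)) != len(cyc):
            raise MeshError("surface cycle contains a repeated vertex id")
        for v in cyc:
            self._require_vertex(v)
        sid = self._next_surface_id
        self.surfaces[sid] = Surface(sid, cyc, type_id)
        for v in cyc:
            self.vertices[v].surface_ids.append(sid)
        self._next_surface_id += 1
        self.topology_version += 1
        return sid

    def add_body(self, surface_ids: Iterable[int], type_id: int = 0,
                 drag_density: float | None = None) -> int:
        sids = {int(s) for s in surface_ids}
        if len(sids) < 4:
            raise MeshError(f"body needs >= 4 surfaces, got {len(sids)}")
        for s in sids:
            self._require_surface(s)
            if len(self.surfaces[s].body_ids) >= 2:
                raise MeshError(f"surface {s} already defines two bodies")
        bid = self._next_body_id
        self.bodies[bid] = Body(bid, sids, type_id, drag_density)
        for s in sids:
            self.surfaces[s].body_ids.append(bid)
        self._next_body_id += 1
        self.topology_version += 1
        return bid

    def remove_surface(self, sid: int) -> None:
        surf = self._require_surface(sid)
        for v in surf.cycle:
            vert = self.vertices.get(v)
            if vert is not None and sid in vert.surface_ids:
                vert.surface_ids.remove(sid)
        for b in list(surf.body_ids):
            body = self.bodies.get(b)
            if body is not None:
                body.surface_ids.discard(sid)
        del self.surfaces[sid]
        self.topology_version += 1

    def remove_body(self, bid: int) -> None:
        body = self._require_body(bid)
        for s in body.surface_ids:
            surf = self.surfaces.get(s)
            if surf is not None and bid in surf.body_ids:
                surf.body_ids.remove(bid)
        del self.bodies[bid]
        self.topology_version += 1

    def remove_vertex(self, vid: int) -> None:
        vert = self._require_vertex(vid)
        if vert.surface_ids:
            raise MeshError(f"vertex {vid} still defines surfaces {vert.surface_ids}")
        del self.vertices[vid]
        self.topology_version += 1

    # ------------------------------------------------------------------
    # derived connectivity (cached per topology version)
    # ------------------------------------------------------------------
    def edge_owners(self) -> dict[tuple[int, int], list[int]]:
        """Map undirected edge (min vid, max vid) -> surface ids containing it."""
        cached = getattr(self, "_edge_cache", None)
        if cached is not None and cached[0] == self.topology_version:
            return cached[1]
        owners: dict[tuple[int, int], list[int]] = {}
        for sid, surf in self.surfaces.items():
            cyc = surf.cycle
            n = len(cyc)
            for k in range(n):
                a, b = cyc[k], cyc[(k + 1) % n]
                key = (a, b) if a < b else (b, a)
                owners.setdefault(key, []).append(sid)
        self._edge_cache = (self.topology_version, owners)
        return owners

    def vertex_neighbors(self, vid: int) -> list[int]:
        """Vertices connected to ``vid`` by an edge, ascending id order."""
        self._require_vertex(vid)
        nbrs: set[int] = set()
        for sid in self.vertices[vid].surface_ids:
            cyc = self.surfaces[sid].cycle
            k = cyc.index(vid)
            n = len(cyc)
            nbrs.add(cyc[(k - 1) % n])
            nbrs.add(cyc[(k + 1) % n])
        return sorted(nbrs)

    # ------------------------------------------------------------------
    def _require_vertex(self, vid: int) -> Vertex:
        try:
            return self.vertices[vid]
        except KeyError:
            raise MeshError(f"unknown vertex id {vid}") from None

    def _require_surface(self, sid: int) -> Surface:
        try:
            return self.surfaces[sid]
        except KeyError:
            raise MeshError(f"unknown surface id {sid}") from None

    def _require_body(self, bid: int) -> Body:
        try:
            return self.bodies[bid]
        except KeyError:
            raise MeshError(f"unknown body id {bid}") from None

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Mesh(dim={self.dim}, vertices={len(self.vertices)}, "
                f"surfaces={len(self.surfaces)}, bodies={len(self.bodies)})")


# ----------------------------------------------------------------------
# geometric measures
# ----------------------------------------------------------------------

def _cycle_positions_3d(mesh: Mesh, sid: int) -> np.ndarray:
    """Cycle positions embedded in 3D (z = 0 in planar mode), shape (n, 3)."""
    surf = mesh._require_surface(sid)
    P = mesh._positions[np.asarray(surf.cycle, dtype=int)]
    if mesh.dim == 2:
        P3 = np.zeros((P.shape[0], 3))
        P3[:, :2] = P
        return P3
    return P.copy()


def surface_centroid(mesh: Mesh, sid: int) -> np.ndarray:
    """Centroid of a surface: the mean of its cycle's vertex positions."""
    surf = mesh._require_surface(sid)
    return mesh._positions[np.asarray(surf.cycle, dtype=int)].mean(axis=0)


def _triangle_normals(P3: np.ndarray) -> np.ndarray:
    """Unnormalized triangle normals eta_k = (P_k - C) x (P_{k+1} - C)."""
    C = P3.mean(axis=0)
    a = P3 - C
    b = np.roll(a, -1, axis=0)
    return np.cross(a, b)


def triangle_geometry(mesh: Mesh, sid: int, k: int) -> tuple[np.ndarray, float, float]:
    """Normal vector, area and volume contribution of the k-th triangle.

    The triangle is spanned by cycle vertices ``k`` and ``k+1`` together with
    the surface centroid ``C``.  Its volume contribution is ``C . eta / 6``
    (used by the divergence-theorem body volume); it is only meaningful in
    3D mode and reported as 0.0 in planar mode.  A degenerate (collinear)
    triangle has zero area and zero normal; this is not an error.
    """
    P3 = _cycle_positions_3d(mesh, sid)
    n = P3.shape[0]
    if not 0 <= k < n:
        raise MeshError(f"triangle index {k} out of range for cycle of {n}")
    eta = _triangle_normals(P3)[k]
    area = 0.5 * float(np.linalg.norm(eta))
    vol = float(P3.mean(axis=0) @ eta) / 6.0 if mesh.dim == 3 else 0.0
    return eta, area, vol


@dataclass(frozen=True)
class SurfaceMeasures:
    normal: np.ndarray      # unit normal (3-vector); zero vector if degenerate
    area: float
    perimeter: float
    degenerate: bool        # True when the summed normal vanished


def surface_measures(mesh: Mesh, sid: int) -> SurfaceMeasures:
    """Unit normal, triangulated area and perimeter of a surface.

    The area is the sum of the areas of the centroid-fan triangles and the
    normal is the normalized sum of their normal vectors.  A zero summed
    normal flags the surface as degenerate rather than raising, so force
    evaluation can defer the problem to the topology quality operations.
    """
    P3 = _cycle_positions_3d(mesh, sid)
    etas = _triangle_normals(P3)
    area = 0.5 * float(np.linalg.norm(etas, axis=1).sum())
    total = etas.sum(axis=0)
    norm = float(np.linalg.norm(total))
    degenerate = norm < 1e-300
    normal = np.zeros(3) if degenerate else total / norm
    edges = np.roll(P3, -1, axis=0) - P3
    perimeter = float(np.linalg.norm(edges, axis=1).sum())
    return SurfaceMeasures(normal, area, perimeter, degenerate)


def vertex_area_contribution(mesh: Mesh, vid: int, sid: int) -> float:
    """Half the summed area of the two triangles of ``sid`` that ``vid`` defines."""
    surf = mesh._require_surface(sid)
    try:
        k = surf.cycle.index(vid)
    except ValueError:
        raise MeshError(f"vertex {vid} is not in the cycle of surface {sid}") from None
    P3 = _cycle_positions_3d(mesh, sid)
    etas = _triangle_normals(P3)
    areas = 0.5 * np.linalg.norm(etas, axis=1)
    n = len(surf.cycle)
    return 0.5 * float(areas[k] + areas[(k - 1) % n])


def vertex_area(mesh: Mesh, vid: int) -> float:
    """Total area of a vertex: sum of its contributions to all its surfaces."""
    vert = mesh._require_vertex(vid)
    return sum(vertex_area_contribution(mesh, vid, sid) for sid in vert.surface_ids)


@dataclass(frozen=True)
class BodyMeasures:
    area: float
    centroid: np.ndarray
    volume: float


def orientation_sign(mesh: Mesh, bid: int, sid: int) -> int:
    """+1 when the surface normal faces outward from the body, else -1.

    Outwardness is decided by the sign of ``normal . (surface centroid - body
    centroid)``.  An exactly-zero dot product leaves the orientation
    unresolvable and raises, forcing mesh repair.
    """
    body = mesh._require_body(bid)
    if sid not in body.surface_ids:
        raise MeshError(f"surface {sid} does not define body {bid}")
    # area-weighted body centroid (Eq. 9 analog) without recursing via volume
    areas = []
    cents = []
    for s in body.surface_ids:
        m = surface_measures(mesh, s)
        areas.append(m.area)
        cents.append(surface_centroid(mesh, s))
    areas_arr = np.asarray(areas)
    total_area = float(areas_arr.sum())
    if total_area <= 0.0:
        raise DegenerateGeometryError(f"body {bid} has zero surface area")
    body_centroid = (np.asarray(cents) * areas_arr[:, None]).sum(axis=0) / total_area
    m = surface_measures(mesh, sid)
    if m.degenerate:
        raise DegenerateGeometryError(f"surface {sid} has a degenerate normal")
    c3 = surface_centroid(mesh, sid)
    if mesh.dim == 2:
        c3 = np.array([c3[0], c3[1], 0.0])
        body_centroid = np.array([body_centroid[0], body_centroid[1], 0.0])
    dot = float(m.normal @ (c3 - body_centroid))
    if dot == 0.0:
        raise DegenerateGeometryError(
            f"orientation of surface {sid} w.r.t. body {bid} is degenerate")
    return 1 if dot > 0 else -1


def body_measures(mesh: Mesh, bid: int) -> BodyMeasures:
    """Surface area, area-weighted centroid and divergence-theorem volume."""
    body = mesh._require_body(bid)
    if mesh.dim != 3:
        raise MeshError("body measures require a 3D mesh")
    areas = []
    cents = []
    vols = []
    for s in body.surface_ids:
        P3 = _cycle_positions_3d(mesh, s)
        etas = _triangle_normals(P3)
        areas.append(0.5 * float(np.linalg.norm(etas, axis=1).sum()))
        cents.append(P3.mean(axis=0))
        vols.append(float(P3.mean(axis=0) @ etas.sum(axis=0)) / 6.0)
    areas_arr = np.asarray(areas)
    total_area = float(areas_arr.sum())
    if total_area <= 0.0:
        raise DegenerateGeometryError(f"body {bid} has zero surface area")
    centroid = (np.asarray(cents) * areas_arr[:, None]).sum(axis=0) / total_area
    volume = 0.0
    for s, v in zip(body.surface_ids, vols):
        volume += orientation_sign(mesh, bid, s) * v
    return BodyMeasures(total_area, centroid, volume)


def vertex_volume_contribution(mesh: Mesh, vid: int, bid: int) -> float:
    """Volume share of a vertex in a body.

    Proportional to the body volume and the vertex's relative area
    contribution: ``V_B / A_B * sum_S A_{V,S}`` over the body's surfaces
    containing the vertex.
    """
    vert = mesh._require_vertex(vid)
    body = mesh._require_body(bid)
    in_body = [s for s in vert.surface_ids if s in body.surface_ids]
    if not in_body:
        raise MeshError(f"vertex {vid} does not define body {bid}")
    bm = body_measures(mesh, bid)
    if bm.area <= 0.0:
        raise DegenerateGeometryError(f"body {bid} has zero surface area")
    a = sum(vertex_area_contribution(mesh, vid, s) for s in in_body)
    return bm.volume / bm.area * a


def vertex_volume(mesh: Mesh, vid: int) -> float:
    """Total volume of a vertex: sum of contributions over bodies it defines."""
    vert = mesh._require_vertex(vid)
    bids = {b for s in vert.surface_ids for b in mesh.surfaces[s].body_ids}
    return sum(vertex_volume_contribution(mesh, vid, b) for b in sorted(bids))


def vertex_drag(mesh: Mesh, vid: int, fixed: float | None = None) -> float:
    """Drag coefficient of a vertex.

    In fixed mode (``fixed`` given) every vertex has the same drag ``M``.  In
    variable mode the drag is ``sum_B rho(B) * V_{V,B}`` over the bodies the
    vertex defines (3D) or ``sum_S rho(S) * A_{V,S}`` over its surfaces (2D),
    with ``rho`` read from the ``drag_density`` field of Body / Surface.
    """
    if fixed is not None:
        if fixed <= 0:
            raise MeshError("fixed drag must be positive")
        return float(fixed)
    vert = mesh._require_vertex(vid)
    total = 0.0
    if mesh.dim == 3:
        bids = {b for s in vert.surface_ids for b in mesh.surfaces[s].body_ids}
        for b in sorted(bids):
            rho = mesh.bodies[b].drag_density
            if rho is None:
                raise MeshError(f"body {b} has no drag density set")
            total += rho * vertex_volume_contribution(mesh, vid, b)
    else:
        for s in vert.surface_ids:
            rho = mesh.surfaces[s].drag_density
            if rho is None:
                raise MeshError(f"surface {s} has no drag density set")
            total += rho * vertex_area_contribution(mesh, vid, s)
    if total <= 0.0:
        raise DegenerateGeometryError(f"vertex {vid} has zero drag (immobile)")
    return total


def neighbors_and_shared_edges(mesh: Mesh, sid: int) -> dict[int, float]:
    """Neighbor surfaces of ``sid`` mapped to total shared-edge length.

    Two surfaces are neighbors iff they share at least one vertex; surfaces
    sharing only a vertex map to length 0.0.
    """
    surf = mesh._require_surface(sid)
    out: dict[int, float] = {}
    for v in surf.cycle:
        for other in mesh.vertices[v].surface_ids:
            if other != sid:
                out.setdefault(other, 0.0)
    owners = mesh.edge_owners()
    cyc = surf.cycle
    n = len(cyc)
    for k in range(n):
        a, b = cyc[k], cyc[(k + 1) % n]
        key = (a, b) if a < b else (b, a)
        length = float(np.linalg.norm(mesh._positions[a] - mesh._positions[b]))
        for other in owners.get(key, ()):
            if other != sid:
                out[other] += length
    return out


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate_mesh(mesh: Mesh) -> list[str]:
    """Check all structural invariants; return human-readable violations.

    An empty list means every type invariant holds and all cross-references
    are bidirectionally consistent.  This is a reporting operation: it never
    raises.
    """
    problems: list[str] = []
    for sid, surf in mesh.surfaces.items():
        if len(surf.cycle) < 3:
            problems.append(f"surface {sid}: cycle < 3 vertices")
        if len(set(surf.cycle)) != len(surf.cycle):
            problems.append(f"surface {sid}: repeated vertex in cycle")
        if len(surf.body_ids) > 2:
            problems.append(f"surface {sid}: defines more than two bodies")
        for v in surf.cycle:
            if v not in mesh.vertices:
                problems.append(f"surface {sid}: unknown vertex {v}")
            elif sid not in mesh.vertices[v].surface_ids:
                problems.append(f"surface {sid}: vertex {v} lacks back-reference")
        for b in surf.body_ids:
            if b not in mesh.bodies:
                problems.append(f"surface {sid}: unknown body {b}")
            elif sid not in mesh.bodies[b].surface_ids:
                problems.append(f"surface {sid}: body {b} lacks back-reference")
    for vid, vert in mesh.vertices.items():
        seen = set()
        for sid in vert.surface_ids:
            if sid in seen:
                problems.append(f"vertex {vid}: duplicate surface reference {sid}")
            seen.add(sid)
            if sid not in mesh.surfaces:
                problems.append(f"vertex {vid}: unknown surface {sid}")
            elif vert.id not in mesh.surfaces[sid].cycle:
                problems.append(f"vertex {vid}: not in cycle of surface {sid}")
            elif mesh.surfaces[sid].cycle.count(vid) != 1:
                problems.append(f"vertex {vid}: appears multiple times in surface {sid}")
    for bid, body in mesh.bodies.items():
        if len(body.surface_ids) < 4:
            problems.append(f"body {bid}: body < 4 surfaces")
        for s in body.surface_ids:
            if s not in mesh.surfaces:
                problems.append(f"body {bid}: unknown surface {s}")
            elif bid not in mesh.surfaces[s].body_ids:
                problems.append(f"body {bid}: surface {s} lacks back-reference")
        problems.extend(_check_body_closed(mesh, bid))
    return problems


def _check_body_closed(mesh: Mesh, bid: int) -> list[str]:
    """A body's surfaces must form a connected, closed shell.

    Connectedness: the surface-sharing-a-vertex graph is connected.
    Closedness: every edge appearing in the body's surface cycles appears in
    exactly two of them.
    """
    body = mesh.bodies[bid]
    sids = [s for s in body.surface_ids if s in mesh.surfaces]
    if len(sids) < 2:
        return []
    problems = []
    # connectivity via shared vertices
    vert_to_surfs: dict[int, list[int]] = {}
    for s in sids:
        for v in mesh.surfaces[s].cycle:
            vert_to_surfs.setdefault(v, []).append(s)
    adj: dict[int, set[int]] = {s: set() for s in sids}
    for group in vert_to_surfs.values():
        for s in group:
            adj[s].update(group)
    seen = set()
    stack = [sids[0]]
    while stack:
        s = stack.pop()
        if s in seen:
            continue
        seen.add(s)
        stack.extend(adj[s] - seen)
    if len(seen) != len(sids):
        problems.append(f"body {bid}: surface set is not connected")
    edge_count: dict[tuple[int, int], int] = {}
    for s in sids:
        cyc = mesh.surfaces[s].cycle
        n = len(cyc)
        for k in range(n):
            a, b = cyc[k], cyc[(k + 1) % n]
            key = (a, b) if a < b else (b, a)
            edge_count[key] = edge_count.get(key, 0) + 1
    bad = [e for e, c in edge_count.items() if c != 2]
    if bad:
        problems.append(f"body {bid}: {len(bad)} edge(s) not shared by exactly two surfaces")
    return problems
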