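"""Actors: parameterized force models bound to mesh objects or types.

An *actor* is any model that resolves to forces on vertices — either an
explicit force (surface traction, body force, normal stress, random motility)
or the negative gradient of an effective energy (area/perimeter constraints,
edge tension, adhesion, volume constraints).  Actors are *bound* to surfaces,
bodies, their types, or the whole mesh through a :class:`BindingTable`;
binding is additive, and all bound actors act simultaneously: the per-step
force field is the plain sum of every binding's contribution.

Energy-based actors implement both :meth:`~Actor.add_forces` (analytic
gradient, chain rule through the surface centroid included) and
:meth:`~Actor.energy`; the test suite verifies each analytic gradient against
central finite differences of the energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Callable

import numpy as np

from . import _geom
from .mesh import Mesh

logger = logging.getLogger(__name__)

__all__ = [
    "Actor", "BindingTable", "Binding", "GeomEval", "ConfigError",
    "SurfaceAreaConstraint", "PerimeterConstraint", "EdgeTension",
    "Adhesion2D", "Adhesion3D", "SurfaceTraction", "NormalStress",
    "BodyForce", "VolumeConstraint", "BodySurfaceAreaConstraint",
    "FlatSurfaceConstraint", "ConvexPolygonConstraint", "RandomMotility",
    "CustomEnergy", "accumulate_forces", "total_energy",
]


class ConfigError(ValueError):
    """Inconsistent actor parameters or bindings."""


# ----------------------------------------------------------------------
# flattened mesh arrays (topology-dependent, cached per topology version)
# ----------------------------------------------------------------------

class MeshArrays:
    """CSR-style flattening of all surface cycles for vectorized evaluation."""

    @staticmethod
    def of(mesh: Mesh) -> "MeshArrays":
        cached = getattr(mesh, "_mesh_arrays", None)
        if cached is not None and cached.version == mesh.topology_version:
            return cached
        arr = MeshArrays(mesh)
        mesh._mesh_arrays = arr
        return arr

    def __init__(self, mesh: Mesh):
        self.version = mesh.topology_version
        sids = sorted(mesh.surfaces)
        self.sids = np.asarray(sids, dtype=int)
        self.row_of = {s: i for i, s in enumerate(sids)}
        cycles = [mesh.surfaces[s].cycle for s in sids]
        self.cyc_n = np.asarray([len(c) for c in cycles], dtype=int)
        self.ptr = np.concatenate([[0], np.cumsum(self.cyc_n)])
        self.flat_v = (np.concatenate(cycles).astype(int)
                       if cycles else np.empty(0, dtype=int))
        self.surf_of = np.repeat(np.arange(len(sids)), self.cyc_n)
        # previous / next slot within each cycle block (vectorized)
        F = len(self.flat_v)
        lo = self.ptr[self.surf_of] if F else np.zeros(0, dtype=int)
        n_here = self.cyc_n[self.surf_of] if F else np.zeros(0, dtype=int)
        local = np.arange(F) - lo
        self.nxt_slot = lo + (local + 1) % np.maximum(n_here, 1)
        self.prv_slot = lo + (local - 1) % np.maximum(n_here, 1)
        self.nxt_v = self.flat_v[self.nxt_slot] if F else self.flat_v
        self.stype = np.asarray([mesh.surfaces[s].type_id for s in sids], dtype=int)
        # unique undirected edges with up to two owning surface rows
        owners: dict[tuple[int, int], list[int]] = {}
        for i, cyc in enumerate(cycles):
            n = len(cyc)
            for k in range(n):
                a, b = cyc[k], cyc[(k + 1) % n]
                key = (a, b) if a < b else (b, a)
                owners.setdefault(key, []).append(i)
        E = len(owners)
        self.edge_a = np.empty(E, dtype=int)
        self.edge_b = np.empty(E, dtype=int)
        self.edge_owner = np.full((E, 2), -1, dtype=int)
        for e, (key, own) in enumerate(sorted(owners.items())):
            self.edge_a[e], self.edge_b[e] = key
            for j, s in enumerate(own[:2]):
                self.edge_owner[e, j] = s
        self.n_surf = len(sids)


class GeomEval:
    """Per-step geometric quantities of every surface, computed lazily.

    Positions are embedded in 3D (z = 0 for planar meshes) so a single code
    path serves both modes; forces are scattered back to ``dim`` components.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.arr = MeshArrays.of(mesh)
        self.dim = mesh.dim
        pos = mesh.positions
        if mesh.dim == 2:
            self.pos3 = np.zeros((pos.shape[0], 3))
            self.pos3[:, :2] = pos
        else:
            self.pos3 = np.asarray(pos, dtype=float)

    @cached_property
    def P(self) -> np.ndarray:
        return self.pos3[self.arr.flat_v]

    @cached_property
    def Pn(self) -> np.ndarray:
        return self.pos3[self.arr.nxt_v]

    @cached_property
    def centroid(self) -> np.ndarray:
        sums = np.add.reduceat(self.P, self.arr.ptr[:-1], axis=0) \
            if self.arr.n_surf else np.zeros((0, 3))
        return sums / self.arr.cyc_n[:, None]

    @cached_property
    def a(self) -> np.ndarray:
        return self.P - self.centroid[self.arr.surf_of]

    @cached_property
    def b(self) -> np.ndarray:
        return self.Pn - self.centroid[self.arr.surf_of]

    @cached_property
    def eta(self) -> np.ndarray:
        return np.cross(self.a, self.b)

    @cached_property
    def eta_norm(self) -> np.ndarray:
        return np.linalg.norm(self.eta, axis=1)

    @cached_property
    def eta_hat(self) -> np.ndarray:
        hat = np.zeros_like(self.eta)
        ok = self.eta_norm > 1e-300
        hat[ok] = self.eta[ok] / self.eta_norm[ok, None]
        return hat

    @cached_property
    def tri_area(self) -> np.ndarray:
        return 0.5 * self.eta_norm

    @cached_property
    def area(self) -> np.ndarray:
        """Triangulated area per surface row."""
        return (np.add.reduceat(self.tri_area, self.arr.ptr[:-1])
                if self.arr.n_surf else np.zeros(0))

    @cached_property
    def normal(self) -> np.ndarray:
        """Unit normal per surface row (zero rows where degenerate)."""
        total = (np.add.reduceat(self.eta, self.arr.ptr[:-1], axis=0)
                 if self.arr.n_surf else np.zeros((0, 3)))
        n = np.linalg.norm(total, axis=1)
        out = np.zeros_like(total)
        ok = n > 1e-300
        out[ok] = total[ok] / n[ok, None]
        return out

    @cached_property
    def edge_vec(self) -> np.ndarray:
        return self.Pn - self.P

    @cached_property
    def edge_len(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vec, axis=1)

    @cached_property
    def edge_hat(self) -> np.ndarray:
        out = np.zeros_like(self.edge_vec)
        ok = self.edge_len > 1e-300
        out[ok] = self.edge_vec[ok] / self.edge_len[ok, None]
        return out

    @cached_property
    def perimeter(self) -> np.ndarray:
        return (np.add.reduceat(self.edge_len, self.arr.ptr[:-1])
                if self.arr.n_surf else np.zeros(0))

    @cached_property
    def area_grad(self) -> np.ndarray:
        """dA_S/dP per flat slot (chain rule through the centroid included)."""
        u = np.cross(self.b, self.eta_hat)
        w = np.cross(self.eta_hat, self.a)
        uw = u + w
        mean_uw = (np.add.reduceat(uw, self.arr.ptr[:-1], axis=0)
                   / self.arr.cyc_n[:, None])
        return 0.5 * (u + w[self.arr.prv_slot] - mean_uw[self.arr.surf_of])

    @cached_property
    def perimeter_grad(self) -> np.ndarray:
        """dL_S/dP per flat slot."""
        return self.edge_hat[self.arr.prv_slot] - self.edge_hat

    @cached_property
    def vertex_area_contrib(self) -> np.ndarray:
        """A_{V,S} per flat slot."""
        return 0.5 * (self.tri_area + self.tri_area[self.arr.prv_slot])

    # ------------------------------------------------------------------
    def scatter(self, out: np.ndarray, flat_forces: np.ndarray) -> None:
        np.add.at(out, self.arr.flat_v, flat_forces[:, : self.dim])

    def surface_rows(self, sids) -> np.ndarray:
        return np.asarray([self.arr.row_of[s] for s in sids], dtype=int)


# ----------------------------------------------------------------------
# bindings
# ----------------------------------------------------------------------

@dataclass
class Binding:
    actor: "Actor"
    kind: str        # surface | surface_type | body | body_type | vertices | mesh
    target: object


class BindingTable:
    """Additive associations of actors with mesh objects or types."""

    def __init__(self):
        self.entries: list[Binding] = []

    def bind(self, actor: "Actor", *, surface_type: int | None = None,
             body_type: int | None = None, surface_id: int | None = None,
             body_id: int | None = None, vertices: bool = False,
             mesh: bool = False) -> "BindingTable":
        given = [surface_type is not None, body_type is not None,
                 surface_id is not None, body_id is not None, vertices, mesh]
        if sum(given) != 1:
            raise ConfigError("bind() needs exactly one target")
        if surface_type is not None:
            kind, target = "surface_type", surface_type
        elif body_type is not None:
            kind, target = "body_type", body_type
        elif surface_id is not None:
            kind, target = "surface", surface_id
        elif body_id is not None:
            kind, target = "body", body_id
        elif vertices:
            kind, target = "vertices", None
        else:
            kind, target = "mesh", None
        allowed = {
            "surface": ("surface", "surface_type", "mesh"),
            "body": ("body", "body_type", "mesh"),
            "vertex": ("vertices",),
            "mesh": ("mesh",),
        }[actor.scope]
        if kind not in allowed:
            raise ConfigError(
                f"{type(actor).__name__} (scope {actor.scope!r}) cannot bind to {kind!r}")
        self.entries.append(Binding(actor, kind, target))
        return self

    def _resolve(self, binding: Binding, ev: GeomEval):
        mesh = ev.mesh
        kind = binding.kind
        if kind == "surface":
            if binding.target not in mesh.surfaces:
                raise ConfigError(f"binding targets unknown surface {binding.target}")
            return np.asarray([ev.arr.row_of[binding.target]], dtype=int)
        if kind == "surface_type":
            return np.nonzero(ev.arr.stype == binding.target)[0]
        if kind == "body":
            if binding.target not in mesh.bodies:
                raise ConfigError(f"binding targets unknown body {binding.target}")
            return [binding.target]
        if kind == "body_type":
            return [b for b, body in sorted(mesh.bodies.items())
                    if body.type_id == binding.target]
        if kind == "vertices":
            return np.asarray(sorted(mesh.vertices), dtype=int)
        if binding.actor.scope == "surface":
            return np.arange(ev.arr.n_surf)
        if binding.actor.scope == "body":
            return sorted(mesh.bodies)
        return None


def accumulate_forces(mesh: Mesh, table: BindingTable,
                      rng: np.random.Generator | None = None,
                      out: np.ndarray | None = None,
                      ev: GeomEval | None = None) -> np.ndarray:
    """Sum of all bound actors' per-vertex forces (order-independent).

    Returns an array indexed by vertex id (rows of removed vertices are
    zero).  ``rng`` is required when a stochastic actor is bound.
    """
    if ev is None:
        ev = GeomEval(mesh)
    if out is None:
        out = np.zeros((mesh.positions.shape[0], mesh.dim))
    for binding in table.entries:
        targets = table._resolve(binding, ev)
        binding.actor.add_forces(ev, targets, out, rng)
    if not np.all(np.isfinite(out)):
        bad = np.nonzero(~np.isfinite(out).all(axis=1))[0]
        raise FloatingPointError(f"non-finite force on vertices {bad[:5].tolist()}")
    return out


def total_energy(mesh: Mesh, table: BindingTable,
                 ev: GeomEval | None = None) -> float:
    """Total effective energy of all bound energy-based actors."""
    if ev is None:
        ev = GeomEval(mesh)
    total = 0.0
    for binding in table.entries:
        if binding.actor.is_energy:
            targets = table._resolve(binding, ev)
            total += binding.actor.energy(ev, targets)
    return total


# ----------------------------------------------------------------------
# actor catalog
# ----------------------------------------------------------------------

class Actor:
    scope = "surface"       # surface | body | vertex | mesh
    is_energy = False

    def add_forces(self, ev: GeomEval, targets, out: np.ndarray,
                   rng: np.random.Generator | None = None) -> None:
        raise NotImplementedError

    def energy(self, ev: GeomEval, targets) -> float:
        raise NotImplementedError(f"{type(self).__name__} is not energy-based")


def _row_coef(ev: GeomEval, rows: np.ndarray, values) -> np.ndarray:
    coef = np.zeros(ev.arr.n_surf)
    coef[rows] = values
    return coef


class SurfaceAreaConstraint(Actor):
    """Quadratic area penalty lambda * (A_S - A_o)^2 on each bound surface."""

    is_energy = True

    def __init__(self, lam: float, target_area: float):
        if lam < 0:
            raise ConfigError("area constraint strength must be >= 0")
        self.lam = float(lam)
        self.target_area = float(target_area)

    def add_forces(self, ev, rows, out, rng=None):
        coef = _row_coef(ev, rows, -2.0 * self.lam
                         * (ev.area[rows] - self.target_area))
        ev.scatter(out, coef[ev.arr.surf_of, None] * ev.area_grad)

    def energy(self, ev, rows):
        return float(self.lam * ((ev.area[rows] - self.target_area) ** 2).sum())


class PerimeterConstraint(Actor):
    """Quadratic perimeter penalty lambda * (L_S - L_o)^2."""

    is_energy = True

    def __init__(self, lam: float, target_perimeter: float):
        if lam < 0:
            raise ConfigError("perimeter constraint strength must be >= 0")
        self.lam = float(lam)
        self.target_perimeter = float(target_perimeter)

    def add_forces(self, ev, rows, out, rng=None):
        coef = _row_coef(ev, rows, -2.0 * self.lam
                         * (ev.perimeter[rows] - self.target_perimeter))
        ev.scatter(out, coef[ev.arr.surf_of, None] * ev.perimeter_grad)

    def energy(self, ev, rows):
        return float(self.lam
                     * ((ev.perimeter[rows] - self.target_perimeter) ** 2).sum())


class EdgeTension(Actor):
    """Edge-length energy lambda * sum ||edge||^p over a surface cycle, p in {1, 2}.

    p = 1 gives a constant-magnitude contractile force per edge; p = 2 gives
    a linear (spring-like, zero rest length) contraction.  A zero-length edge
    contributes zero force (subgradient choice at the kink for p = 1).
    """

    is_energy = True

    def __init__(self, lam: float, exponent: int = 1):
        if exponent not in (1, 2):
            raise ConfigError("edge tension exponent must be 1 or 2")
        self.lam = float(lam)
        self.exponent = exponent

    def add_forces(self, ev, rows, out, rng=None):
        coef = _row_coef(ev, rows, self.lam)[ev.arr.surf_of]
        if self.exponent == 1:
            f = coef[:, None] * ev.edge_hat
        else:
            f = 2.0 * coef[:, None] * ev.edge_vec
        dim = ev.dim
        np.add.at(out, ev.arr.flat_v, f[:, :dim])
        np.add.at(out, ev.arr.nxt_v, -f[:, :dim])

    def energy(self, ev, rows):
        L = ev.edge_len if self.exponent == 1 else ev.edge_len ** 2
        per_surf = (np.add.reduceat(L, ev.arr.ptr[:-1])
                    if ev.arr.n_surf else np.zeros(0))
        return float(self.lam * per_surf[rows].sum())


class Adhesion2D(Actor):
    """Contact energy along shared edges of connected surfaces.

    Energy ``sum_edges lambda(t, t') * len(edge)`` with the coefficient keyed
    by the unordered pair of the two owning surfaces' types; each shared edge
    is counted exactly once.  Negative coefficients reward contact
    (adhesion); positive ones penalize it.  Edges owned by a single surface
    (tissue boundary) carry no adhesion.
    """

    scope = "mesh"
    is_energy = True

    def __init__(self, matrix: dict[tuple[int, int], float]):
        self.matrix = {(min(a, b), max(a, b)): float(v)
                       for (a, b), v in matrix.items()}

    def _edge_lambda(self, ev: GeomEval) -> np.ndarray:
        arr = ev.arr
        lam = np.zeros(len(arr.edge_a))
        both = arr.edge_owner[:, 1] >= 0
        if both.any():
            t1 = arr.stype[arr.edge_owner[both, 0]]
            t2 = arr.stype[arr.edge_owner[both, 1]]
            vals = np.asarray([self.matrix.get((min(a, b), max(a, b)), 0.0)
                               for a, b in zip(t1, t2)])
            lam[both] = vals
        return lam

    def add_forces(self, ev, targets, out, rng=None):
        arr = ev.arr
        lam = self._edge_lambda(ev)
        active = lam != 0.0
        if not active.any():
            return
        a = arr.edge_a[active]
        b = arr.edge_b[active]
        d = ev.pos3[a] - ev.pos3[b]
        L = np.linalg.norm(d, axis=1)
        ok = L > 1e-300
        f = np.zeros_like(d)
        f[ok] = -(lam[active][ok] / L[ok])[:, None] * d[ok]
        dim = ev.dim
        np.add.at(out, a, f[:, :dim])
        np.add.at(out, b, -f[:, :dim])

    def energy(self, ev, targets):
        arr = ev.arr
        lam = self._edge_lambda(ev)
        d = ev.pos3[arr.edge_a] - ev.pos3[arr.edge_b]
        return float((lam * np.linalg.norm(d, axis=1)).sum())


class Adhesion3D(Actor):
    """Contact energy on shared surfaces of connected bodies.

    Energy ``lambda(bt, bt') * A_S`` summed over every surface defining two
    bodies, with the coefficient keyed by the unordered pair of body types.
    """

    scope = "mesh"
    is_energy = True

    def __init__(self, matrix: dict[tuple[int, int], float]):
        self.matrix = {(min(a, b), max(a, b)): float(v)
                       for (a, b), v in matrix.items()}

    def _shared(self, ev: GeomEval):
        mesh = ev.mesh
        for sid, surf in sorted(mesh.surfaces.items()):
            if len(surf.body_ids) == 2:
                b1, b2 = surf.body_ids
                t1 = mesh.bodies[b1].type_id
                t2 = mesh.bodies[b2].type_id
                lam = self.matrix.get((min(t1, t2), max(t1, t2)), 0.0)
                if lam != 0.0:
                    yield sid, lam

    def add_forces(self, ev, targets, out, rng=None):
        mesh = ev.mesh
        for sid, lam in self._shared(ev):
            cyc = np.asarray(mesh.surfaces[sid].cycle, dtype=int)
            P = ev.pos3[cyc]
            grad = _geom.polygon_area_grad(P)
            np.add.at(out, cyc, -lam * grad[:, : ev.dim])

    def energy(self, ev, targets):
        mesh = ev.mesh
        total = 0.0
        for sid, lam in self._shared(ev):
            total += lam * _geom.polygon_area(ev.pos3[np.asarray(mesh.surfaces[sid].cycle)])
        return total


class SurfaceTraction(Actor):
    """Uniform traction (force per unit area) on surfaces.

    Each cycle vertex receives ``A_{V,S} * tau``; the total force on the
    surface is ``A_S * tau``.
    """

    def __init__(self, traction):
        self.traction = np.asarray(traction, dtype=float)

    def add_forces(self, ev, rows, out, rng=None):
        tau = np.zeros(3)
        tau[: len(self.traction)] = self.traction
        mask = _row_coef(ev, rows, 1.0)[ev.arr.surf_of]
        f = (mask * ev.vertex_area_contrib)[:, None] * tau
        ev.scatter(out, f)


class NormalStress(Actor):
    """Uniform pressure-like traction along each bound surface's unit normal."""

    def __init__(self, magnitude: float):
        self.magnitude = float(magnitude)

    def add_forces(self, ev, rows, out, rng=None):
        normals = ev.normal
        degenerate = rows[np.linalg.norm(normals[rows], axis=1) < 0.5]
        if len(degenerate):
            logger.warning("normal stress skipped on degenerate surfaces %s",
                           ev.arr.sids[degenerate].tolist())
        mask = _row_coef(ev, rows, 1.0)[ev.arr.surf_of]
        tau = self.magnitude * normals[ev.arr.surf_of]
        f = (mask * ev.vertex_area_contrib)[:, None] * tau
        ev.scatter(out, f)


class RandomMotility(Actor):
    """Random force of fixed magnitude, direction resampled uniformly each step.

    Directions are drawn for all bound vertices in ascending id order from the
    provided generator, so trajectories are seed-reproducible.
    """

    scope = "vertex"

    def __init__(self, magnitude: float):
        if magnitude < 0:
            raise ConfigError("motility magnitude must be >= 0")
        self.magnitude = float(magnitude)

    def add_forces(self, ev, vids, out, rng=None):
        if rng is None:
            raise ConfigError("RandomMotility requires an rng")
        n = len(vids)
        if ev.dim == 2:
            theta = rng.uniform(0.0, 2.0 * np.pi, n)
            dirs = np.column_stack([np.cos(theta), np.sin(theta)])
        else:
            dirs = rng.standard_normal((n, 3))
            norms = np.linalg.norm(dirs, axis=1, keepdims=True)
            small = norms[:, 0] < 1e-12
            dirs[small] = (1.0, 0.0, 0.0)
            norms[small] = 1.0
            dirs /= norms
        out[vids] += self.magnitude * dirs


# ---------------------------- body actors -----------------------------

def _body_geometry(ev: GeomEval, bid: int):
    """Per-body area, volume, orientation signs and surface cycles."""
    mesh = ev.mesh
    body = mesh.bodies[bid]
    sids = sorted(body.surface_ids)
    cycles = [np.asarray(mesh.surfaces[s].cycle, dtype=int) for s in sids]
    Ps = [ev.pos3[c] for c in cycles]
    areas = np.asarray([_geom.polygon_area(P) for P in Ps])
    cents = np.asarray([P.mean(axis=0) for P in Ps])
    A = float(areas.sum())
    if A <= 0.0:
        from .mesh import DegenerateGeometryError
        raise DegenerateGeometryError(f"body {bid} has zero surface area")
    C = (cents * areas[:, None]).sum(axis=0) / A
    signs = []
    for P, cen in zip(Ps, cents):
        nrm = _geom.polygon_normal(P)
        dot = float(nrm @ (cen - C))
        signs.append(1.0 if dot > 0 else -1.0)
    V = float(sum(s * _geom.surface_volume(P) for s, P in zip(signs, Ps)))
    return sids, cycles, Ps, areas, A, C, np.asarray(signs), V


class BodyForce(Actor):
    """Uniform force distributed over a body by vertex volume share.

    Vertex force is ``V_{V,B} / V_B * f_B``; the per-vertex forces sum to the
    applied force exactly.
    """

    scope = "body"

    def __init__(self, force):
        self.force = np.asarray(force, dtype=float)

    def add_forces(self, ev, bids, out, rng=None):
        from .mesh import DegenerateGeometryError
        f3 = np.zeros(3)
        f3[: len(self.force)] = self.force
        for bid in bids:
            sids, cycles, Ps, areas, A, C, signs, V = _body_geometry(ev, bid)
            if V <= 0.0:
                raise DegenerateGeometryError(f"body {bid} has non-positive volume")
            # V_{V,B}/V_B = (sum_S A_{V,S}) / A_B
            share: dict[int, float] = {}
            for cyc, P in zip(cycles, Ps):
                contrib = _geom.vertex_area_contribs(P)
                for v, c in zip(cyc, contrib):
                    share[v] = share.get(v, 0.0) + c
            for v, c in share.items():
                out[v] += (c / A) * f3[: ev.dim]


class VolumeConstraint(Actor):
    """Quadratic volume penalty lambda * (V_B - V_o)^2 on each bound body."""

    scope = "body"
    is_energy = True

    def __init__(self, lam: float, target_volume: float):
        if lam < 0:
            raise ConfigError("volume constraint strength must be >= 0")
        self.lam = float(lam)
        self.target_volume = float(target_volume)

    def add_forces(self, ev, bids, out, rng=None):
        for bid in bids:
            sids, cycles, Ps, areas, A, C, signs, V = _body_geometry(ev, bid)
            coef = -2.0 * self.lam * (V - self.target_volume)
            for cyc, P, s in zip(cycles, Ps, signs):
                grad = s * _geom.surface_volume_grad(P)
                np.add.at(out, cyc, coef * grad[:, : ev.dim])

    def energy(self, ev, bids):
        total = 0.0
        for bid in bids:
            *_, V = _body_geometry(ev, bid)
            total += self.lam * (V - self.target_volume) ** 2
        return total


class BodySurfaceAreaConstraint(Actor):
    """Quadratic penalty lambda * (A_B - A_o)^2 on a body's total surface area."""

    scope = "body"
    is_energy = True

    def __init__(self, lam: float, target_area: float):
        if lam < 0:
            raise ConfigError("surface area constraint strength must be >= 0")
        self.lam = float(lam)
        self.target_area = float(target_area)

    def add_forces(self, ev, bids, out, rng=None):
        for bid in bids:
            sids, cycles, Ps, areas, A, *_ = _body_geometry(ev, bid)
            coef = -2.0 * self.lam * (A - self.target_area)
            for cyc, P in zip(cycles, Ps):
                grad = _geom.polygon_area_grad(P)
                np.add.at(out, cyc, coef * grad[:, : ev.dim])

    def energy(self, ev, bids):
        total = 0.0
        for bid in bids:
            _, _, _, _, A, *_ = _body_geometry(ev, bid)
            total += self.lam * (A - self.target_area) ** 2
        return total


class FlatSurfaceConstraint(Actor):
    """Restores vertices of a 3D surface onto their least-squares plane.

    Energy ``kappa/2 * sum_j d_j^2`` with ``d_j`` the distance of vertex j to
    the best-fit plane of the cycle.  Because the plane is optimal, the exact
    gradient reduces to each vertex's own term (envelope theorem), so the
    force is ``-kappa d_j n_hat``.  Vacuous in planar-2D mode.
    """

    is_energy = True

    def __init__(self, kappa: float):
        self.kappa = float(kappa)

    def add_forces(self, ev, rows, out, rng=None):
        if ev.dim == 2:
            return
        mesh = ev.mesh
        for row in rows:
            cyc = np.asarray(mesh.surfaces[int(ev.arr.sids[row])].cycle, dtype=int)
            P = ev.pos3[cyc]
            point, nrm = _geom.best_fit_plane(P)
            d = (P - point) @ nrm
            np.add.at(out, cyc, ((-self.kappa * d)[:, None] * nrm)[:, : ev.dim])

    def energy(self, ev, rows):
        if ev.dim == 2:
            return 0.0
        mesh = ev.mesh
        total = 0.0
        for row in rows:
            cyc = np.asarray(mesh.surfaces[int(ev.arr.sids[row])].cycle, dtype=int)
            P = ev.pos3[cyc]
            point, nrm = _geom.best_fit_plane(P)
            d = (P - point) @ nrm
            total += 0.5 * self.kappa * float(d @ d)
        return total


class ConvexPolygonConstraint(Actor):
    """Pushes reflex vertices of a surface back toward convexity.

    A cycle vertex is reflex when the normal of the triangle spanned by its
    two adjacent edges opposes the surface normal.  Each reflex vertex
    receives an explicit restoring force of magnitude ``kappa * deviation``
    toward the line through its two cycle neighbors.  This is a corrective
    (non-variational) actor, not an energy gradient.  Vacuous in planar-2D
    mode.
    """

    def __init__(self, kappa: float):
        self.kappa = float(kappa)

    def add_forces(self, ev, rows, out, rng=None):
        if ev.dim == 2:
            return
        mesh = ev.mesh
        for row in rows:
            cyc = np.asarray(mesh.surfaces[int(ev.arr.sids[row])].cycle, dtype=int)
            P = ev.pos3[cyc]
            nrm = _geom.polygon_normal(P)
            prv = np.roll(P, 1, axis=0)
            nxt = np.roll(P, -1, axis=0)
            wedge = np.cross(P - prv, nxt - P)
            reflex = (wedge @ nrm) < 0.0
            if not reflex.any():
                continue
            for j in np.nonzero(reflex)[0]:
                seg = nxt[j] - prv[j]
                seg_len2 = float(seg @ seg)
                if seg_len2 < 1e-300:
                    continue
                t = float((P[j] - prv[j]) @ seg) / seg_len2
                foot = prv[j] + t * seg
                out[cyc[j]] += self.kappa * (foot - P[j])[: ev.dim]


class CustomEnergy(Actor):
    """Arbitrary scalar effective energy H(mesh) with analytic or numeric forces.

    ``grad`` (optional) maps the mesh to dH/dr per vertex id; without it the
    force falls back to central finite differences of ``fn`` — adequate for
    prototyping new actors on small meshes.
    """

    scope = "mesh"
    is_energy = True

    def __init__(self, fn: Callable[[Mesh], float],
                 grad: Callable[[Mesh], np.ndarray] | None = None,
                 h: float = 1e-6):
        self.fn = fn
        self.grad = grad
        self.h = float(h)

    def add_forces(self, ev, targets, out, rng=None):
        mesh = ev.mesh
        if self.grad is not None:
            g = np.asarray(self.grad(mesh), dtype=float)
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite energy gradient")
            out[: g.shape[0]] -= g
            return
        pos = mesh.positions
        for vid in sorted(mesh.vertices):
            for k in range(mesh.dim):
                orig = pos[vid, k]
                pos[vid, k] = orig + self.h
                ep = self.fn(mesh)
                pos[vid, k] = orig - self.h
                em = self.fn(mesh)
                pos[vid, k] = orig
                out[vid, k] -= (ep - em) / (2.0 * self.h)

    def energy(self, ev, targets):
        return float(self.fn(ev.mesh))
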