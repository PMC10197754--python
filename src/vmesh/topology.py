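"""Quality operations: discrete, condition-triggered topology transformations.

After each integration step the solver applies local *quality operations*
that keep the mesh well conditioned while enforcing the structural rules
(cycles of three or more vertices, bodies of four or more surfaces):

* ``vertex_merge``   — two connected vertices closer than the merge distance
  collapse into one (first half of a T1 transition).
* ``vertex_split``   — a high-valence vertex splits in two when the edge that
  would be created is predicted to be in tension (second half of a T1).
* ``surface_demote`` — a surface whose area shrank below threshold collapses
  into a vertex at its centroid (T2 transition).
* ``body_demote``    — the 3D analog: a small body collapses into a vertex,
  cascading over any bodies the collapse invalidates.
* ``vertex_insert``  — a vertex that crosses the edge of an unconnected
  surface is inserted into that surface's cycle (T3 transition; planar mode
  only, automatically disabled when bodies are present).

Operations are evaluated per level of the object hierarchy (vertices, then
surfaces, then bodies), serially in priority order (ascending id of the
owning object).  Each mesh object may be affected by at most one accepted
operation per step; conflicting candidates are skipped and recorded.  Every
accepted operation leaves the mesh in a valid state.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh, surface_centroid, surface_measures, body_measures, validate_mesh

logger = logging.getLogger(__name__)

__all__ = ["QualityConfig", "OperationRecord", "vertex_merge", "vertex_split",
           "surface_demote", "body_demote", "vertex_insert",
           "apply_quality_operations"]


@dataclass
class QualityConfig:
    merge_distance: float = 0.1
    split_distance: float = 0.2
    surface_demote_area: float = 0.0     # 0 disables area-triggered demotes
    body_demote_volume: float = 0.0      # 0 disables volume-triggered demotes
    enable_merge: bool = True
    enable_split: bool = True
    enable_surface_demote: bool = True
    enable_body_demote: bool = True
    enable_insert: bool = True
    enabled: bool = True                 # False = fully static topology
    #: "per_neighbor": n = sum_j (f_j - f_c);  "sum_minus_center": n = (sum_j f_j) - f_c
    relative_force_mode: str = "per_neighbor"
    validate_after_ops: bool = False

    def __post_init__(self):
        if self.enabled and self.enable_merge and self.enable_split \
                and self.split_distance <= self.merge_distance:
            raise ValueError(
                "split_distance must exceed merge_distance "
                "(prevents immediate re-merge of a fresh split)")
        if self.relative_force_mode not in ("per_neighbor", "sum_minus_center"):
            raise ValueError(f"unknown relative_force_mode {self.relative_force_mode!r}")


@dataclass
class OperationRecord:
    kind: str
    owner: int
    affected: set = field(default_factory=set)   # of ("v"|"s"|"b", id)
    step: int | None = None
    accepted: bool = False
    reason: str = ""
    created: list = field(default_factory=list)  # ids of created vertices


def _snapshot(mesh: Mesh):
    return (copy.deepcopy(mesh.vertices), copy.deepcopy(mesh.surfaces),
            copy.deepcopy(mesh.bodies), mesh.positions.copy(),
            mesh._next_vertex_id, mesh._next_surface_id, mesh._next_body_id)


def _restore(mesh: Mesh, snap) -> None:
    (mesh.vertices, mesh.surfaces, mesh.bodies, pos,
     mesh._next_vertex_id, mesh._next_surface_id, mesh._next_body_id) = snap
    mesh._positions[: pos.shape[0]] = pos
    mesh.topology_version += 1


def _snapshot_local(mesh: Mesh, sids):
    """Cheap snapshot of a set of surfaces, their vertices and their bodies."""
    from .mesh import Body, Surface, Vertex
    verts = {v for s in sids for v in mesh.surfaces[s].cycle}
    bids = {b for s in sids for b in mesh.surfaces[s].body_ids}
    return {
        "surfaces": {s: (list(mesh.surfaces[s].cycle), mesh.surfaces[s].type_id,
                         list(mesh.surfaces[s].body_ids),
                         mesh.surfaces[s].drag_density) for s in sids},
        "vertices": {v: (list(mesh.vertices[v].surface_ids),
                         mesh.position(v).copy()) for v in verts},
        "bodies": {b: (set(mesh.bodies[b].surface_ids), mesh.bodies[b].type_id,
                       mesh.bodies[b].drag_density) for b in bids},
        "counters": (mesh._next_vertex_id, mesh._next_surface_id,
                     mesh._next_body_id),
    }


def _restore_local(mesh: Mesh, snap) -> None:
    from .mesh import Body, Surface, Vertex
    nv, ns, nb = snap["counters"]
    for v in [v for v in mesh.vertices if v >= nv]:
        del mesh.vertices[v]
    for s in [s for s in mesh.surfaces if s >= ns]:
        del mesh.surfaces[s]
    for b in [b for b in mesh.bodies if b >= nb]:
        del mesh.bodies[b]
    for s, (cyc, tid, bids, rho) in snap["surfaces"].items():
        mesh.surfaces[s] = Surface(s, list(cyc), tid, list(bids), rho)
    for v, (sids, pos) in snap["vertices"].items():
        mesh.vertices[v] = Vertex(v, list(sids))
        mesh._positions[v] = pos
    for b, (sids, tid, rho) in snap["bodies"].items():
        mesh.bodies[b] = Body(b, set(sids), tid, rho)
    mesh._next_vertex_id, mesh._next_surface_id, mesh._next_body_id = nv, ns, nb
    mesh.topology_version += 1


def _validate_local(mesh: Mesh, sids) -> list[str]:
    """Invariant check restricted to the given surfaces and their vertices."""
    problems = []
    for sid in sids:
        surf = mesh.surfaces.get(sid)
        if surf is None:
            continue
        if len(surf.cycle) < 3:
            problems.append(f"surface {sid}: cycle < 3 vertices")
        if len(set(surf.cycle)) != len(surf.cycle):
            problems.append(f"surface {sid}: repeated vertex in cycle")
        for v in surf.cycle:
            vert = mesh.vertices.get(v)
            if vert is None or sid not in vert.surface_ids:
                problems.append(f"surface {sid}: vertex {v} back-reference broken")
    return problems


def _set_cycle(mesh: Mesh, sid: int, new_cycle: list[int]) -> None:
    """Rewrite a surface's cycle, keeping vertex back-references consistent."""
    surf = mesh.surfaces[sid]
    old = set(surf.cycle)
    new = set(new_cycle)
    for v in old - new:
        vert = mesh.vertices.get(v)
        if vert is not None and sid in vert.surface_ids:
            vert.surface_ids.remove(sid)
    for v in new - old:
        mesh.vertices[v].surface_ids.append(sid)
    surf.cycle = list(new_cycle)
    mesh.topology_version += 1


# ----------------------------------------------------------------------
# vertex merge
# ----------------------------------------------------------------------

def vertex_merge(mesh: Mesh, v1: int, v2: int, rng: np.random.Generator,
                 config: QualityConfig) -> OperationRecord:
    """Merge two connected vertices into one at their midpoint.

    One vertex of the pair is removed (random, seeded choice); the survivor
    replaces it in every cycle and moves to the pair's midpoint.  Restricted
    to pairs whose surfaces all have cycles of four or more vertices, since
    each affected cycle shrinks by one.
    """
    rec = OperationRecord("vertex_merge", min(v1, v2))
    if v1 not in mesh.vertices or v2 not in mesh.vertices or v1 == v2:
        rec.reason = "invalid vertex pair"
        return rec
    owners = mesh.edge_owners()
    key = (v1, v2) if v1 < v2 else (v2, v1)
    if key not in owners:
        rec.reason = "vertices not connected"
        return rec
    d = float(np.linalg.norm(mesh.position(v1) - mesh.position(v2)))
    if d >= config.merge_distance:
        rec.reason = f"distance {d:.4g} >= merge distance"
        return rec
    touched = set(mesh.vertices[v1].surface_ids) | set(mesh.vertices[v2].surface_ids)
    for sid in touched:
        if len(mesh.surfaces[sid].cycle) < 4:
            rec.reason = f"surface {sid} cycle would drop below 3"
            return rec
    removed, survivor = (v1, v2) if rng.integers(2) == 0 else (v2, v1)
    midpoint = 0.5 * (mesh.position(v1) + mesh.position(v2))
    for sid in list(mesh.vertices[removed].surface_ids):
        cyc = mesh.surfaces[sid].cycle
        new_cyc = []
        for v in cyc:
            u = survivor if v == removed else v
            if not new_cyc or new_cyc[-1] != u:
                new_cyc.append(u)
        if len(new_cyc) > 1 and new_cyc[0] == new_cyc[-1]:
            new_cyc.pop()
        # collapse any remaining duplicate of the survivor (non-adjacent case)
        if new_cyc.count(survivor) > 1:
            seen = False
            dedup = []
            for u in new_cyc:
                if u == survivor:
                    if seen:
                        continue
                    seen = True
                dedup.append(u)
            new_cyc = dedup
        _set_cycle(mesh, sid, new_cyc)
    mesh.set_position(survivor, midpoint)
    mesh.remove_vertex(removed)
    rec.accepted = True
    rec.affected = {("v", v1), ("v", v2)} | {("s", s) for s in touched}
    return rec


# ----------------------------------------------------------------------
# vertex split
# ----------------------------------------------------------------------

def vertex_split(mesh: Mesh, vid: int, forces: np.ndarray,
                 config: QualityConfig) -> OperationRecord:
    """Split a high-valence vertex in two when the new edge would be in tension.

    The cut plane passes through the vertex with normal along the total
    relative force on its connected vertices.  The two candidate vertices sit
    at +/- (split distance / 2) along the normal; each neighbor reattaches to
    the candidate on its side (exactly-on-plane neighbors go to the positive
    side).  Each candidate inherits half the center force, and the split is
    accepted only if, on both sides, the total relative force (excluding the
    split pair itself) points away from the cut plane.
    """
    rec = OperationRecord("vertex_split", vid)
    if vid not in mesh.vertices:
        rec.reason = "unknown vertex"
        return rec
    nbrs = mesh.vertex_neighbors(vid)
    if len(nbrs) < 4:
        rec.reason = f"valence {len(nbrs)} < 4"
        return rec
    dim = mesh.dim
    f_c = forces[vid, :dim]
    fn = forces[np.asarray(nbrs), :dim]
    if config.relative_force_mode == "per_neighbor":
        rel = (fn - f_c).sum(axis=0)
    else:
        rel = fn.sum(axis=0) - f_c
    norm = float(np.linalg.norm(rel))
    if norm < 1e-12:
        rec.reason = "zero total relative force"
        return rec
    nhat = rel / norm
    p_c = mesh.position(vid).copy()
    side_dot = (mesh.positions[np.asarray(nbrs)] - p_c) @ nhat
    on_plane = np.isclose(side_dot, 0.0, atol=1e-12)
    if on_plane.any():
        logger.debug("split %d: %d neighbor(s) exactly on cut plane -> positive side",
                     vid, int(on_plane.sum()))
    pos_side = {v for v, s in zip(nbrs, side_dot) if s >= 0.0}
    neg_side = set(nbrs) - pos_side
    if not pos_side or not neg_side:
        rec.reason = "all neighbors on one side of cut plane"
        return rec
    f_half = 0.5 * f_c
    tot_pos = (forces[np.asarray(sorted(pos_side)), :dim] - f_half).sum(axis=0)
    tot_neg = (forces[np.asarray(sorted(neg_side)), :dim] - f_half).sum(axis=0)
    if not (float(tot_pos @ nhat) > 0.0 and float(tot_neg @ -nhat) > 0.0):
        rec.reason = "new edge not in tension"
        return rec
    # classify surfaces around the vertex by the sides of its cycle neighbors
    plans = []
    mixed = 0
    for sid in mesh.vertices[vid].surface_ids:
        cyc = mesh.surfaces[sid].cycle
        i = cyc.index(vid)
        n = len(cyc)
        sp = cyc[(i - 1) % n] in pos_side
        sn = cyc[(i + 1) % n] in pos_side
        plans.append((sid, i, sp, sn))
        if sp != sn:
            mixed += 1
    # mixed == 2: interior T1 edge; mixed == 1: boundary split; mixed == 0:
    # clean partition of surfaces (reverse T3 — surfaces sharing only this
    # vertex disconnect).  More than 2 mixed surfaces would create a
    # non-manifold edge, so such splits are rejected.
    if mixed > 2:
        rec.reason = f"cut plane splits surfaces non-contiguously ({mixed} mixed)"
        return rec
    touched = list(mesh.vertices[vid].surface_ids)
    snap = _snapshot_local(mesh, touched)
    half = 0.5 * config.split_distance
    new_v = mesh.add_vertex(p_c - half * nhat[:dim])
    mesh.set_position(vid, p_c + half * nhat[:dim])
    for sid, i, sp, sn in plans:
        cyc = mesh.surfaces[sid].cycle
        if sp and sn:
            continue
        if not sp and not sn:
            new_cyc = [new_v if v == vid else v for v in cyc]
        else:
            first = vid if sp else new_v
            second = vid if sn else new_v
            new_cyc = cyc[:i] + [first, second] + cyc[i + 1:]
        _set_cycle(mesh, sid, new_cyc)
    problems = _validate_local(mesh, touched)
    if problems:
        _restore_local(mesh, snap)
        rec.reason = f"split would invalidate mesh: {problems[0]}"
        return rec
    rec.accepted = True
    rec.created = [new_v]
    rec.affected = ({("v", vid), ("v", new_v)}
                    | {("s", sid) for sid, *_ in plans})
    return rec


# ----------------------------------------------------------------------
# surface demote (T2)
# ----------------------------------------------------------------------

def surface_demote(mesh: Mesh, sid: int, config: QualityConfig) -> OperationRecord:
    """Collapse a surface into a new vertex at its centroid (T2 transition).

    Every connected surface has the demoted surface's vertices replaced by
    the new vertex, inserted exactly once per cycle; connected cycles left
    with fewer than three vertices are removed as well.  Rejected when the
    surface defines a body of exactly four surfaces (the operation may never
    remove a body from the mesh).
    """
    rec = OperationRecord("surface_demote", sid)
    if sid not in mesh.surfaces:
        rec.reason = "unknown surface"
        return rec
    surf = mesh.surfaces[sid]
    for b in surf.body_ids:
        if len(mesh.bodies[b].surface_ids) <= 4:
            rec.reason = f"body {b} has only 4 surfaces"
            return rec
    snap = _snapshot(mesh)
    old_vertices = set(surf.cycle)
    connected = {s for v in surf.cycle for s in mesh.vertices[v].surface_ids
                 if s != sid}
    touched_bodies = {b for b in surf.body_ids}
    new_v = mesh.add_vertex(surface_centroid(mesh, sid))
    mesh.remove_surface(sid)
    removed_surfaces = {sid}
    for s in sorted(connected):
        cyc = mesh.surfaces[s].cycle
        new_cyc: list[int] = []
        inserted = False
        for v in cyc:
            if v in old_vertices:
                if not inserted:
                    new_cyc.append(new_v)
                    inserted = True
            else:
                new_cyc.append(v)
        if len(new_cyc) < 3:
            touched_bodies.update(mesh.surfaces[s].body_ids)
            mesh.remove_surface(s)
            removed_surfaces.add(s)
        else:
            _set_cycle(mesh, s, new_cyc)
    for v in sorted(old_vertices):
        if v in mesh.vertices and not mesh.vertices[v].surface_ids:
            mesh.remove_vertex(v)
    # vertices orphaned by cascading surface removal go too
    orphans = [v for v, vert in mesh.vertices.items()
               if not vert.surface_ids and v != new_v]
    for v in orphans:
        mesh.remove_vertex(v)
    problems = validate_mesh(mesh)
    if problems:
        _restore(mesh, snap)
        rec.reason = f"demote would invalidate mesh: {problems[0]}"
        return rec
    rec.accepted = True
    rec.created = [new_v]
    rec.affected = ({("s", s) for s in removed_surfaces | connected}
                    | {("v", v) for v in old_vertices} | {("v", new_v)}
                    | {("b", b) for b in touched_bodies})
    return rec


# ----------------------------------------------------------------------
# body demote (3D T2 analog)
# ----------------------------------------------------------------------

def body_demote(mesh: Mesh, bid: int, config: QualityConfig) -> OperationRecord:
    """Collapse a body into a new vertex at its centroid.

    A fixed-point pass first determines every body invalidated by the
    collapse (a body is invalid with fewer than four surfaces); all removed
    bodies and their exclusive surfaces are destroyed, and each boundary
    surface (shared with a surviving body) is surface-demoted onto the same
    new vertex.
    """
    rec = OperationRecord("body_demote", bid)
    if bid not in mesh.bodies:
        rec.reason = "unknown body"
        return rec
    centroid = body_measures(mesh, bid).centroid
    removed_bodies = {bid}
    while True:
        surfs_of_removed = {s for b in removed_bodies
                            for s in mesh.bodies[b].surface_ids}
        collapsed = {v for s in surfs_of_removed
                     for v in mesh.surfaces[s].cycle}
        cascade = set()
        for s, surf in mesh.surfaces.items():
            if s in surfs_of_removed:
                continue
            if not collapsed.intersection(surf.cycle):
                continue
            distinct = {v for v in surf.cycle if v not in collapsed}
            n_after = len(distinct) + 1      # + the single new vertex
            if n_after < 3:
                cascade.add(s)
        gone = surfs_of_removed | cascade
        newly_invalid = {b for b, body in mesh.bodies.items()
                         if b not in removed_bodies
                         and len(body.surface_ids - gone) < 4}
        if not newly_invalid:
            break
        removed_bodies |= newly_invalid
    snap = _snapshot(mesh)
    new_v = mesh.add_vertex(centroid)
    surviving_touched = set()
    for b in sorted(removed_bodies):
        mesh.remove_body(b)
    for s in sorted(surfs_of_removed | cascade):
        for b in mesh.surfaces[s].body_ids:
            surviving_touched.add(b)
        mesh.remove_surface(s)
    # rewrite every surviving surface that referenced a collapsed vertex
    for s in sorted(mesh.surfaces):
        cyc = mesh.surfaces[s].cycle
        if not collapsed.intersection(cyc):
            continue
        new_cyc: list[int] = []
        inserted = False
        for v in cyc:
            if v in collapsed:
                if not inserted:
                    new_cyc.append(new_v)
                    inserted = True
            else:
                new_cyc.append(v)
        _set_cycle(mesh, s, new_cyc)
    orphans = [v for v, vert in mesh.vertices.items()
               if not vert.surface_ids and v != new_v]
    for v in orphans:
        mesh.remove_vertex(v)
    if not mesh.vertices[new_v].surface_ids and len(mesh.vertices) > 1:
        mesh.remove_vertex(new_v)
        created = []
    else:
        created = [new_v]
    problems = validate_mesh(mesh)
    if problems:
        _restore(mesh, snap)
        rec.reason = f"body demote would invalidate mesh: {problems[0]}"
        return rec
    rec.accepted = True
    rec.created = created
    rec.affected = ({("b", b) for b in removed_bodies | surviving_touched}
                    | {("s", s) for s in surfs_of_removed | cascade}
                    | {("v", v) for v in collapsed} | {("v", new_v)})
    return rec


# ----------------------------------------------------------------------
# vertex insert (T3)
# ----------------------------------------------------------------------

def vertex_insert(mesh: Mesh, vid: int, sid: int, edge: tuple[int, int],
                  config: QualityConfig) -> OperationRecord:
    """Insert a penetrating vertex into the cycle of an unconnected surface.

    ``edge`` gives the penetrated edge's endpoints, consecutive in the
    surface's cycle; the vertex is inserted between them (T3 transition).
    """
    rec = OperationRecord("vertex_insert", sid)
    if vid not in mesh.vertices or sid not in mesh.surfaces:
        rec.reason = "unknown object"
        return rec
    if sid in mesh.vertices[vid].surface_ids:
        rec.reason = "vertex already defines the surface"
        return rec
    # connectedness: the vertex's surfaces may not share a vertex with sid
    target_verts = set(mesh.surfaces[sid].cycle)
    for s in mesh.vertices[vid].surface_ids:
        if target_verts.intersection(mesh.surfaces[s].cycle):
            rec.reason = "surfaces are connected"
            return rec
    a, b = edge
    cyc = mesh.surfaces[sid].cycle
    n = len(cyc)
    pos = None
    for k in range(n):
        if (cyc[k], cyc[(k + 1) % n]) in ((a, b), (b, a)):
            pos = k
            break
    if pos is None:
        rec.reason = "edge not found in cycle"
        return rec
    new_cyc = cyc[: pos + 1] + [vid] + cyc[pos + 1:]
    _set_cycle(mesh, sid, new_cyc)
    rec.accepted = True
    rec.affected = {("v", vid), ("v", a), ("v", b), ("s", sid)}
    return rec


def _insert_candidates(mesh: Mesh, prev_positions: np.ndarray):
    """(vertex, surface, edge, t) for motion segments crossing boundary edges.

    Only free-boundary edges (single owning surface) and vertices lying on at
    least one such edge are examined: in a confluent planar tissue a vertex
    reaches an unconnected surface only across the free boundary.
    """
    owners = mesh.edge_owners()
    boundary_edges = [(e, own[0]) for e, own in sorted(owners.items())
                      if len(own) == 1]
    if not boundary_edges:
        return []
    bverts = sorted({v for (a, b), _ in boundary_edges for v in (a, b)}
                    & set(range(prev_positions.shape[0])) & set(mesh.vertices))
    if not bverts:
        return []
    V = np.asarray(bverts, dtype=int)
    p = prev_positions[V]
    q = mesh.positions[V]
    moved = ~np.all(p == q, axis=1)
    if not moved.any():
        return []
    V, p, q = V[moved], p[moved], q[moved]
    ea = np.asarray([a for (a, b), _ in boundary_edges], dtype=int)
    eb = np.asarray([b for (a, b), _ in boundary_edges], dtype=int)
    A = mesh.positions[ea]
    B = mesh.positions[eb]
    # broadcast segment-segment intersection: motion p->q vs edge A->B
    r = q - p                                 # (nv, 2)
    s = B - A                                 # (ne, 2)
    denom = r[:, None, 0] * s[None, :, 1] - r[:, None, 1] * s[None, :, 0]
    ap = A[None, :, :] - p[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ap[:, :, 0] * s[None, :, 1] - ap[:, :, 1] * s[None, :, 0]) / denom
        u = (ap[:, :, 0] * r[:, None, 1] - ap[:, :, 1] * r[:, None, 0]) / denom
    hit = (np.abs(denom) > 1e-300) & (t > 0.0) & (t <= 1.0) & (u >= 0.0) & (u <= 1.0)
    out = []
    for i in np.nonzero(hit.any(axis=1))[0]:
        vid = int(V[i])
        my_verts = {w for sid in mesh.vertices[vid].surface_ids
                    for w in mesh.surfaces[sid].cycle}
        best = None
        for j in np.nonzero(hit[i])[0]:
            a, b = int(ea[j]), int(eb[j])
            sid = boundary_edges[j][1]
            if vid in (a, b) or {a, b} & my_verts:
                continue
            if my_verts.intersection(mesh.surfaces[sid].cycle):
                continue            # connected surfaces never trigger T3
            tj = float(t[i, j])
            if best is None or tj < best[3]:
                best = (vid, sid, (a, b), tj)
        if best is not None:
            if best[3] < 1.0:
                logger.debug("vertex %d crossed an edge mid-step (t=%.3f)",
                             vid, best[3])
            out.append(best)
    return out


# ----------------------------------------------------------------------
# scheduling
# ----------------------------------------------------------------------

def apply_quality_operations(mesh: Mesh, forces: np.ndarray,
                             config: QualityConfig, rng: np.random.Generator,
                             prev_positions: np.ndarray | None = None,
                             step: int | None = None) -> list[OperationRecord]:
    """Enumerate, prioritize and serially apply all quality operations.

    Candidates are processed per hierarchy level (vertices, surfaces, bodies),
    within each level by ascending owner id; an operation is skipped when any
    object it would affect has already been affected this step, so the
    intersection of accepted operations' affected sets is empty.
    """
    records: list[OperationRecord] = []
    if not config.enabled:
        return records
    affected: set = set()

    def attempt(rec_fn, tentative) -> OperationRecord | None:
        if affected.intersection(tentative):
            return None
        rec = rec_fn()
        if rec.accepted:
            affected.update(rec.affected)
        return rec

    # ---- vertex level: merges and splits -----------------------------
    candidates: list[tuple[int, int, tuple]] = []
    if config.enable_merge:
        owners = mesh.edge_owners()
        for (a, b) in sorted(owners):
            d = float(np.linalg.norm(mesh.position(a) - mesh.position(b)))
            if d < config.merge_distance:
                candidates.append((min(a, b), 0, (a, b)))
    if config.enable_split:
        owners = mesh.edge_owners()
        degree: dict[int, set[int]] = {}
        for (a, b) in owners:
            degree.setdefault(a, set()).add(b)
            degree.setdefault(b, set()).add(a)
        for vid in sorted(degree):
            if len(degree[vid]) >= 4:
                candidates.append((vid, 1, (vid,)))
    candidates.sort()
    for owner, kind, args in candidates:
        if kind == 0:
            a, b = args
            if a not in mesh.vertices or b not in mesh.vertices:
                continue
            tentative = ({("v", a), ("v", b)}
                         | {("s", s) for s in mesh.vertices[a].surface_ids}
                         | {("s", s) for s in mesh.vertices[b].surface_ids})
            rec = attempt(lambda: vertex_merge(mesh, a, b, rng, config), tentative)
        else:
            (vid,) = args
            if vid not in mesh.vertices:
                continue
            tentative = ({("v", vid)}
                         | {("s", s) for s in mesh.vertices[vid].surface_ids})
            rec = attempt(lambda: vertex_split(mesh, vid, forces, config), tentative)
        if rec is not None:
            rec.step = step
            records.append(rec)

    # ---- surface level: demotes and inserts --------------------------
    surf_candidates: list[tuple[int, int, tuple]] = []
    if config.enable_surface_demote and config.surface_demote_area > 0.0:
        for sid in sorted(mesh.surfaces):
            if surface_measures(mesh, sid).area < config.surface_demote_area:
                surf_candidates.append((sid, 0, (sid,)))
    if (config.enable_insert and mesh.dim == 2 and not mesh.bodies
            and prev_positions is not None):
        for vid, sid, edge, _t in _insert_candidates(mesh, prev_positions):
            surf_candidates.append((sid, 1, (vid, sid, edge)))
    surf_candidates.sort(key=lambda c: (c[0], c[1]))
    for owner, kind, args in surf_candidates:
        if kind == 0:
            (sid,) = args
            if sid not in mesh.surfaces:
                continue
            surf = mesh.surfaces[sid]
            tentative = ({("s", sid)} | {("v", v) for v in surf.cycle}
                         | {("s", s) for v in surf.cycle
                            for s in mesh.vertices[v].surface_ids}
                         | {("b", b) for b in surf.body_ids})
            rec = attempt(lambda: surface_demote(mesh, sid, config), tentative)
        else:
            vid, sid, edge = args
            if vid not in mesh.vertices or sid not in mesh.surfaces:
                continue
            tentative = {("v", vid), ("v", edge[0]), ("v", edge[1]), ("s", sid)}
            rec = attempt(lambda: vertex_insert(mesh, vid, sid, edge, config),
                          tentative)
        if rec is not None:
            rec.step = step
            records.append(rec)

    # ---- body level: demotes -----------------------------------------
    if config.enable_body_demote and config.body_demote_volume > 0.0 and mesh.dim == 3:
        for bid in sorted(mesh.bodies):
            if bid not in mesh.bodies:
                continue
            try:
                vol = body_measures(mesh, bid).volume
            except Exception:
                vol = 0.0
            if vol < config.body_demote_volume:
                body = mesh.bodies[bid]
                tentative = ({("b", bid)}
                             | {("s", s) for s in body.surface_ids}
                             | {("v", v) for s in body.surface_ids
                                for v in mesh.surfaces[s].cycle})
                rec = attempt(lambda: body_demote(mesh, bid, config), tentative)
                if rec is not None:
                    rec.step = step
                    records.append(rec)

    if config.validate_after_ops:
        problems = validate_mesh(mesh)
        if problems:
            raise AssertionError(f"mesh invalid after quality operations: {problems}")
    return records
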