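"""Versioned JSON persistence of full simulation state.

A state document carries the mesh, the particle system, every actor binding,
the solver and quality configurations, the RNG state and the clock, so a
saved simulation resumes bit-exactly (same platform, same build).  Floats
round-trip exactly through JSON because Python prints shortest-round-trip
representations.  Event hooks are code, not data, and must be re-registered
after loading.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import actors as A
from .mesh import Mesh
from .solver import SimState, SolverConfig
from .topology import QualityConfig

__all__ = ["save_state", "load_state", "mesh_to_dict", "mesh_from_dict",
           "StateIOError", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class StateIOError(ValueError):
    pass


# ----------------------------------------------------------------------
# mesh
# ----------------------------------------------------------------------

def mesh_to_dict(mesh: Mesh) -> dict:
    return {
        "dim": mesh.dim,
        "domain_box": None if mesh.domain_box is None else mesh.domain_box.tolist(),
        "vertices": [{"id": v, "position": mesh.position(v).tolist()}
                     for v in sorted(mesh.vertices)],
        "surfaces": [{"id": s, "cycle": surf.cycle, "type": surf.type_id,
                      "drag_density": surf.drag_density}
                     for s, surf in sorted(mesh.surfaces.items())],
        "bodies": [{"id": b, "surfaces": sorted(body.surface_ids),
                    "type": body.type_id, "drag_density": body.drag_density}
                   for b, body in sorted(mesh.bodies.items())],
        "next_ids": [mesh._next_vertex_id, mesh._next_surface_id, mesh._next_body_id],
    }


def mesh_from_dict(doc: dict) -> Mesh:
    mesh = Mesh(dim=doc["dim"],
                domain_box=None if doc["domain_box"] is None else doc["domain_box"])
    nv, ns, nb = doc["next_ids"]
    # ids may be sparse (tombstoned); allocate densely then drop the gaps
    present_v = {d["id"] for d in doc["vertices"]}
    pos = {d["id"]: d["position"] for d in doc["vertices"]}
    for i in range(nv):
        mesh.add_vertex(pos.get(i, [0.0] * doc["dim"]))
    for i in range(nv):
        if i not in present_v:
            del mesh.vertices[i]
    surf_docs = {d["id"]: d for d in doc["surfaces"]}
    for i in range(ns):
        if i in surf_docs:
            d = surf_docs[i]
            sid = mesh.add_surface(d["cycle"], type_id=d["type"])
            assert sid == i
            mesh.surfaces[sid].drag_density = d["drag_density"]
        else:
            mesh._next_surface_id += 1
    body_docs = {d["id"]: d for d in doc["bodies"]}
    for i in range(nb):
        if i in body_docs:
            d = body_docs[i]
            bid = mesh.add_body(d["surfaces"], type_id=d["type"],
                                drag_density=d["drag_density"])
            assert bid == i
        else:
            mesh._next_body_id += 1
    return mesh


# ----------------------------------------------------------------------
# actors / bindings
# ----------------------------------------------------------------------

def _pairs_to_list(matrix: dict) -> list:
    return [[a, b, v] for (a, b), v in sorted(matrix.items())]


def _pairs_from_list(items: list) -> dict:
    return {(int(a), int(b)): float(v) for a, b, v in items}


def _actor_to_dict(actor: A.Actor) -> dict:
    t = type(actor).__name__
    if isinstance(actor, A.SurfaceAreaConstraint):
        params = {"lam": actor.lam, "target_area": actor.target_area}
    elif isinstance(actor, A.PerimeterConstraint):
        params = {"lam": actor.lam, "target_perimeter": actor.target_perimeter}
    elif isinstance(actor, A.EdgeTension):
        params = {"lam": actor.lam, "exponent": actor.exponent}
    elif isinstance(actor, (A.Adhesion2D, A.Adhesion3D)):
        params = {"matrix": _pairs_to_list(actor.matrix)}
    elif isinstance(actor, A.SurfaceTraction):
        params = {"traction": actor.traction.tolist()}
    elif isinstance(actor, A.NormalStress):
        params = {"magnitude": actor.magnitude}
    elif isinstance(actor, A.BodyForce):
        params = {"force": actor.force.tolist()}
    elif isinstance(actor, A.VolumeConstraint):
        params = {"lam": actor.lam, "target_volume": actor.target_volume}
    elif isinstance(actor, A.BodySurfaceAreaConstraint):
        params = {"lam": actor.lam, "target_area": actor.target_area}
    elif isinstance(actor, (A.FlatSurfaceConstraint, A.ConvexPolygonConstraint)):
        params = {"kappa": actor.kappa}
    elif isinstance(actor, A.RandomMotility):
        params = {"magnitude": actor.magnitude}
    else:
        raise StateIOError(f"actor {t} is not serializable")
    return {"kind": t, "params": params}


def _actor_from_dict(doc: dict) -> A.Actor:
    kind = doc["kind"]
    params = dict(doc["params"])
    if kind in ("Adhesion2D", "Adhesion3D"):
        params["matrix"] = _pairs_from_list(params["matrix"])
    cls = getattr(A, kind, None)
    if cls is None:
        raise StateIOError(f"unknown actor kind {kind!r}")
    return cls(**params)


def _bindings_to_list(table: A.BindingTable) -> list:
    return [{"actor": _actor_to_dict(b.actor), "kind": b.kind, "target": b.target}
            for b in table.entries]


def _bindings_from_list(items: list) -> A.BindingTable:
    table = A.BindingTable()
    for d in items:
        actor = _actor_from_dict(d["actor"])
        table.entries.append(A.Binding(actor, d["kind"], d["target"]))
    return table


# ----------------------------------------------------------------------
# state
# ----------------------------------------------------------------------

def _config_hash(doc: dict) -> str:
    payload = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_state(state: SimState, path) -> None:
    config_echo = {
        "solver": dataclasses.asdict(state.solver),
        "quality": dataclasses.asdict(state.quality),
        "bindings": _bindings_to_list(state.bindings),
    }
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": _config_hash(config_echo),
        "config": config_echo,
        "mesh": mesh_to_dict(state.mesh),
        "particles": None if state.particles is None else state.particles.to_dict(),
        "rng_state": state.rng.bit_generator.state,
        "step_count": state.step_count,
        "time": state.time,
    }
    Path(path).write_text(json.dumps(doc))


def load_state(path) -> SimState:
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise StateIOError(f"cannot read state document: {exc}") from None
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise StateIOError(
            f"state schema version {version!r} does not match {SCHEMA_VERSION}")
    mesh = mesh_from_dict(doc["mesh"])
    table = _bindings_from_list(doc["config"]["bindings"])
    solver = SolverConfig(**doc["config"]["solver"])
    quality = QualityConfig(**doc["config"]["quality"])
    rng = np.random.default_rng()
    rng.bit_generator.state = doc["rng_state"]
    particles = None
    if doc["particles"] is not None:
        from .particles import ParticleSystem
        particles = ParticleSystem.from_dict(doc["particles"])
    state = SimState(mesh=mesh, bindings=table, solver=solver, quality=quality,
                     rng=rng, particles=particles,
                     step_count=doc["step_count"], time=doc["time"])
    return state
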