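"""YAML simulation configs: mesh source, actor bindings, solver and quality.

Schema (all sections optional unless noted)::

    mesh:                       # exactly one source
      generate: {tiling: square, rows: 4, cols: 4, cell_area: 1.0}
      lattice:  {nx: 2, ny: 2, nz: 2, edge: 1.0}
      obj:      path/to/mesh.obj
      state:    path/to/state.json      # resume a saved simulation
    domain: [[xmin, ymin], [xmax, ymax]]
    actors:
      - kind: surface_area_constraint   # see KIND_MAP for the catalog
        params: {lam: 50.0, target_area: 1.0}
        bind: {surface_type: 1}         # or surface_id / body_type / body_id
                                        # or {vertices: true} / {mesh: true}
    solver:  {dt: 0.0025, drag_mode: fixed, M: 1.0}
    quality: {merge_distance: 0.1, split_distance: 0.2,
              demote_area: 0.0, demote_volume: 0.0,
              enable: {merge: true, split: true, surface_demote: true,
                       body_demote: true, insert: true}}

Adhesion matrices are written as mappings with "t1,t2" keys or as
``[[t1, t2, value], ...]`` lists.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import actors as A
from .meshgen import LatticeSpec, SheetSpec, generate_cube_lattice, generate_sheet
from .objio import import_obj
from .solver import SimState, SolverConfig
from .topology import QualityConfig

__all__ = ["load_config", "build_state", "KIND_MAP"]

KIND_MAP = {
    "surface_traction": A.SurfaceTraction,
    "body_force": A.BodyForce,
    "normal_stress": A.NormalStress,
    "surface_area_constraint": A.SurfaceAreaConstraint,
    "perimeter_constraint": A.PerimeterConstraint,
    "edge_tension": A.EdgeTension,
    "adhesion_2d": A.Adhesion2D,
    "adhesion_3d": A.Adhesion3D,
    "flat_surface_constraint": A.FlatSurfaceConstraint,
    "convex_polygon_constraint": A.ConvexPolygonConstraint,
    "body_surface_area_constraint": A.BodySurfaceAreaConstraint,
    "volume_constraint": A.VolumeConstraint,
    "random_motility": A.RandomMotility,
}


def _parse_matrix(raw) -> dict[tuple[int, int], float]:
    out: dict[tuple[int, int], float] = {}
    if isinstance(raw, dict):
        for key, val in raw.items():
            a, b = (int(x) for x in str(key).split(","))
            out[(a, b)] = float(val)
    else:
        for a, b, val in raw:
            out[(int(a), int(b))] = float(val)
    return out


def _build_actor(doc: dict) -> A.Actor:
    kind = doc["kind"]
    if kind not in KIND_MAP:
        raise A.ConfigError(f"unknown actor kind {kind!r}")
    params = dict(doc.get("params", {}))
    if kind in ("adhesion_2d", "adhesion_3d"):
        params["matrix"] = _parse_matrix(params["matrix"])
    return KIND_MAP[kind](**params)


def _build_mesh(doc: dict):
    src = doc.get("mesh", {})
    given = [k for k in ("generate", "lattice", "obj", "state") if k in src]
    if len(given) != 1:
        raise A.ConfigError("config needs exactly one mesh source "
                            "(generate | lattice | obj | state)")
    key = given[0]
    if key == "generate":
        g = src["generate"]
        return generate_sheet(SheetSpec(
            tiling=g.get("tiling", "square"),
            n_rows=int(g.get("rows", 1)), n_cols=int(g.get("cols", 1)),
            cell_area=float(g.get("cell_area", 1.0)))), None
    if key == "lattice":
        g = src["lattice"]
        return generate_cube_lattice(LatticeSpec(
            nx=int(g.get("nx", 1)), ny=int(g.get("ny", 1)),
            nz=int(g.get("nz", 1)), edge=float(g.get("edge", 1.0)))), None
    if key == "obj":
        return import_obj(src["obj"]), None
    from .state_io import load_state
    return None, load_state(src["state"])


def build_state(doc: dict, seed: int = 0) -> SimState:
    """Assemble a :class:`SimState` from a parsed config document."""
    mesh, resumed = _build_mesh(doc)
    if resumed is not None:
        state = resumed
        mesh = state.mesh
    else:
        table = A.BindingTable()
        sol = doc.get("solver", {})
        solver = SolverConfig(
            dt=float(sol.get("dt", 0.0025)),
            drag_mode=sol.get("drag_mode", "fixed"),
            M=float(sol.get("M", 1.0)))
        q = doc.get("quality", {})
        enable = q.get("enable", {})
        quality = QualityConfig(
            merge_distance=float(q.get("merge_distance", 0.1)),
            split_distance=float(q.get("split_distance", 0.2)),
            surface_demote_area=float(q.get("demote_area", 0.0)),
            body_demote_volume=float(q.get("demote_volume", 0.0)),
            enable_merge=bool(enable.get("merge", True)),
            enable_split=bool(enable.get("split", True)),
            enable_surface_demote=bool(enable.get("surface_demote", True)),
            enable_body_demote=bool(enable.get("body_demote", True)),
            enable_insert=bool(enable.get("insert", True)),
            enabled=bool(q.get("enabled", True)))
        state = SimState(mesh=mesh, bindings=table, solver=solver,
                         quality=quality, rng=np.random.default_rng(seed))
    if "domain" in doc:
        mesh.domain_box = np.asarray(doc["domain"], dtype=float)
    types = doc.get("surface_types", {})
    for sid, t in types.items():
        mesh.surfaces[int(sid)].type_id = int(t)
    for entry in doc.get("actors", []):
        actor = _build_actor(entry)
        bind = dict(entry.get("bind", {"mesh": True}))
        state.bindings.bind(actor, **{k: (v if isinstance(v, bool) else int(v))
                                      for k, v in bind.items()})
    return state


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
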