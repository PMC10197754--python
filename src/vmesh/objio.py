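"""Wavefront OBJ import/export for polygonal vertex-model meshes.

Only ``v`` and ``f`` records are handled; faces stay polygons (no
triangulation), since the surface cycles are the model's topology.  OBJ
indices are 1-based and mapped to 0-based mesh ids; face winding is
preserved as cycle order.  Bodies are reconstructed from an explicit sidecar
manifest (JSON list of face-index groups, 1-based in file order) rather than
by automatic closed-shell detection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import Mesh

__all__ = ["import_obj", "export_obj"]


class ObjError(ValueError):
    pass


def export_obj(mesh: Mesh, path, manifest_path=None) -> None:
    """Write surfaces as polygonal faces; optionally write a body manifest."""
    path = Path(path)
    vids = sorted(mesh.vertices)
    index = {v: i + 1 for i, v in enumerate(vids)}
    lines = ["# vmesh OBJ export"]
    for v in vids:
        p = mesh.position(v)
        x, y = float(p[0]), float(p[1])
        z = float(p[2]) if mesh.dim == 3 else 0.0
        lines.append(f"v {x!r} {y!r} {z!r}")
    sids = sorted(mesh.surfaces)
    face_no = {s: i + 1 for i, s in enumerate(sids)}
    for s in sids:
        lines.append("f " + " ".join(str(index[v]) for v in mesh.surfaces[s].cycle))
    path.write_text("\n".join(lines) + "\n")
    if mesh.bodies:
        mpath = Path(manifest_path) if manifest_path else path.with_suffix(".bodies.json")
        groups = [sorted(face_no[s] for s in mesh.bodies[b].surface_ids)
                  for b in sorted(mesh.bodies)]
        mpath.write_text(json.dumps({"bodies": groups}))


def import_obj(path, manifest_path=None, weld_tolerance_factor: float = 1e-9) -> Mesh:
    """Read an OBJ file into a mesh; faces become surfaces.

    Vertices are welded by coordinate match within
    ``weld_tolerance_factor * bounding-box diagonal``.  If a manifest is
    given (or found alongside the file), its face groups become bodies.
    Degenerate faces (repeated indices, fewer than three vertices) raise an
    error listing the offending line numbers.
    """
    path = Path(path)
    raw_vertices: list[tuple[float, float, float]] = []
    faces: list[tuple[int, list[int]]] = []
    bad: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "v":
            if len(parts) < 3:
                bad.append(lineno)
                continue
            x, y = float(parts[1]), float(parts[2])
            z = float(parts[3]) if len(parts) > 3 else 0.0
            raw_vertices.append((x, y, z))
        elif parts[0] == "f":
            try:
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
            except ValueError:
                bad.append(lineno)
                continue
            idx = [i - 1 if i > 0 else len(raw_vertices) + i for i in idx]
            if len(idx) < 3 or len(set(idx)) != len(idx) \
                    or any(i < 0 or i >= len(raw_vertices) for i in idx):
                bad.append(lineno)
                continue
            faces.append((lineno, idx))
    if bad:
        raise ObjError(f"invalid OBJ records at lines {bad}")
    if not raw_vertices:
        raise ObjError("OBJ file contains no vertices")
    coords = np.asarray(raw_vertices, dtype=float)
    diag = float(np.linalg.norm(coords.max(axis=0) - coords.min(axis=0)))
    tol = max(weld_tolerance_factor * diag, 1e-300)
    planar = bool(np.all(coords[:, 2] == 0.0))
    mesh = Mesh(dim=2 if planar else 3)
    welded: dict[tuple, int] = {}
    remap: list[int] = []
    for c in coords:
        key = tuple(np.round(c / tol).astype(np.int64)) if diag > 0 else tuple(c)
        if key not in welded:
            welded[key] = mesh.add_vertex(c[:2] if planar else c)
        remap.append(welded[key])
    face_sids: list[int] = []
    for lineno, idx in faces:
        cyc = [remap[i] for i in idx]
        if len(set(cyc)) != len(cyc):
            raise ObjError(f"face at line {lineno} degenerates after vertex welding")
        face_sids.append(mesh.add_surface(cyc))
    mpath = Path(manifest_path) if manifest_path else path.with_suffix(".bodies.json")
    if mpath.exists():
        doc = json.loads(mpath.read_text())
        for group in doc.get("bodies", []):
            mesh.add_body([face_sids[i - 1] for i in group])
    return mesh
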