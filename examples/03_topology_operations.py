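"""Discrete topology operations: the T1 neighbor exchange and the T2 collapse.

First a scripted T1: four cells meet along a short central edge; merging its
endpoints forms a four-valent vertex, and a force pattern that stretches the
junction sideways drives an accepted vertex split whose new edge connects
the previously unconnected top/bottom cells — the classic neighbor exchange.
Then a T2: the center cell of a 3x3 sheet is shrunk below the demote
threshold and collapses into a single vertex.
"""

import numpy as np
import vmesh as vm

cfg = vm.QualityConfig(merge_distance=0.5, split_distance=0.6)
rng = np.random.default_rng(0)

# ---- T1: merge then split ------------------------------------------------
m = vm.Mesh(dim=2)
v1 = m.add_vertex((0, 0.2)); v2 = m.add_vertex((0, -0.2))
lt = m.add_vertex((-1, 1)); lb = m.add_vertex((-1, -1))
rt = m.add_vertex((1, 1)); rb = m.add_vertex((1, -1))
tt = m.add_vertex((0, 2)); bb = m.add_vertex((0, -2))
left = m.add_surface([lb, v2, v1, lt])
right = m.add_surface([rb, rt, v1, v2])
top = m.add_surface([v1, rt, tt, lt])
bottom = m.add_surface([v2, lb, bb, rb])
print("before: left-right share an edge of length",
      round(vm.neighbors_and_shared_edges(m, left)[right], 3))

rec = vm.vertex_merge(m, v1, v2, rng, cfg)
center = v1 if v1 in m.vertices else v2
print(f"merge accepted={rec.accepted}; vertex {center} now has "
      f"{len(m.vertex_neighbors(center))} neighbors")

forces = np.zeros((m.positions.shape[0], 2))
forces[rt] = (2.0, 0.1); forces[rb] = (2.0, -0.1)   # pull right pair right
forces[lt] = (-1.0, 0.1); forces[lb] = (-1.0, -0.1)  # pull left pair left
rec = vm.vertex_split(m, center, forces, cfg)
new = rec.created[0]
print(f"split accepted={rec.accepted}; new edge {center}-{new} is shared by "
      f"surfaces {m.edge_owners()[tuple(sorted((center, new)))]} "
      f"(top={top}, bottom={bottom}) -> neighbors exchanged")

# ---- T2: surface demote --------------------------------------------------
sheet = vm.generate_sheet(vm.SheetSpec("square", 3, 3))
mid = 4
c = vm.surface_centroid(sheet, mid)
for v in sheet.surfaces[mid].cycle:
    sheet.set_position(v, c + 0.02 * (sheet.position(v) - c))
rec = vm.surface_demote(sheet, mid, vm.QualityConfig())
print(f"\nT2: demoted the shrunken center cell; accepted={rec.accepted}; "
      f"{len(sheet.surfaces)} cells remain (was 9), mesh valid: "
      f"{vm.validate_mesh(sheet) == []}")
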