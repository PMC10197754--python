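"""Triangulated geometry of vertex-model meshes.

Builds a small confluent sheet and a cube lattice and prints the
triangulation-based measures: surface areas and normals, per-vertex area
shares, divergence-theorem body volumes and per-vertex volume shares.  The
per-vertex quantities always sum back to the parent object's measure — that
conservation is what lets forces defined on surfaces and bodies act
consistently on vertices.
"""

import vmesh as vm

sheet = vm.generate_sheet(vm.SheetSpec("square", 2, 2))
print(f"2x2 sheet: {len(sheet.vertices)} vertices, {len(sheet.surfaces)} cells")
m = vm.surface_measures(sheet, 0)
print(f"cell 0: area {m.area:.3f}, perimeter {m.perimeter:.3f}, normal {m.normal}")
shares = [vm.vertex_area_contribution(sheet, v, 0) for v in sheet.surfaces[0].cycle]
print(f"vertex area shares of cell 0: {shares} (sum {sum(shares):.3f})")
center = 4  # the vertex shared by all four cells
print(f"vertex {center} total area: {vm.vertex_area(sheet, center):.3f} "
      "(a quarter of each of the four cells)")

cube = vm.generate_cube_lattice(vm.LatticeSpec(1, 1, 1))
bm = vm.body_measures(cube, 0)
print(f"\nunit cube: surface area {bm.area:.3f}, volume {bm.volume:.3f}, "
      f"centroid {bm.centroid}")
corner = vm.vertex_volume_contribution(cube, 0, 0)
print(f"corner vertex volume share: {corner:.4f} "
      f"(8 corners x {corner:.4f} = {8 * corner:.3f} = body volume)")
for body in cube.bodies.values():
    body.drag_density = 2.0
print(f"corner vertex drag at rho = 2: {vm.vertex_drag(cube, 0):.4f}")
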