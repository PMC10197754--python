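"""Quality operations: T1 merge/split, T2 demotes, T3 insert, scheduling."""

import numpy as np
import pytest

import vmesh as vm
from vmesh import topology as T
from conftest import four_cell_junction


@pytest.fixture
def cfg():
    return vm.QualityConfig(merge_distance=0.5, split_distance=0.6)


class TestVertexMerge:
    def test_close_connected_pair_merges_to_midpoint(self, cfg, rng):
        m, ids = four_cell_junction()
        n_surf = len(m.surfaces)
        rec = vm.vertex_merge(m, ids["v1"], ids["v2"], rng, cfg)
        assert rec.accepted
        assert vm.validate_mesh(m) == []
        assert len(m.surfaces) == n_surf           # merges never remove cells
        survivor = ids["v1"] if ids["v1"] in m.vertices else ids["v2"]
        assert np.allclose(m.position(survivor), (0.0, 0.0))
        # every cycle containing the pair shrank by exactly one
        assert len(m.surfaces[ids["left"]].cycle) == 3
        assert len(m.surfaces[ids["right"]].cycle) == 3

    def test_distance_gate(self, rng):
        m, ids = four_cell_junction()
        tight = vm.QualityConfig(merge_distance=0.1, split_distance=0.2)
        rec = vm.vertex_merge(m, ids["v1"], ids["v2"], rng, tight)
        assert not rec.accepted and "distance" in rec.reason

    def test_triangle_cycle_blocks_merge(self, cfg, rng):
        m = vm.Mesh(dim=2)
        a = m.add_vertex((0, 0))
        b = m.add_vertex((0.1, 0))
        c = m.add_vertex((0, 0.1))
        m.add_surface([a, b, c])
        rec = vm.vertex_merge(m, a, b, rng, cfg)
        assert not rec.accepted and "below 3" in rec.reason

    def test_unconnected_pair_rejected(self, cfg, rng):
        m = vm.generate_sheet(vm.SheetSpec("square", 2, 2))
        rec = vm.vertex_merge(m, 0, 8, rng, cfg)      # opposite corners
        assert not rec.accepted

    def test_removal_choice_is_seed_deterministic(self, cfg):
        kept = []
        for _ in range(2):
            m, ids = four_cell_junction()
            vm.vertex_merge(m, ids["v1"], ids["v2"],
                            np.random.default_rng(9), cfg)
            kept.append(ids["v1"] in m.vertices)
        assert kept[0] == kept[1]


class TestVertexSplit:
    def split_forces(self, m, ids):
        forces = np.zeros((m.positions.shape[0], 2))
        forces[ids["rt"]] = (2.0, 0.1)
        forces[ids["rb"]] = (2.0, -0.1)
        forces[ids["lt"]] = (-1.0, 0.1)
        forces[ids["lb"]] = (-1.0, -0.1)
        return forces

    def test_t1_exchanges_neighbors_and_restores_vertex_count(self, cfg, rng):
        m, ids = four_cell_junction()
        n_before = len(m.vertices)
        vm.vertex_merge(m, ids["v1"], ids["v2"], rng, cfg)
        assert len(m.vertices) == n_before - 1
        center = ids["v1"] if ids["v1"] in m.vertices else ids["v2"]
        rec = vm.vertex_split(m, center, self.split_forces(m, ids), cfg)
        assert rec.accepted
        assert vm.validate_mesh(m) == []
        assert len(m.vertices) == n_before         # T1 reversibility
        new = rec.created[0]
        owners = m.edge_owners()[tuple(sorted((center, new)))]
        # the new edge joins the cells that were unconnected before (T1)
        assert sorted(owners) == sorted([ids["top"], ids["bottom"]])
        assert m.surfaces[ids["left"]].id not in owners
        # split pair separated by exactly the split distance
        d = np.linalg.norm(m.position(center) - m.position(new))
        assert d == pytest.approx(cfg.split_distance)

    def test_zero_relative_force_rejected(self, cfg, rng):
        m, ids = four_cell_junction()
        vm.vertex_merge(m, ids["v1"], ids["v2"], rng, cfg)
        center = ids["v1"] if ids["v1"] in m.vertices else ids["v2"]
        rec = vm.vertex_split(m, center,
                              np.zeros((m.positions.shape[0], 2)), cfg)
        assert not rec.accepted and "zero total relative force" in rec.reason

    def test_compression_rejected(self, cfg, rng):
        m, ids = four_cell_junction()
        vm.vertex_merge(m, ids["v1"], ids["v2"], rng, cfg)
        center = ids["v1"] if ids["v1"] in m.vertices else ids["v2"]
        forces = -self.split_forces(m, ids)     # pushes toward the vertex
        rec = vm.vertex_split(m, center, forces, cfg)
        assert not rec.accepted

    def test_low_valence_rejected(self, cfg):
        m = vm.generate_sheet(vm.SheetSpec("square", 2, 2))
        corner = 0
        forces = np.ones((len(m.vertices), 2))
        rec = vm.vertex_split(m, corner, forces, cfg)
        assert not rec.accepted and "valence" in rec.reason


class TestSurfaceDemote:
    def shrink(self, m, sid, factor=0.02):
        c = vm.surface_centroid(m, sid)
        for v in m.surfaces[sid].cycle:
            m.set_position(v, c + factor * (m.position(v) - c))

    def test_interior_cell_collapses_to_vertex(self):
        m = vm.generate_sheet(vm.SheetSpec("square", 3, 3))
        self.shrink(m, 4)
        rec = vm.surface_demote(m, 4, vm.QualityConfig())
        assert rec.accepted
        assert vm.validate_mesh(m) == []
        assert len(m.surfaces) == 8
        new = rec.created[0]
        # the new vertex replaces the cell in all 8 surrounding cycles
        assert len(m.vertices[new].surface_ids) == 8
        # edge-sharing neighbors lost one net vertex, corner neighbors none
        for s in (1, 3, 5, 7):
            assert len(m.surfaces[s].cycle) == 3
        for s in (0, 2, 6, 8):
            assert len(m.surfaces[s].cycle) == 4

    def test_four_surface_body_blocks_demote(self, rng):
        m = vm.Mesh(dim=3)
        pts = [(0, 0, 0), (1, 0, 0), (0.5, 1, 0), (0.5, 0.5, 1)]
        ids = [m.add_vertex(p) for p in pts]
        f = [m.add_surface([ids[0], ids[1], ids[2]]),
             m.add_surface([ids[0], ids[1], ids[3]]),
             m.add_surface([ids[1], ids[2], ids[3]]),
             m.add_surface([ids[0], ids[2], ids[3]])]
        m.add_body(f)
        rec = vm.surface_demote(m, f[0], vm.QualityConfig())
        assert not rec.accepted and "4 surfaces" in rec.reason


class TestBodyDemote:
    def test_isolated_cube_becomes_single_vertex(self):
        c = vm.generate_cube_lattice(vm.LatticeSpec(1, 1, 1))
        rec = vm.body_demote(c, 0, vm.QualityConfig())
        assert rec.accepted
        assert (len(c.vertices), len(c.surfaces), len(c.bodies)) == (1, 0, 0)

    def test_middle_cube_of_row(self):
        c = vm.generate_cube_lattice(vm.LatticeSpec(3, 1, 1))
        rec = vm.body_demote(c, 1, vm.QualityConfig())
        assert rec.accepted
        assert vm.validate_mesh(c) == []
        # hand-enumerated: 16-8+1 vertices, 16-6 surfaces, 2 bodies survive
        assert (len(c.vertices), len(c.surfaces), len(c.bodies)) == (9, 10, 2)
        for body in c.bodies.values():
            assert len(body.surface_ids) == 5

    def test_cascade_removes_invalidated_neighbor(self):
        # cube-like body (top face split into two triangles) with a
        # tetrahedron glued onto one top triangle: demoting the cube leaves
        # the tetrahedron with fewer than four surfaces, so both collapse
        m = vm.Mesh(dim=3)
        p = [m.add_vertex(q) for q in
             [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
              (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]]
        apex = m.add_vertex((0.5, 0.5, 2.0))
        f_bot = m.add_surface([p[0], p[1], p[2], p[3]])
        f_t1 = m.add_surface([p[4], p[5], p[6]])
        f_t2 = m.add_surface([p[4], p[6], p[7]])
        sides = [m.add_surface([p[0], p[1], p[5], p[4]]),
                 m.add_surface([p[1], p[2], p[6], p[5]]),
                 m.add_surface([p[2], p[3], p[7], p[6]]),
                 m.add_surface([p[3], p[0], p[4], p[7]])]
        b1 = m.add_body([f_bot, f_t1, f_t2] + sides)
        b2 = m.add_body([f_t1,
                         m.add_surface([p[4], p[5], apex]),
                         m.add_surface([p[5], p[6], apex]),
                         m.add_surface([p[4], apex, p[6]])])
        assert vm.validate_mesh(m) == []
        rec = vm.body_demote(m, b1, vm.QualityConfig())
        assert rec.accepted
        assert (len(m.vertices), len(m.surfaces), len(m.bodies)) == (1, 0, 0)


class TestVertexInsert:
    def colliding_pair(self):
        """Two unconnected squares; one vertex of the left square has just
        crossed the facing edge of the right square."""
        m = vm.Mesh(dim=2)
        left = [m.add_vertex(p) for p in [(0, 0), (1.05, 0.5), (0, 1)]]
        right = [m.add_vertex(p) for p in [(1.0, -0.5), (2, -0.5), (2, 1.5), (1.0, 1.5)]]
        s_left = m.add_surface(left)
        s_right = m.add_surface(right)
        return m, left, right, s_left, s_right

    def test_insert_grows_cycle(self):
        m, left, right, s_left, s_right = self.colliding_pair()
        rec = vm.vertex_insert(m, left[1], s_right, (right[0], right[3]),
                               vm.QualityConfig())
        assert rec.accepted
        assert len(m.surfaces[s_right].cycle) == 5
        assert vm.validate_mesh(m) == []

    def test_connected_surfaces_never_trigger(self):
        m = vm.generate_sheet(vm.SheetSpec("square", 1, 2))
        edge = (m.surfaces[1].cycle[0], m.surfaces[1].cycle[1])
        rec = vm.vertex_insert(m, m.surfaces[0].cycle[0], 1, edge,
                               vm.QualityConfig())
        assert not rec.accepted

    def test_detection_from_motion_segment(self):
        m, left, right, s_left, s_right = self.colliding_pair()
        prev = m.positions.copy()
        prev[left[1]] = (0.9, 0.5)          # was on the near side last step
        forces = np.zeros_like(prev)
        records = vm.apply_quality_operations(
            m, forces, vm.QualityConfig(enable_merge=False, enable_split=False),
            np.random.default_rng(0), prev_positions=prev)
        accepted = [r for r in records if r.accepted]
        assert len(accepted) == 1 and accepted[0].kind == "vertex_insert"
        assert len(m.surfaces[s_right].cycle) == 5

    def test_reverse_t3_split_disconnects_single_shared_vertex(self):
        # two squares sharing exactly one vertex; pulling them apart drives a
        # split that separates the surfaces again (reverse T3)
        m = vm.Mesh(dim=2)
        shared = m.add_vertex((0, 0))
        a = [m.add_vertex(p) for p in [(-1, 0), (-1, -1), (0, -1)]]
        b = [m.add_vertex(p) for p in [(1, 0), (1, 1), (0, 1)]]
        s1 = m.add_surface([shared, a[0], a[1], a[2]])
        s2 = m.add_surface([shared, b[0], b[1], b[2]])
        forces = np.zeros((m.positions.shape[0], 2))
        for v in a:
            forces[v] = (-1.0, -1.0)
        for v in b:
            forces[v] = (2.0, 2.0)
        cfg = vm.QualityConfig(merge_distance=0.1, split_distance=0.2)
        rec = vm.vertex_split(m, shared, forces, cfg)
        assert rec.accepted
        assert vm.validate_mesh(m) == []
        new = rec.created[0]
        # surfaces no longer share any vertex
        cyc1 = set(m.surfaces[s1].cycle)
        cyc2 = set(m.surfaces[s2].cycle)
        assert not cyc1 & cyc2
        assert (shared in cyc1) != (shared in cyc2)
        assert (new in cyc1) != (new in cyc2)


class TestScheduling:
    def test_no_candidates_no_records(self, unit_square):
        records = vm.apply_quality_operations(
            unit_square, np.zeros((4, 2)), vm.QualityConfig(),
            np.random.default_rng(0))
        assert records == []

    def test_conflicting_merges_keep_lower_owner(self, rng):
        # chain of three vertices within merge distance inside one pentagon
        # pair (0,1) and pair (1,2) conflict; priority goes to owner 0
        m = vm.Mesh(dim=2)
        v = [m.add_vertex(p) for p in
             [(0, 0), (0.05, 0), (0.1, 0), (1, 1), (-1, 1)]]
        m.add_surface(v)
        records = vm.apply_quality_operations(
            m, np.zeros((5, 2)), vm.QualityConfig(merge_distance=0.08,
                                                  split_distance=0.2),
            np.random.default_rng(0))
        accepted = [r for r in records if r.accepted and r.kind == "vertex_merge"]
        assert len(accepted) == 1
        assert accepted[0].owner == 0

    def test_accepted_operations_have_disjoint_affected_sets(self):
        rng = np.random.default_rng(3)
        state = vm.build_cell_sorting(vm.SortingSpec(n=4), rng)
        for _ in range(300):
            vm.step(state)
        by_step: dict = {}
        for r in state.op_records:
            by_step.setdefault(r.step, []).append(r)
        for step_records in by_step.values():
            seen = set()
            for r in step_records:
                assert not (seen & r.affected)
                seen |= r.affected

    def test_mesh_valid_throughout_sorting(self):
        rng = np.random.default_rng(5)
        state = vm.build_cell_sorting(vm.SortingSpec(n=4), rng)
        state.quality.validate_after_ops = True
        vm.run(state, 300)
        assert vm.validate_mesh(state.mesh) == []

    def test_insert_disabled_when_bodies_present(self):
        c = vm.generate_cube_lattice(vm.LatticeSpec(1, 1, 1))
        prev = c.positions.copy()
        records = vm.apply_quality_operations(
            c, np.zeros((8, 3)), vm.QualityConfig(), np.random.default_rng(0),
            prev_positions=prev)
        assert all(r.kind != "vertex_insert" for r in records)

    def test_static_topology_switch(self, rng):
        m, ids = four_cell_junction()
        records = vm.apply_quality_operations(
            m, np.zeros((m.positions.shape[0], 2)),
            vm.QualityConfig(merge_distance=0.5, split_distance=0.6,
                             enabled=False),
            rng)
        assert records == []
        assert ids["v1"] in m.vertices and ids["v2"] in m.vertices

    def test_merge_and_split_conserve_cell_count(self):
        rng = np.random.default_rng(11)
        state = vm.build_cell_sorting(vm.SortingSpec(n=4), rng)
        n_cells = len(state.mesh.surfaces)
        vm.run(state, 500)
        kinds = {r.kind for r in state.op_records}
        assert "vertex_merge" in kinds or "vertex_split" in kinds
        assert len(state.mesh.surfaces) == n_cells
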