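"""Actor forces: analytic gradients, explicit forces, binding semantics."""

import math

import numpy as np
import pytest

import vmesh as vm
from vmesh import actors as A
from conftest import assert_forces_match_fd, polygon_mesh, random_convex_polygon


def perturbed_two_cells(rng):
    m = vm.generate_sheet(vm.SheetSpec("square", 1, 2))
    n = len(m.vertices)
    m.positions[:n] += rng.normal(0, 0.15, (n, 2))
    m.surfaces[1].type_id = 1
    return m


def perturbed_cubes(rng, nx=2):
    c = vm.generate_cube_lattice(vm.LatticeSpec(nx, 1, 1))
    n = len(c.vertices)
    c.positions[:n] += rng.normal(0, 0.04, (n, 3))
    if nx > 1:
        c.bodies[1].type_id = 1
    return c


ENERGY_ACTOR_CASES = [
    ("area", lambda: A.SurfaceAreaConstraint(50.0, 1.0), perturbed_two_cells),
    ("perimeter", lambda: A.PerimeterConstraint(1.0, 2 * math.pi), perturbed_two_cells),
    ("tension_p1", lambda: A.EdgeTension(10.0, 1), perturbed_two_cells),
    ("tension_p2", lambda: A.EdgeTension(0.5, 2), perturbed_two_cells),
    ("adhesion_2d", lambda: A.Adhesion2D({(0, 1): -26.0, (0, 0): -18.0}),
     perturbed_two_cells),
    ("volume", lambda: A.VolumeConstraint(10.0, 2.0),
     lambda rng: perturbed_cubes(rng, 1)),
    ("body_area", lambda: A.BodySurfaceAreaConstraint(5.0, 6.0),
     lambda rng: perturbed_cubes(rng, 1)),
    ("adhesion_3d", lambda: A.Adhesion3D({(0, 1): -2.0}), perturbed_cubes),
    ("flat", lambda: A.FlatSurfaceConstraint(3.0),
     lambda rng: perturbed_cubes(rng, 1)),
]


class TestEnergyGradients:
    @pytest.mark.parametrize("name, actor_fn, mesh_fn",
                             ENERGY_ACTOR_CASES, ids=[c[0] for c in ENERGY_ACTOR_CASES])
    def test_analytic_force_matches_finite_differences(self, name, actor_fn,
                                                       mesh_fn, rng):
        for _ in range(10):
            mesh = mesh_fn(rng)
            table = A.BindingTable().bind(actor_fn(), mesh=True)
            assert_forces_match_fd(mesh, table)

    def test_constant_energy_gives_zero_force(self, unit_square):
        table = A.BindingTable().bind(A.CustomEnergy(lambda m: 42.0), mesh=True)
        f = A.accumulate_forces(unit_square, table)
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_quadratic_energy_gives_minus_position(self, unit_square):
        def h(mesh):
            ids = sorted(mesh.vertices)
            return 0.5 * float((mesh.positions[ids] ** 2).sum())
        table = A.BindingTable().bind(A.CustomEnergy(h), mesh=True)
        f = A.accumulate_forces(unit_square, table)
        for v in unit_square.vertices:
            assert np.allclose(f[v], -unit_square.position(v), atol=1e-8)


class TestAreaConstraint:
    def test_zero_force_at_target(self, unit_square):
        table = A.BindingTable().bind(A.SurfaceAreaConstraint(50.0, 1.0),
                                      surface_id=0)
        assert np.allclose(A.accumulate_forces(unit_square, table), 0.0, atol=1e-12)

    def test_oversized_square_pushed_inward_symmetrically(self):
        m = polygon_mesh([(0, 0), (2, 0), (2, 2), (0, 2)])
        table = A.BindingTable().bind(A.SurfaceAreaConstraint(50.0, 1.0),
                                      surface_id=0)
        f = A.accumulate_forces(m, table)
        center = np.array([1.0, 1.0])
        for v in m.vertices:
            inward = center - m.position(v)
            assert f[v] @ inward > 0.0
        mags = [np.linalg.norm(f[v]) for v in m.vertices]
        assert np.allclose(mags, mags[0])


class TestEdgeTension:
    def test_forces_shorten_edges(self, unit_square):
        table = A.BindingTable().bind(A.EdgeTension(2.0, 1), surface_id=0)
        f = A.accumulate_forces(unit_square, table)
        center = np.array([0.5, 0.5])
        for v in unit_square.vertices:
            assert f[v] @ (center - unit_square.position(v)) > 0.0

    def test_quadratic_scale(self):
        # p=2 tension pulls each endpoint toward the other with force 2*lam*L
        m = polygon_mesh([(0, 0), (3, 0), (1.5, 1e-9)])
        table = A.BindingTable().bind(A.EdgeTension(1.0, 2), surface_id=0)
        f = A.accumulate_forces(m, table)
        # vertex 0: 2*3.0 toward vertex 1 plus 2*1.5 toward vertex 2 (both +x)
        assert np.allclose(f[0], (9.0, 0.0), atol=1e-6)


class TestAdhesion:
    def test_no_shared_edges_no_force(self, unit_square):
        table = A.BindingTable().bind(A.Adhesion2D({(0, 0): -5.0}), mesh=True)
        f = A.accumulate_forces(unit_square, table)
        assert np.allclose(f, 0.0)

    def test_negative_coefficient_extends_shared_edge(self, two_squares):
        table = A.BindingTable().bind(A.Adhesion2D({(0, 0): -26.0}), mesh=True)
        f = A.accumulate_forces(two_squares, table)
        shared = [v for v, vert in two_squares.vertices.items()
                  if len(vert.surface_ids) == 2]
        a, b = sorted(shared, key=lambda v: two_squares.position(v)[1])
        # endpoints pushed apart along the edge with magnitude |lambda|
        assert f[a][1] == pytest.approx(-26.0)
        assert f[b][1] == pytest.approx(26.0)

    def test_3d_adhesion_acts_only_on_shared_surface(self, rng):
        c = vm.generate_cube_lattice(vm.LatticeSpec(2, 1, 1))
        c.bodies[1].type_id = 1
        table = A.BindingTable().bind(A.Adhesion3D({(0, 1): -2.0}), mesh=True)
        f = A.accumulate_forces(c, table)
        shared_sid = next(s for s, surf in c.surfaces.items()
                          if len(surf.body_ids) == 2)
        shared_vs = set(c.surfaces[shared_sid].cycle)
        for v in c.vertices:
            if v not in shared_vs:
                assert np.allclose(f[v], 0.0)


class TestExplicitForceActors:
    def test_surface_traction_distributes_by_vertex_area(self, unit_square):
        table = A.BindingTable().bind(A.SurfaceTraction((1.0, 0.0)), surface_id=0)
        f = A.accumulate_forces(unit_square, table)
        for v in unit_square.vertices:
            assert np.allclose(f[v], (0.25, 0.0))
        assert np.allclose(f.sum(axis=0), (1.0, 0.0))

    def test_zero_traction_zero_force(self, unit_square):
        table = A.BindingTable().bind(A.SurfaceTraction((0.0, 0.0)), surface_id=0)
        assert np.allclose(A.accumulate_forces(unit_square, table), 0.0)

    def test_body_force_distributes_by_volume_share(self, unit_cube):
        table = A.BindingTable().bind(A.BodyForce((0, 0, -1.0)), body_id=0)
        f = A.accumulate_forces(unit_cube, table)
        for v in unit_cube.vertices:
            assert np.allclose(f[v], (0, 0, -0.125))
        assert np.allclose(f.sum(axis=0), (0, 0, -1.0))

    def test_normal_stress_total_and_sign(self, unit_square):
        for p in (2.0, -2.0):
            table = A.BindingTable().bind(A.NormalStress(p), surface_id=0)
            ev = A.GeomEval(unit_square)
            out = np.zeros((4, 2))
            table.entries[0].actor.add_forces(ev, np.array([0]), out)
            # planar surface: normal is +z, so in-plane force components vanish
            assert np.allclose(out, 0.0)

    def test_normal_stress_on_cube_face_is_area_times_pressure(self, unit_cube):
        top = next(s for s in unit_cube.surfaces
                   if all(unit_cube.position(v)[2] == 1.0
                          for v in unit_cube.surfaces[s].cycle))
        table = A.BindingTable().bind(A.NormalStress(3.0), surface_id=top)
        f = A.accumulate_forces(unit_cube, table)
        assert np.allclose(np.abs(f.sum(axis=0)), (0, 0, 3.0), atol=1e-12)


class TestShapeConstraints:
    def test_flat_constraint_zero_on_planar_polygon(self):
        m = vm.Mesh(dim=3)
        ids = [m.add_vertex(p) for p in [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]]
        m.add_surface(ids)
        table = A.BindingTable().bind(A.FlatSurfaceConstraint(5.0), mesh=True)
        assert np.allclose(A.accumulate_forces(m, table), 0.0, atol=1e-12)

    def test_flat_constraint_pulls_lifted_vertex_back(self):
        m = vm.Mesh(dim=3)
        ids = [m.add_vertex(p) for p in [(0, 0, 0.4), (1, 0, 0), (1, 1, 0), (0, 1, 0)]]
        m.add_surface(ids)
        table = A.BindingTable().bind(A.FlatSurfaceConstraint(5.0), mesh=True)
        f = A.accumulate_forces(m, table)
        assert f[0][2] < 0.0       # lifted vertex pushed toward the plane

    def test_convex_constraint_acts_only_on_reflex_vertex(self):
        m = vm.Mesh(dim=3)
        # square with one vertex dented inward (reflex)
        ids = [m.add_vertex(p) for p in [(1.2, 1.2, 0), (2, 0, 0), (2, 2, 0), (0, 2, 0)]]
        m.add_surface(ids)
        table = A.BindingTable().bind(A.ConvexPolygonConstraint(1.0), mesh=True)
        f = A.accumulate_forces(m, table)
        assert np.linalg.norm(f[0]) > 0.0
        for v in (1, 2, 3):
            assert np.allclose(f[v], 0.0)

    def test_both_vacuous_in_planar_mode(self, unit_square):
        table = A.BindingTable()
        table.bind(A.FlatSurfaceConstraint(5.0), mesh=True)
        table.bind(A.ConvexPolygonConstraint(5.0), mesh=True)
        assert np.allclose(A.accumulate_forces(unit_square, table), 0.0)


class TestRandomMotility:
    def test_fixed_magnitude(self, unit_square, rng):
        table = A.BindingTable().bind(A.RandomMotility(8.94), vertices=True)
        f = A.accumulate_forces(unit_square, table, rng)
        assert np.allclose(np.linalg.norm(f[:4], axis=1), 8.94)

    def test_isotropic_mean(self, unit_square):
        actor = A.RandomMotility(1.0)
        rng = np.random.default_rng(7)
        ev = A.GeomEval(unit_square)
        n = 100_000
        out = np.zeros((4, 2))
        total = np.zeros(2)
        for _ in range(n // 4):
            out[:] = 0.0
            actor.add_forces(ev, np.arange(4), out, rng)
            total += out.sum(axis=0)
        # CLT: per-component variance of a unit direction is 1/2
        assert np.linalg.norm(total / n) < 3.0 / math.sqrt(2 * n)

    def test_seeded_determinism(self, unit_square):
        table = A.BindingTable().bind(A.RandomMotility(2.0), vertices=True)
        f1 = A.accumulate_forces(unit_square, table, np.random.default_rng(5))
        f2 = A.accumulate_forces(unit_square, table, np.random.default_rng(5))
        assert np.array_equal(f1, f2)

    def test_requires_rng(self, unit_square):
        table = A.BindingTable().bind(A.RandomMotility(1.0), vertices=True)
        with pytest.raises(A.ConfigError):
            A.accumulate_forces(unit_square, table)


class TestBindingSemantics:
    def test_no_bindings_zero_field(self, unit_square):
        assert np.allclose(A.accumulate_forces(unit_square, A.BindingTable()), 0.0)

    def test_double_binding_doubles_force(self):
        m = polygon_mesh([(0, 0), (2, 0), (2, 2), (0, 2)])
        single = A.BindingTable().bind(A.SurfaceAreaConstraint(50.0, 1.0),
                                       surface_id=0)
        double = A.BindingTable()
        double.bind(A.SurfaceAreaConstraint(50.0, 1.0), surface_id=0)
        double.bind(A.SurfaceAreaConstraint(50.0, 1.0), surface_id=0)
        f1 = A.accumulate_forces(m, single)
        f2 = A.accumulate_forces(m, double)
        assert np.allclose(f2, 2.0 * f1)

    def test_accumulation_order_independent(self, rng):
        m = vm.generate_sheet(vm.SheetSpec("square", 2, 2))
        n = len(m.vertices)
        m.positions[:n] += rng.normal(0, 0.1, (n, 2))
        actors = [A.SurfaceAreaConstraint(50.0, 1.0),
                  A.PerimeterConstraint(1.0, 2 * math.pi),
                  A.EdgeTension(10.0, 1)]
        fwd = A.BindingTable()
        rev = A.BindingTable()
        for a in actors:
            fwd.bind(a, mesh=True)
        for a in reversed(actors):
            rev.bind(a, mesh=True)
        assert np.allclose(A.accumulate_forces(m, fwd),
                           A.accumulate_forces(m, rev), atol=1e-12)

    def test_full_assembly_equals_termwise_sum(self, rng):
        m = perturbed_two_cells(rng)
        terms = [
            A.BindingTable().bind(A.SurfaceAreaConstraint(50.0, 1.0), mesh=True),
            A.BindingTable().bind(A.PerimeterConstraint(1.0, 2 * math.pi), mesh=True),
            A.BindingTable().bind(A.EdgeTension(10.0, 1), mesh=True),
            A.BindingTable().bind(A.Adhesion2D({(0, 1): -26.0}), mesh=True),
        ]
        full = A.BindingTable()
        full.bind(A.SurfaceAreaConstraint(50.0, 1.0), mesh=True)
        full.bind(A.PerimeterConstraint(1.0, 2 * math.pi), mesh=True)
        full.bind(A.EdgeTension(10.0, 1), mesh=True)
        full.bind(A.Adhesion2D({(0, 1): -26.0}), mesh=True)
        total = sum(A.accumulate_forces(m, t) for t in terms)
        assert np.allclose(A.accumulate_forces(m, full), total, atol=1e-12)

    def test_scope_mismatch_rejected(self):
        with pytest.raises(A.ConfigError):
            A.BindingTable().bind(A.SurfaceAreaConstraint(1.0, 1.0), vertices=True)


class TestMomentumConservation:
    def test_internal_actors_have_zero_net_force_and_torque(self, rng):
        m = perturbed_two_cells(rng)
        table = A.BindingTable()
        table.bind(A.SurfaceAreaConstraint(50.0, 1.0), mesh=True)
        table.bind(A.PerimeterConstraint(1.0, 2 * math.pi), mesh=True)
        table.bind(A.EdgeTension(10.0, 1), mesh=True)
        table.bind(A.Adhesion2D({(0, 1): -26.0, (0, 0): -18.0}), mesh=True)
        f = A.accumulate_forces(m, table)
        scale = np.abs(f).max()
        assert np.abs(f.sum(axis=0)).max() < 1e-9 * scale
        ids = sorted(m.vertices)
        r = m.positions[ids]
        torque = float((r[:, 0] * f[ids, 1] - r[:, 1] * f[ids, 0]).sum())
        assert abs(torque) < 1e-9 * scale


class TestRigidTranslation:
    def test_uniform_traction_with_variable_drag_translates_rigidly(self, rng):
        m = vm.generate_sheet(vm.SheetSpec("square", 2, 2))
        n = len(m.vertices)
        m.positions[:n] += rng.normal(0, 0.1, (n, 2))
        rho = 2.0
        for surf in m.surfaces.values():
            surf.drag_density = rho
        tau = np.array([1.3, -0.4])
        table = A.BindingTable().bind(A.SurfaceTraction(tau), mesh=True)
        f = A.accumulate_forces(m, table)
        for v in sorted(m.vertices):
            vel = f[v] / vm.vertex_drag(m, v)
            assert np.allclose(vel, tau / rho, atol=1e-12)

    def test_uniform_body_force_with_variable_drag_translates_rigidly(self, rng):
        c = vm.generate_cube_lattice(vm.LatticeSpec(1, 1, 1))
        n = len(c.vertices)
        c.positions[:n] += rng.normal(0, 0.05, (n, 3))
        c.bodies[0].drag_density = 1.0
        fb = np.array([0.7, 0.2, -0.5])
        table = A.BindingTable().bind(A.BodyForce(fb), body_id=0)
        f = A.accumulate_forces(c, table)
        V = vm.body_measures(c, 0).volume
        for v in sorted(c.vertices):
            vel = f[v] / vm.vertex_drag(c, v)
            assert np.allclose(vel, fb / V, atol=1e-9)
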