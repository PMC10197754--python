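"""Demonstration models: differential-adhesion cell sorting and cell migration.

*Cell sorting* — an n x n aggregate of unit-square cells, each randomly
assigned one of two types, evolves under the per-cell effective energy

    H(S) = lam_area (A_S - A_o)^2 + lam_per (L_S - L_o)^2
         + lam_ten sum_edges ||edge|| + 1/2 sum_neighbors lam_adh(t, t') C(S, S')

plus a random motility force on every vertex.  Negative type-dependent
adhesion coefficients make homotypic contact energetically cheaper than
heterotypic contact, so cells rearrange by type (differential adhesion
hypothesis); progress is tracked by the total heterotypic boundary length
normalized by its initial value.

*Cell migration* — a single unit-area hexagonal cell with an area constraint
and quadratic edge tension, coupled to a fibrous ECM band through integrins
(see :mod:`vmesh.particles`), migrates along the band in a fixed +x forward
direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kendalltau

from . import actors as A
from .mesh import Mesh
from .meshgen import SheetSpec, generate_sheet
from .particles import (BondParams, SubstrateSpec, UNIT_HEX_CIRCUMRADIUS,
                        build_substrate, integrin_lifecycle)
from .solver import Reporter, SimState, SolverConfig
from .topology import QualityConfig

__all__ = [
    "SortingSpec", "MigrationSpec", "MetricSeries", "build_cell_sorting",
    "heterotypic_length", "heterotypic_fraction", "build_cell_migration",
    "TrajectoryRecorder", "HeterotypicRecorder",
]


@dataclass
class SortingSpec:
    """Cell-sorting study conditions (two cell types on a square aggregate)."""
    n: int = 8                       # n x n cells
    p_type1: float = 0.5
    dt: float = 0.00250
    drag: float = 1.00
    merge_distance: float = 0.100
    split_distance: float = 0.200
    lam_area: float = 50.0
    target_area: float = 1.00
    lam_per: float = 1.00
    target_perimeter: float = 2.0 * math.pi
    lam_ten: dict[int, float] = field(default_factory=lambda: {1: 10.0, 2: 20.0})
    adhesion: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(1, 1): -18.0, (1, 2): -26.0, (2, 2): -38.0})
    motility: float = 8.94
    metric_cadence: int = 100


@dataclass
class MigrationSpec:
    """Cell-migration study conditions (single hexagonal cell on an ECM band)."""
    dt: float = 0.01
    vertex_drag: float = 1.00
    fiber_drag: float = 1.00
    lam_area: float = 1.00
    target_area: float = 1.00
    lam_ten: float = 0.500           # quadratic edge tension
    n_integrins: int = 100
    start_x: float = 0.5
    substrate: SubstrateSpec = field(default_factory=SubstrateSpec)
    bonds: BondParams = field(default_factory=BondParams)


@dataclass
class MetricSeries:
    steps: list[int] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    values: list = field(default_factory=list)

    def append(self, step: int, time: float, value) -> None:
        self.steps.append(step)
        self.times.append(time)
        self.values.append(value)


# ----------------------------------------------------------------------
# cell sorting
# ----------------------------------------------------------------------

def build_cell_sorting(spec: SortingSpec, rng: np.random.Generator) -> SimState:
    """Assemble the sorting model: mesh, type assignment, bindings, solver."""
    mesh = generate_sheet(SheetSpec("square", spec.n, spec.n,
                                    cell_area=spec.target_area))
    margin = 2.0 * spec.n
    side = math.sqrt(spec.target_area) * spec.n
    mesh.domain_box = np.array([[-margin, -margin], [side + margin, side + margin]])
    for sid in sorted(mesh.surfaces):
        mesh.surfaces[sid].type_id = 1 if rng.random() < spec.p_type1 else 2
    table = A.BindingTable()
    for t in (1, 2):
        table.bind(A.SurfaceAreaConstraint(spec.lam_area, spec.target_area),
                   surface_type=t)
        table.bind(A.PerimeterConstraint(spec.lam_per, spec.target_perimeter),
                   surface_type=t)
        table.bind(A.EdgeTension(spec.lam_ten[t], exponent=1), surface_type=t)
    table.bind(A.Adhesion2D(spec.adhesion), mesh=True)
    table.bind(A.RandomMotility(spec.motility), vertices=True)
    solver = SolverConfig(dt=spec.dt, drag_mode="fixed", M=spec.drag)
    quality = QualityConfig(merge_distance=spec.merge_distance,
                            split_distance=spec.split_distance)
    return SimState(mesh=mesh, bindings=table, solver=solver,
                    quality=quality, rng=rng)


def heterotypic_length(mesh: Mesh) -> float:
    """Total length of edges shared by cells of different types."""
    total = 0.0
    for (a, b), owners in mesh.edge_owners().items():
        if len(owners) == 2:
            t1 = mesh.surfaces[owners[0]].type_id
            t2 = mesh.surfaces[owners[1]].type_id
            if t1 != t2:
                total += float(np.linalg.norm(mesh.position(a) - mesh.position(b)))
    return total


def heterotypic_fraction(mesh: Mesh, baseline: float) -> float:
    """Heterotypic boundary length normalized by its value at time 0."""
    if baseline <= 0.0:
        raise ValueError("heterotypic baseline must be positive")
    return heterotypic_length(mesh) / baseline


class HeterotypicRecorder:
    """Reporter collecting the heterotypic fraction; baseline from first call."""

    def __init__(self, cadence: int = 100):
        self.cadence = cadence
        self.baseline: float | None = None
        self.series = MetricSeries()

    def as_reporter(self) -> Reporter:
        return Reporter(self.cadence, self)

    def __call__(self, state: SimState) -> None:
        length = heterotypic_length(state.mesh)
        if self.baseline is None:
            self.baseline = length
        self.series.append(state.step_count, state.time,
                           length / self.baseline if self.baseline > 0 else 0.0)


# ----------------------------------------------------------------------
# cell migration
# ----------------------------------------------------------------------

def unit_area_hexagon_cell(center: np.ndarray) -> Mesh:
    """Planar mesh with one regular hexagon of area 1, leading edge facing +x.

    Vertices sit at angles 30 + 60 k degrees, so the rightmost side is an
    edge (two equally forward vertices) perpendicular to the forward
    direction.
    """
    R = UNIT_HEX_CIRCUMRADIUS
    mesh = Mesh(dim=2)
    cyc = []
    for k in range(6):
        th = math.pi / 6.0 + k * math.pi / 3.0
        cyc.append(mesh.add_vertex(center + R * np.array([math.cos(th), math.sin(th)])))
    mesh.add_surface(cyc)
    return mesh


def build_cell_migration(spec: MigrationSpec, rng: np.random.Generator) -> SimState:
    """Assemble the migration model: cell, substrate, integrins, bindings."""
    sub = spec.substrate
    y0 = float(sub.band_center(spec.start_x))
    mesh = unit_area_hexagon_cell(np.array([spec.start_x, y0]))
    pad = 2.0
    mesh.domain_box = np.array(
        [[sub.x_range[0] - pad, -sub.amplitude - sub.width - pad],
         [sub.x_range[1] + pad, sub.amplitude + sub.width + pad]])
    table = A.BindingTable()
    table.bind(A.SurfaceAreaConstraint(spec.lam_area, spec.target_area),
               surface_id=0)
    table.bind(A.EdgeTension(spec.lam_ten, exponent=2), surface_id=0)
    ps = build_substrate(sub, rng, params=spec.bonds, fiber_drag=spec.fiber_drag)
    ps.cell_surface = 0
    ps.n_integrins = spec.n_integrins
    solver = SolverConfig(dt=spec.dt, drag_mode="fixed", M=spec.vertex_drag)
    quality = QualityConfig(enabled=False)      # static 6-vertex cell topology
    state = SimState(mesh=mesh, bindings=table, solver=solver,
                     quality=quality, rng=rng, particles=ps)
    integrin_lifecycle(state)                   # seed the initial integrins
    return state


class TrajectoryRecorder:
    """Reporter collecting cell centroid, net displacement and edge orientation."""

    def __init__(self, surface_id: int = 0, cadence: int = 10):
        self.surface_id = surface_id
        self.cadence = cadence
        self.series = MetricSeries()
        self._origin: np.ndarray | None = None

    def as_reporter(self) -> Reporter:
        return Reporter(self.cadence, self)

    def __call__(self, state: SimState) -> None:
        from .mesh import surface_centroid
        from .particles import leading_edge
        c = surface_centroid(state.mesh, self.surface_id)
        if self._origin is None:
            self._origin = c.copy()
        disp = c - self._origin
        v1, v2 = leading_edge(state.mesh, self.surface_id,
                              state.particles.forward if state.particles is not None
                              else np.array([1.0, 0.0]))
        edge = state.mesh.position(v2) - state.mesh.position(v1)
        orientation = math.atan2(edge[1], edge[0])
        self.series.append(state.step_count, state.time,
                           {"centroid": c.tolist(),
                            "displacement": disp.tolist(),
                            "leading_edge_orientation": orientation})

    def centroid_x(self) -> np.ndarray:
        return np.asarray([v["centroid"][0] for v in self.series.values])


def mann_kendall_statistic(series: np.ndarray) -> float:
    """Kendall rank correlation of a series against time (positive = uptrend)."""
    series = np.asarray(series, dtype=float)
    tau, _ = kendalltau(np.arange(len(series)), series)
    return float(tau)
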