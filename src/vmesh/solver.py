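"""Overdamped explicit time integration and the per-step pipeline.

Dynamics follow force balance with viscous drag and no inertia: each vertex
moves with velocity ``f / M`` where ``f`` is the accumulated actor force and
``M`` the vertex drag (a fixed constant, or the variable drag derived from
body/surface drag densities).  One step runs

    accumulate forces -> forward-Euler position update -> no-flux clamp
    -> event hooks -> quality operations -> advance clock

Stability is the user's parameter responsibility (explicit integration); the
per-step maximum displacement is tracked as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .actors import BindingTable, GeomEval, accumulate_forces, total_energy
from .mesh import Mesh, validate_mesh
from .topology import OperationRecord, QualityConfig, apply_quality_operations

logger = logging.getLogger(__name__)

__all__ = ["SolverConfig", "SimState", "EventHook", "Reporter", "step", "run"]


@dataclass
class SolverConfig:
    dt: float = 0.0025
    drag_mode: str = "fixed"        # "fixed" | "variable"
    M: float = 1.0                  # fixed-mode drag coefficient
    clamp_to_domain: bool = True
    validate_every: int = 0         # 0 = never validate during stepping

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.drag_mode not in ("fixed", "variable"):
            raise ValueError(f"unknown drag mode {self.drag_mode!r}")
        if self.drag_mode == "fixed" and self.M <= 0:
            raise ValueError("fixed drag M must be positive")


@dataclass
class EventHook:
    """A mesh/particle mutation procedure run every ``cadence`` steps.

    Hooks fire after integration and before quality operations; a hook must
    leave the mesh valid.
    """
    cadence: int
    fn: Callable[["SimState"], None]
    name: str = ""
    debug_validate: bool = False


@dataclass
class Reporter:
    cadence: int
    fn: Callable[["SimState"], None]


@dataclass
class SimState:
    mesh: Mesh
    bindings: BindingTable
    solver: SolverConfig
    quality: QualityConfig
    rng: np.random.Generator
    particles: object | None = None          # ParticleSystem, if coupled
    events: list[EventHook] = field(default_factory=list)
    step_count: int = 0
    time: float = 0.0
    op_records: list[OperationRecord] = field(default_factory=list)
    #: per-step diagnostic: maximum vertex displacement of the last step
    last_max_displacement: float = 0.0

    def register_event(self, hook: EventHook) -> "SimState":
        self.events.append(hook)
        return self


def _vertex_drags(state: SimState, ev: GeomEval, vids: np.ndarray) -> np.ndarray:
    cfg = state.solver
    if cfg.drag_mode == "fixed":
        return np.full(len(vids), cfg.M)
    mesh = state.mesh
    if mesh.dim == 2:
        rho = np.asarray([mesh.surfaces[s].drag_density
                          if mesh.surfaces[s].drag_density is not None else np.nan
                          for s in ev.arr.sids])
        if np.isnan(rho).any():
            raise ValueError("variable drag requires drag_density on every surface")
        acc = np.zeros(mesh.positions.shape[0])
        np.add.at(acc, ev.arr.flat_v,
                  rho[ev.arr.surf_of] * ev.vertex_area_contrib)
        drags = acc[vids]
    else:
        from .mesh import vertex_drag
        drags = np.asarray([vertex_drag(mesh, int(v)) for v in vids])
    if (drags <= 0.0).any():
        bad = vids[drags <= 0.0]
        raise ValueError(f"zero drag would immobilize vertices {bad[:5].tolist()}")
    return drags


def step(state: SimState) -> SimState:
    """Advance the simulation by one time step (in place)."""
    mesh = state.mesh
    dt = state.solver.dt
    ev = GeomEval(mesh)
    forces = accumulate_forces(mesh, state.bindings, state.rng, ev=ev)
    if state.particles is not None:
        from .particles import coupled_forces
        particle_forces = coupled_forces(state, forces)
    vids = np.asarray(sorted(mesh.vertices), dtype=int)
    prev = mesh.positions.copy()
    drags = _vertex_drags(state, ev, vids)
    disp = forces[vids] / drags[:, None] * dt
    mesh.positions[vids] += disp
    if not np.all(np.isfinite(mesh.positions[vids])):
        bad = vids[~np.isfinite(mesh.positions[vids]).all(axis=1)]
        raise FloatingPointError(
            f"integration blow-up at step {state.step_count}: vertices "
            f"{bad[:5].tolist()} are non-finite")
    state.last_max_displacement = float(np.abs(disp).max()) if len(disp) else 0.0
    if state.solver.clamp_to_domain and mesh.domain_box is not None:
        lo, hi = mesh.domain_box
        mesh.positions[vids] = np.clip(mesh.positions[vids], lo, hi)
    if state.particles is not None:
        state.particles.integrate(particle_forces, dt)
        from .particles import integrin_lifecycle
        integrin_lifecycle(state)
    next_step = state.step_count + 1
    for hook in state.events:
        if hook.cadence > 0 and next_step % hook.cadence == 0:
            hook.fn(state)
            if hook.debug_validate:
                problems = validate_mesh(mesh)
                if problems:
                    raise AssertionError(
                        f"event {hook.name or hook.fn!r} left mesh invalid: {problems}")
    records = apply_quality_operations(
        mesh, forces, state.quality, state.rng,
        prev_positions=prev, step=next_step)
    if records:
        state.op_records.extend(r for r in records if r.accepted)
    state.step_count = next_step
    state.time += dt
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug("step %d: max displacement %.3g, %d ops accepted",
                     next_step, state.last_max_displacement,
                     sum(r.accepted for r in records))
    if state.solver.validate_every and next_step % state.solver.validate_every == 0:
        problems = validate_mesh(mesh)
        if problems:
            raise AssertionError(f"mesh invalid at step {next_step}: {problems}")
    return state


def run(state: SimState, n_steps: int,
        reporters: list[Reporter] | None = None) -> SimState:
    """Apply :func:`step` ``n_steps`` times, firing reporters at their cadence.

    Reporters also fire once before the first step (the t = 0 baseline).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    reporters = reporters or []
    for rep in reporters:
        if state.step_count % max(rep.cadence, 1) == 0:
            rep.fn(state)
    for _ in range(n_steps):
        step(state)
        for rep in reporters:
            if state.step_count % max(rep.cadence, 1) == 0:
                rep.fn(state)
    return state


def effective_energy(state: SimState) -> float:
    """Total effective energy of all bound energy-based actors."""
    return total_energy(state.mesh, state.bindings)
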