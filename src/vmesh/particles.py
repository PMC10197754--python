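"""Bonded-particle subsystem: ECM fibers, integrins and mesh coupling.

The mixed vertex/particle migration model represents the extracellular
matrix as chains of *fiber segment particles* connected by tensile
(harmonic pair) and bending (harmonic angle) bonds, with a Morse-like
adhesion between particles of different fibers.  *Integrins* are particles
constrained to the area occupied by the cell; each binds one fiber segment
particle (harmonic bond) and, through linear "cytoskeleton" bonds with a
negative coefficient, pushes the cell's two leading-edge vertices forward.
Because every mesh vertex is itself a particle-like degree of freedom, bond
forces act directly on vertices and close the mechanical loop between the
cell and the matrix.

Bond potentials (r = pair distance, theta = angle at the middle particle):

* tensile           U = k (r - r0)^2
* bending           U = k (theta - theta0)^2
* inter_fiber       U = k (1 - exp(-a (r - r0)))^2      (nonbonded, cutoff)
* integrin_fiber    U = k (r - r0)^2
* cytoskeleton      U = k r        (k < 0 gives a constant protrusive force)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "BondParams", "SubstrateSpec", "ParticleSystem", "evaluate_potential",
    "build_substrate", "leading_edge", "point_in_cell", "integrin_lifecycle",
    "coupled_forces",
]

#: circumradius of the unit-area regular hexagon; sets the integrin length scales
UNIT_HEX_CIRCUMRADIUS = math.sqrt(2.0 / (3.0 * math.sqrt(3.0)))


@dataclass
class BondParams:
    k_tensile: float = 10.0
    r0_tensile: float = 0.0100
    k_bending: float = 1.0e-4
    theta0: float = math.pi
    k_inter: float = 0.00100
    a_inter: float = 12.0
    r0_inter: float = 0.0200
    k_integ: float = 1.00
    r0_integ: float = 0.0100
    k_cyto: float = -0.0100

    @property
    def inter_cutoff(self) -> float:
        return 3.0 * self.r0_inter


@dataclass
class SubstrateSpec:
    """Fibrous band between two sine curves of fixed width and period."""
    width: float = 1.00
    period: float = 4.00
    amplitude: float = 0.05
    x_range: tuple[float, float] = (0.0, 6.0)
    n_fibers: int = 90
    particles_per_fiber: tuple[int, int] = (10, 100)
    spacing: float = 0.0100          # rest length of tensile bonds
    max_retries: int = 50

    def band_center(self, x) -> np.ndarray:
        return self.amplitude * np.sin(2.0 * np.pi * np.asarray(x) / self.period)

    def inside_band(self, xy: np.ndarray) -> np.ndarray:
        x, y = xy[..., 0], xy[..., 1]
        yc = self.band_center(x)
        half = 0.5 * self.width
        return ((x >= self.x_range[0]) & (x <= self.x_range[1])
                & (y >= yc - half) & (y <= yc + half))


# ----------------------------------------------------------------------
# per-bond potential evaluation (reference implementation; batch versions below)
# ----------------------------------------------------------------------

def evaluate_potential(kind: str, coords: np.ndarray,
                       params: BondParams) -> tuple[float, np.ndarray]:
    """Energy and forces (= -gradient) of one bond.

    ``coords`` has shape (2, 2) for pair bonds and (3, 2) for the bending
    bond, whose angle sits at the middle row.  A coincident pair contributes
    zero force by convention.
    """
    coords = np.asarray(coords, dtype=float)
    forces = np.zeros_like(coords)
    if kind == "bending":
        u = coords[0] - coords[1]
        v = coords[2] - coords[1]
        cross = u[0] * v[1] - u[1] * v[0]
        dot = float(u @ v)
        denom = cross * cross + dot * dot
        if denom < 1e-300:
            logger.debug("degenerate angle bond; zero force")
            return 0.0, forces
        phi = math.atan2(cross, dot)
        theta = abs(phi)
        energy = params.k_bending * (theta - params.theta0) ** 2
        dU = 2.0 * params.k_bending * (theta - params.theta0) * math.copysign(1.0, phi)
        dphi_du = (dot * np.array([v[1], -v[0]]) - cross * v) / denom
        dphi_dv = (dot * np.array([-u[1], u[0]]) - cross * u) / denom
        forces[0] = -dU * dphi_du
        forces[2] = -dU * dphi_dv
        forces[1] = -(forces[0] + forces[2])
        return float(energy), forces
    d = coords[0] - coords[1]
    r = float(np.linalg.norm(d))
    if kind == "tensile":
        energy = params.k_tensile * (r - params.r0_tensile) ** 2
        dUdr = 2.0 * params.k_tensile * (r - params.r0_tensile)
    elif kind == "integrin_fiber":
        energy = params.k_integ * (r - params.r0_integ) ** 2
        dUdr = 2.0 * params.k_integ * (r - params.r0_integ)
    elif kind == "inter_fiber":
        e = math.exp(-params.a_inter * (r - params.r0_inter))
        energy = params.k_inter * (1.0 - e) ** 2
        dUdr = 2.0 * params.k_inter * (1.0 - e) * params.a_inter * e
    elif kind == "cytoskeleton":
        energy = params.k_cyto * r
        dUdr = params.k_cyto
    else:
        raise ValueError(f"unknown bond kind {kind!r}")
    if r < 1e-300:
        logger.debug("zero-length %s bond; zero force", kind)
        return float(energy), forces
    grad = (dUdr / r) * d
    forces[0] = -grad
    forces[1] = grad
    return float(energy), forces


# ----------------------------------------------------------------------
# particle system
# ----------------------------------------------------------------------

ROLE_FIBER = 0
ROLE_INTEGRIN = 1


class ParticleSystem:
    """Fiber-segment and integrin particles with bonded interactions.

    Integrin bookkeeping (which fiber particle each integrin holds, which
    vertices its cytoskeleton bonds pull) lives in plain dicts keyed by
    particle id; fiber bonds are fixed index arrays built once by the
    substrate generator.
    """

    def __init__(self, params: BondParams | None = None):
        self.params = params or BondParams()
        self.positions = np.zeros((0, 2))
        self.drag = np.zeros(0)
        self.role = np.zeros(0, dtype=int)
        self.fiber_id = np.full(0, -1, dtype=int)
        self.alive = np.zeros(0, dtype=bool)
        self.tensile_bonds = np.zeros((0, 2), dtype=int)
        self.bending_bonds = np.zeros((0, 3), dtype=int)
        self.integ_bonds: dict[int, int] = {}          # integrin pid -> fiber pid
        self.cyto_bonds: dict[int, list[int]] = {}     # integrin pid -> vertex ids
        # coupling configuration (set by the migration builder)
        self.cell_surface: int | None = None
        self.forward = np.array([1.0, 0.0])
        self.circumradius = UNIT_HEX_CIRCUMRADIUS
        self.n_integrins = 100
        self.max_bond_length = 0.921
        self.creation_window = (0.05 * UNIT_HEX_CIRCUMRADIUS,
                                0.25 * UNIT_HEX_CIRCUMRADIUS)
        # nonbonded neighbor-list caching
        self.pair_refresh = 10
        self.pair_margin = 0.02
        self._pair_cache: tuple | None = None

    # ------------------------------------------------------------------
    def add_particles(self, positions: np.ndarray, drag: float, role: int,
                      fiber: int = -1) -> np.ndarray:
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        start = self.positions.shape[0]
        self.positions = np.vstack([self.positions, positions])
        self.drag = np.concatenate([self.drag, np.full(n, float(drag))])
        self.role = np.concatenate([self.role, np.full(n, role, dtype=int)])
        self.fiber_id = np.concatenate([self.fiber_id, np.full(n, fiber, dtype=int)])
        self.alive = np.concatenate([self.alive, np.ones(n, dtype=bool)])
        return np.arange(start, start + n)

    def kill(self, pid: int) -> None:
        self.alive[pid] = False
        self.integ_bonds.pop(pid, None)
        self.cyto_bonds.pop(pid, None)

    @property
    def live_integrins(self) -> np.ndarray:
        return np.nonzero(self.alive & (self.role == ROLE_INTEGRIN))[0]

    @property
    def live_fiber_particles(self) -> np.ndarray:
        return np.nonzero(self.alive & (self.role == ROLE_FIBER))[0]

    def integrate(self, forces: np.ndarray, dt: float) -> None:
        live = self.alive
        self.positions[live] += forces[live] / self.drag[live, None] * dt

    # ------------------------------------------------------------------
    def bonded_forces(self, out: np.ndarray | None = None) -> np.ndarray:
        """Forces from fiber bonds and nonbonded inter-fiber adhesion."""
        p = self.params
        if out is None:
            out = np.zeros_like(self.positions)
        tb = self.tensile_bonds
        if len(tb):
            d = self.positions[tb[:, 0]] - self.positions[tb[:, 1]]
            r = np.linalg.norm(d, axis=1)
            ok = r > 1e-300
            f = np.zeros_like(d)
            f[ok] = (-2.0 * p.k_tensile * (r[ok] - p.r0_tensile) / r[ok])[:, None] * d[ok]
            np.add.at(out, tb[:, 0], f)
            np.add.at(out, tb[:, 1], -f)
        bb = self.bending_bonds
        if len(bb):
            u = self.positions[bb[:, 0]] - self.positions[bb[:, 1]]
            v = self.positions[bb[:, 2]] - self.positions[bb[:, 1]]
            cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
            dot = (u * v).sum(axis=1)
            denom = cross * cross + dot * dot
            ok = denom > 1e-300
            phi = np.arctan2(cross, dot)
            theta = np.abs(phi)
            dU = 2.0 * p.k_bending * (theta - p.theta0) * np.sign(phi)
            dU = np.where(ok, dU, 0.0)
            denom = np.where(ok, denom, 1.0)
            perp_v = np.column_stack([v[:, 1], -v[:, 0]])
            perp_u = np.column_stack([-u[:, 1], u[:, 0]])
            dphi_du = (dot[:, None] * perp_v - cross[:, None] * v) / denom[:, None]
            dphi_dv = (dot[:, None] * perp_u - cross[:, None] * u) / denom[:, None]
            f0 = -dU[:, None] * dphi_du
            f2 = -dU[:, None] * dphi_dv
            np.add.at(out, bb[:, 0], f0)
            np.add.at(out, bb[:, 2], f2)
            np.add.at(out, bb[:, 1], -(f0 + f2))
        # nonbonded inter-fiber adhesion within the cutoff; the neighbor list
        # is refreshed every few steps with a margin (particles move far less
        # than the margin per refresh interval at the model's force scales)
        fibers = self.live_fiber_particles
        if len(fibers) > 1:
            cache = self._pair_cache
            if cache is None or cache[0] <= 0 or len(cache[1]) != len(fibers) \
                    or not np.array_equal(cache[1], fibers):
                pts = self.positions[fibers]
                tree = cKDTree(pts)
                pairs = tree.query_pairs(p.inter_cutoff + self.pair_margin,
                                         output_type="ndarray")
                i = fibers[pairs[:, 0]] if len(pairs) else np.zeros(0, dtype=int)
                j = fibers[pairs[:, 1]] if len(pairs) else np.zeros(0, dtype=int)
                different = self.fiber_id[i] != self.fiber_id[j]
                cache = (self.pair_refresh, fibers.copy(),
                         i[different], j[different])
            self._pair_cache = (cache[0] - 1, cache[1], cache[2], cache[3])
            i, j = cache[2], cache[3]
            if len(i):
                d = self.positions[i] - self.positions[j]
                r = np.linalg.norm(d, axis=1)
                ok = (r > 1e-300) & (r < p.inter_cutoff)
                e = np.exp(-p.a_inter * (r - p.r0_inter))
                dUdr = 2.0 * p.k_inter * (1.0 - e) * p.a_inter * e
                f = np.zeros_like(d)
                f[ok] = (-dUdr[ok] / r[ok])[:, None] * d[ok]
                np.add.at(out, i, f)
                np.add.at(out, j, -f)
        # integrin-fiber harmonic bonds (vectorized over the bond dict)
        if self.integ_bonds:
            items = np.asarray(sorted(self.integ_bonds.items()), dtype=int)
            ii, ff = items[:, 0], items[:, 1]
            live = self.alive[ii] & self.alive[ff]
            ii, ff = ii[live], ff[live]
            if len(ii):
                d = self.positions[ii] - self.positions[ff]
                r = np.linalg.norm(d, axis=1)
                ok = r > 1e-300
                f = np.zeros_like(d)
                f[ok] = (-2.0 * p.k_integ * (r[ok] - p.r0_integ) / r[ok])[:, None] * d[ok]
                np.add.at(out, ii, f)
                np.add.at(out, ff, -f)
        return out

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "drag": self.drag.tolist(),
            "role": self.role.tolist(),
            "fiber_id": self.fiber_id.tolist(),
            "alive": self.alive.astype(int).tolist(),
            "tensile_bonds": self.tensile_bonds.tolist(),
            "bending_bonds": self.bending_bonds.tolist(),
            "integ_bonds": {str(k): v for k, v in self.integ_bonds.items()},
            "cyto_bonds": {str(k): v for k, v in self.cyto_bonds.items()},
            "cell_surface": self.cell_surface,
            "forward": self.forward.tolist(),
            "circumradius": self.circumradius,
            "n_integrins": self.n_integrins,
            "max_bond_length": self.max_bond_length,
            "creation_window": list(self.creation_window),
            "params": vars(self.params),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ParticleSystem":
        ps = cls(BondParams(**doc["params"]))
        ps.positions = np.asarray(doc["positions"], dtype=float).reshape(-1, 2)
        ps.drag = np.asarray(doc["drag"], dtype=float)
        ps.role = np.asarray(doc["role"], dtype=int)
        ps.fiber_id = np.asarray(doc["fiber_id"], dtype=int)
        ps.alive = np.asarray(doc["alive"], dtype=int).astype(bool)
        ps.tensile_bonds = np.asarray(doc["tensile_bonds"], dtype=int).reshape(-1, 2)
        ps.bending_bonds = np.asarray(doc["bending_bonds"], dtype=int).reshape(-1, 3)
        ps.integ_bonds = {int(k): int(v) for k, v in doc["integ_bonds"].items()}
        ps.cyto_bonds = {int(k): [int(v) for v in vs]
                         for k, vs in doc["cyto_bonds"].items()}
        ps.cell_surface = doc["cell_surface"]
        ps.forward = np.asarray(doc["forward"], dtype=float)
        ps.circumradius = float(doc["circumradius"])
        ps.n_integrins = int(doc["n_integrins"])
        ps.max_bond_length = float(doc["max_bond_length"])
        ps.creation_window = tuple(doc["creation_window"])
        return ps


# ----------------------------------------------------------------------
# substrate generation
# ----------------------------------------------------------------------

def build_substrate(spec: SubstrateSpec, rng: np.random.Generator,
                    params: BondParams | None = None,
                    fiber_drag: float = 1.0) -> ParticleSystem:
    """Random fibers of random length and orientation inside the sine band.

    Each fiber is a straight chain of particles at the tensile rest spacing,
    with tensile bonds between adjacent particles and a bending bond over
    each interior triple.  A fiber that cannot be placed fully inside the
    band after ``max_retries`` redraws is skipped (logged).
    """
    ps = ParticleSystem(params)
    lo, hi = spec.particles_per_fiber
    tens = []
    bend = []
    placed = 0
    for fiber in range(spec.n_fibers):
        ok = False
        for _ in range(spec.max_retries):
            n = int(rng.integers(lo, hi + 1))
            x0 = rng.uniform(*spec.x_range)
            yc = float(spec.band_center(x0))
            y0 = rng.uniform(yc - 0.5 * spec.width, yc + 0.5 * spec.width)
            angle = rng.uniform(0.0, np.pi)
            direction = np.array([math.cos(angle), math.sin(angle)])
            pts = np.array([x0, y0]) + np.arange(n)[:, None] * spec.spacing * direction
            if spec.inside_band(pts).all():
                ok = True
                break
        if not ok:
            logger.info("fiber %d rejected: does not fit in band", fiber)
            continue
        ids = ps.add_particles(pts, fiber_drag, ROLE_FIBER, fiber=placed)
        tens.extend(zip(ids[:-1], ids[1:]))
        bend.extend(zip(ids[:-2], ids[1:-1], ids[2:]))
        placed += 1
    ps.tensile_bonds = np.asarray(tens, dtype=int).reshape(-1, 2)
    ps.bending_bonds = np.asarray(bend, dtype=int).reshape(-1, 3)
    return ps


# ----------------------------------------------------------------------
# cell queries
# ----------------------------------------------------------------------

def leading_edge(mesh, sid: int, forward: np.ndarray) -> tuple[int, int]:
    """The two forward-most vertices of the cell; ties broken by ascending id."""
    cyc = mesh.surfaces[sid].cycle
    if len(cyc) < 2:
        raise ValueError("cell needs at least two vertices")
    proj = mesh.positions[np.asarray(cyc)] @ np.asarray(forward, dtype=float)
    order = sorted(range(len(cyc)), key=lambda k: (-proj[k], cyc[k]))
    pair = sorted((cyc[order[0]], cyc[order[1]]))
    return pair[0], pair[1]


def point_in_cell(points: np.ndarray, mesh, sid: int) -> np.ndarray:
    """Even-odd ray test against the cell polygon; boundary counts as inside."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cyc = np.asarray(mesh.surfaces[sid].cycle)
    poly = mesh.positions[cyc]
    n = len(poly)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        # even-odd crossing of a rightward ray
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < np.where(cond, xin, np.inf))
        # boundary test: distance to the segment
        ex, ey = x2 - x1, y2 - y1
        L2 = ex * ex + ey * ey
        if L2 < 1e-300:
            continue
        t = np.clip(((x - x1) * ex + (y - y1) * ey) / L2, 0.0, 1.0)
        d2 = (x - (x1 + t * ex)) ** 2 + (y - (y1 + t * ey)) ** 2
        on_edge |= d2 < 1e-24
    result = inside | on_edge
    return result if np.ndim(points) > 1 else result


def _distance_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    e = b - a
    L2 = float(e @ e)
    if L2 < 1e-300:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ e / L2, 0.0, 1.0)
    foot = a + t[:, None] * e
    return np.linalg.norm(points - foot, axis=1)


# ----------------------------------------------------------------------
# integrin lifecycle
# ----------------------------------------------------------------------

def integrin_lifecycle(state) -> None:
    """Destroy and replace integrins so the live count stays at its target.

    A cytoskeleton bond breaks when longer than the maximum bond length; an
    integrin dies when it leaves the cell polygon or when both its
    cytoskeleton bonds are gone.  Replacements pick a random fiber segment
    particle within the creation window (5-25 % of the initial-cell
    circumradius) of the current leading edge, place the integrin on it, and
    bind it to that particle and to both current leading-edge vertices.
    Vertices bound at creation are kept for the bond's lifetime.
    """
    ps: ParticleSystem = state.particles
    mesh = state.mesh
    rng = state.rng
    sid = ps.cell_surface
    if sid is None:
        return
    # 1. break overlong cytoskeleton bonds
    for integ in sorted(ps.cyto_bonds):
        kept = []
        for v in ps.cyto_bonds[integ]:
            if v not in mesh.vertices:
                continue
            L = float(np.linalg.norm(ps.positions[integ] - mesh.position(v)))
            if L <= ps.max_bond_length:
                kept.append(v)
        ps.cyto_bonds[integ] = kept
    # 2. destroy integrins outside the cell or with no remaining bonds
    live = ps.live_integrins
    if len(live):
        inside = point_in_cell(ps.positions[live], mesh, sid)
        for pid, ok in zip(live, inside):
            if not ok or not ps.cyto_bonds.get(pid):
                ps.kill(pid)
    # 3. create replacements at eligible fiber particles near the leading edge
    deficit = ps.n_integrins - len(ps.live_integrins)
    if deficit <= 0:
        return
    v1, v2 = leading_edge(mesh, sid, ps.forward)
    a, b = mesh.position(v1), mesh.position(v2)
    fibers = ps.live_fiber_particles
    if not len(fibers):
        logger.info("no fiber particles; integrin creation deferred")
        return
    dist = _distance_to_segment(ps.positions[fibers], a, b)
    wlo, whi = ps.creation_window
    in_window = (dist >= wlo) & (dist <= whi)
    # the integrin sits on the cell directly above the fiber particle, so the
    # particle must lie under the area occupied by the cell
    under_cell = point_in_cell(ps.positions[fibers], mesh, sid)
    eligible = fibers[in_window & under_cell]
    for _ in range(deficit):
        if not len(eligible):
            logger.info("no eligible fiber particle in window; creation deferred")
            return
        pick = int(eligible[rng.integers(len(eligible))])
        pid = int(ps.add_particles(ps.positions[pick].copy(),
                                   drag=0.100, role=ROLE_INTEGRIN)[0])
        ps.integ_bonds[pid] = pick
        ps.cyto_bonds[pid] = [v1, v2]


# ----------------------------------------------------------------------
# coupling into the solver step
# ----------------------------------------------------------------------

def coupled_forces(state, mesh_forces: np.ndarray) -> np.ndarray:
    """Particle forces; cytoskeleton bonds also push on their mesh vertices."""
    ps: ParticleSystem = state.particles
    mesh = state.mesh
    pf = ps.bonded_forces()
    k = ps.params.k_cyto
    pairs = [(integ, v) for integ in sorted(ps.cyto_bonds) if ps.alive[integ]
             for v in ps.cyto_bonds[integ] if v in mesh.vertices]
    if pairs:
        arr = np.asarray(pairs, dtype=int)
        ii, vv = arr[:, 0], arr[:, 1]
        d = ps.positions[ii] - mesh.positions[vv]
        r = np.linalg.norm(d, axis=1)
        ok = r > 1e-300
        f = np.zeros_like(d)
        f[ok] = (-k / r[ok])[:, None] * d[ok]
        np.add.at(pf, ii, f)
        np.add.at(mesh_forces, vv, -f)
    return pf
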