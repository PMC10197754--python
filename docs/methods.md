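# Methods

This note documents the model, the numerical choices, and the scope of what
the shipped tests demonstrate.

## Mesh model and triangulated measures

A mesh holds vertices (positions in 2 or 3 dimensions), surfaces (ordered
cycles of ≥3 vertex ids; edges are implicit between consecutive cycle
entries) and bodies (unordered sets of ≥4 surfaces forming a connected,
closed shell; a surface belongs to at most two bodies).  All references are
bidirectional and `validate_mesh` checks every structural invariant;
validation is opt-in during stepping because it is O(mesh).

Every surface is triangulated as a centroid fan: triangle k spans cycle
vertices k, k+1 and the centroid (the plain vertex mean).  All measures
derive from the triangle normals η_k = (r_k − C) × (r_{k+1} − C):

* surface area A_S = ½ Σ‖η_k‖, unit normal = normalized Σ η_k;
* vertex area share A_{V,S} = half the area of the vertex's two triangles;
  shares sum exactly to A_S;
* body volume V_B = Σ_S α(B,S) · (1/6) Σ_k C·(r_k × r_{k+1}), with the
  orientation sign α = +1 iff the surface normal points away from the
  area-weighted body centroid.  α is recomputed at every evaluation rather
  than cached across topology changes — robustness over speed at the
  problem sizes this package targets.
* vertex volume share V_{V,B} = (V_B / A_B) Σ_S A_{V,S}; shares sum to V_B.

Surfaces are assumed flat and convex (the constraint actors enforce this
dynamically in 3D); the geometry operations do not verify it.  Degenerate
geometry (zero-area surfaces, zero normals) is reported, not raised, so the
topology operations can repair the mesh.  The area-weighted body centroid is
not the volumetric centroid for strongly non-convex bodies; it is retained
as the model's definition.

## Dynamics

Overdamped force balance f = M dr/dt, integrated with forward Euler.  Drag
is a fixed constant by default; in variable mode it is assembled from drag
densities, M(V) = Σ ρ·V_{V,B} (3D) or Σ ρ·A_{V,S} (2D), which makes a
uniformly loaded cell translate rigidly with velocity τ/ρ — the defining
property of the drag derivation (verified in the tests).  There is no
adaptive stepping; stability is a parameter responsibility (the sorting
demonstration uses a time step already halved for stability) and the
per-step maximum displacement is tracked as a diagnostic.

One step runs: accumulate actor forces → (if particles are present) add
bond forces → Euler update → no-flux clamp onto the domain box (coordinate
projection) → particle integration and integrin lifecycle → event hooks →
quality operations → clock advance.  A single global RNG stream is consumed
in a fixed order (vectorized draws over ascending vertex ids; topology
randomness in candidate order), so a configuration plus a seed determines
the trajectory bit-exactly, including across save/load checkpoints.

## Actors

Actors are bound additively to objects, types, all vertices, or the whole
mesh; all bound actors act simultaneously and accumulation is
order-independent.  Energy-based actors implement analytic gradients with
the full chain rule through the surface centroid (the centroid is a
function of every cycle vertex); every gradient is verified against central
finite differences of its stated energy on randomized configurations
(relative error < 1e−5).

Where only a qualitative description of an actor was available, quadratic
penalty energies consistent with the other constraints were adopted: body
volume and body-surface-area constraints as λ(·−target)², the flat-surface
constraint as ½κ Σ d² on distances to the least-squares plane (its exact
gradient reduces to −κ d n̂ by the envelope theorem, since the best-fit
plane is optimal).  The convex-polygon constraint is an explicit restoring
force κ·deviation on reflex vertices toward the line through their cycle
neighbors — corrective, not variational, so it is excluded from the
finite-difference invariant.  Both shape constraints are ordinary opt-in
actors with user-chosen stiffness (vacuous in planar mode) rather than
auto-applied at a magnitude inferred from other bindings: an implicit
coupling between unrelated actors' stiffnesses would be surprising, and a
3D model's author is best placed to set the scale.  Traction-like magnitudes (surface traction,
normal stress) are per unit area, distributed by A_{V,S}.  Adhesion counts
each shared edge (2D) or shared surface (3D) exactly once, with
coefficients keyed by unordered type pairs; negative coefficients reward
contact.  Random motility is a force of fixed magnitude and uniformly
random direction resampled every step, evaluated before integration.

For performance, all surface cycles are flattened into CSR-style arrays
(rebuilt only when topology changes) and the per-step geometry — edge
vectors, triangle normals, area/perimeter gradients — is computed once and
shared by all actors through a lazy evaluation cache.

## Quality operations

Candidates are enumerated per hierarchy level (vertices, then surfaces,
then bodies) and applied serially in priority order — ascending id of the
owning object (merges are owned by the lesser vertex id, splits by the
splitting vertex, demotes by the removed object, inserts by the penetrated
surface).  An operation is skipped if any object it would affect was
already affected this step, so accepted operations have disjoint affected
sets.  This serial scheme preserves the priority and at-most-once semantics
of a parallel scheduler while staying deterministic.  Each accepted
operation must leave the mesh valid; operations with non-local effects
snapshot the touched region and roll back otherwise.

* **Vertex merge** — connected vertices closer than the merge distance
  collapse; the removed vertex is a seeded random choice and the survivor
  moves to the pair midpoint (the midpoint choice preserves the pair's
  centroid; which position the survivor should keep is otherwise
  unspecified).  Restricted to pairs whose cycles all have ≥4 vertices.
* **Vertex split** — evaluated every step for every vertex of valence ≥4.
  The cut plane normal is the total relative force Σ_j (f_j − f_c) over
  connected vertices (the alternative (Σf_j) − f_c is a config switch);
  neighbors exactly on the plane go to the positive side.  Candidates sit
  ±(split distance)/2 along the normal, each inheriting f_c/2, and the
  split is accepted when both sides' total relative force (excluding the
  split pair) points away from the plane — the new edge would be in
  tension.  Current-step forces are used without re-evaluation after
  candidate placement.  A split whose side assignment is cycle-contiguous
  produces 2 mixed surfaces (interior T1), 1 (boundary), or 0 (surfaces
  sharing only the vertex disconnect — the reverse T3); non-contiguous
  assignments would create a non-manifold edge and are rejected.
* **Surface demote (T2)** — below the area threshold a surface collapses to
  a vertex at its centroid; connected cycles have the old vertices replaced
  by the new vertex exactly once, cycles that fall below 3 vertices are
  removed, and the operation is rejected if any owning body has exactly 4
  surfaces (a demote may never remove a body).
* **Body demote** — a fixed-point pass collects every body invalidated by
  the collapse (fewer than 4 surfaces after the removals), then all removed
  bodies and their exclusive surfaces are destroyed and boundary surfaces
  are demoted onto the single new vertex at the body centroid.
* **Vertex insert (T3)** — planar mode only, automatically disabled when
  bodies exist.  A vertex whose motion segment crosses an edge of an
  unconnected surface is inserted into that cycle between the edge's
  endpoints; with several crossings the earliest along the motion wins.
  Detection is restricted to free-boundary vertices and free-boundary edges
  (in a confluent planar tissue, unconnected surfaces can only meet across
  the free boundary).

Split distance must exceed the merge distance, preventing an immediate
re-merge of a fresh split.

## Particle subsystem and the migration model

Fibers are chains of particles at the tensile rest spacing with harmonic
pair bonds, harmonic angle bonds over interior triples (rest angle π), and
a Morse-like adhesion U = k(1 − e^{−a(r−r0)})² between particles of
different fibers, cut off at 3·r0 with the potential shifted to continuity
(the neighbor list is refreshed every 10 steps with a 0.02 margin — far
more than the per-interval particle motion at the model's force scales).
Integrins are particles bound to one fiber particle (harmonic) and to the
cell's two leading-edge vertices through linear "cytoskeleton" bonds
U = k·r with k < 0 — a constant-magnitude protrusive push separating the
anchor and the membrane vertex.  Bond forces on vertices and particles are
equal and opposite; each entity integrates with its own drag.

The integrin lifecycle (every step): bonds longer than the maximum bond
length break; an integrin outside the cell polygon (vectorized even–odd ray
test, boundary inclusive) or with no surviving vertex bonds dies; the
population is then refilled to its fixed size by selecting a random fiber
particle within 5–25 % of the initial-cell circumradius from the current
leading-edge segment *and under the cell* — the integrin is placed on the
cell directly above the selected particle, which requires the particle to
be under the cell — and binding it to that particle and both current
leading-edge vertices (bonds never change vertices afterwards).  If no
eligible particle exists, creation defers to the next event.  The leading
edge is the two vertices with the greatest projection on the fixed forward
direction (+x), ties by ascending id.  The circumradius constant is that of
the unit-area regular hexagon, R = √(2/(3√3)) ≈ 0.6204, which reproduces
the printed window bounds [0.0310, 0.155]; the printed maximum bond length
0.921 is used verbatim even though 1.5·R = 0.9306.

The migration cell is a unit-area regular hexagon with its two rightmost
vertices forming a vertical leading edge, under an area constraint and
quadratic edge tension, with quality operations disabled (the base model
keeps six vertices).  Free substrate parameters were fixed once: sine-band
amplitude 0.05 (the band's maximum slope stays small against the fixed +x
polarization the leading-edge rule presumes), band x-extent (0, 6) and 90
fibers of 10–100 particles (fresh ECM ahead of a ~2-length-unit crawl).

### Known limitation: transverse instability of the migration model

The protrusion direction is (leading vertex − anchor).  Anchors can only
form on fibers under the cell, and the unit-area hexagon is taller than the
1.0-wide fiber band, so once the cell acquires a transverse offset its
anchors concentrate on the in-band side and the protrusion pushes it
further off-band — positive feedback.  Combined with the cell raking fibers
backward through its anchors, the creation window eventually empties and
the integrin population decays (typically after 400–1,200 steps across
seeds and substrate geometries).  Relatedly, the free-cell energy
equilibrium under the area constraint and quadratic edge tension is
A* = 1 − (2/√3)·λ_ten/λ_area ≈ 0.423, not the target area, and the
anchored crawling steady state measures A ≈ 0.70–0.75; the demonstration
therefore shows robust forward migration (positive, monotone-trend
x-displacement) but not a conserved integrin count or a near-target cell
area over the full run.

## Demonstration conditions and what passing tests show

Cell sorting runs an n×n aggregate of unit-square cells (8×8 for the scaled
acceptance runs, 20,000 steps of dt = 0.0025, three seeds), types assigned
independently with probability ½, with the area constraint (λ=50, A₀=1),
perimeter constraint (λ=1, L₀=2π), type-dependent edge tension (10 and 20),
the adhesion matrix (−18, −26, −38 for the 1–1, 1–2, 2–2 pairs), random
motility of magnitude 8.94, merge/split distances 0.1/0.2, and a fixed drag
of 1.  The heterotypic boundary fraction (sampled every 100 steps,
normalized at time 0) decays strongly in every seed.  Because the series is
stochastic, its "non-increasing" long-run behavior is asserted as a trend:
the 1,000-step moving average must have a negative Mann–Kendall statistic
(measured ≈ −0.9; pointwise upticks of the smoothed series are ≤0.003
against a total decay of ~0.7, so a strict pointwise test would reject any
stochastic realization).

The synthetic conditions are idealized: square initial cells, uniform
parameters within a type, no boundary medium other than edge tension, and
ECM fibers that are straight chains in a clean band.  Passing tests
demonstrate internal consistency of the mechanics (gradients, conservation
laws, topological bookkeeping) and reproduction of the configured
collective behaviors at desk scale — not quantitative agreement with any
particular tissue.

## Numerical choices

* Tolerances: gradient checks at relative 1e−5 with step 1e−7; geometry
  oracles at 1e−10 (area vs shoelace) and relative 1e−8 (volume vs convex
  hull); conservation identities at machine precision scale.
* Degenerate inputs: zero-length edges contribute zero force (subgradient
  choice at the p=1 tension kink); zero-length bonds contribute zero force;
  degenerate normals skip normal-stress application with a warning.
* Vertex ids are never reused; position storage grows geometrically and
  rows of removed vertices go stale.
* JSON state documents round-trip floats exactly (shortest-round-trip
  reprs) and carry the RNG bit-generator state, so resumed runs are
  bit-identical.  OBJ import welds vertices within 1e−9 of the bounding-box
  diagonal and reconstructs bodies from an explicit face-group manifest.
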