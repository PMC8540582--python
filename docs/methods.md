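# Methods

## Problem setting

Orthognathic planning predicts the post-operative face shape given a set
of osteotomies (bone cuts) and rigid repositioning transforms for the
resulting fragments. The package solves the quasistatic problem only:
inertia, damping and time dependence are out of scope, as is everything
upstream of meshing (CT segmentation, surface cleanup, Boolean operations,
tetrahedralization — these are interactive, tool-specific steps; the
volume mesher's `.node/.ele` output is the package's input format).

## Soft tissue

All facial soft structures are modeled as one homogeneous, isotropic,
compressible Neo-Hookean continuum,

Ψ(F) = μ/2 (tr(FᵀF) − 3) − μ log J + λ/2 (log J)², J = det F,

discretized with linear tetrahedra and one quadrature point per element
whose weight is the rest volume (total-Lagrangian convention; the
formulation leaves open whether weights follow the deformed volume, and
rest volume is the standard choice). Defaults are E = 100 kPa and
ν = 0.47 — facial tissue is nearly incompressible and reported moduli
span 3 kPa–1 MPa, so the default sits in the middle of that range; both
are configurable per scene. Units: lengths mm, stresses kPa, energies
kPa·mm³ = µJ, so external forces are kPa·mm². Gravity is omitted on
purpose: the imaged rest shape is already gravity-loaded, and adding
gravity without first estimating an unloaded rest shape would corrupt the
prediction. `f_ext` remains supported and defaults to zero. Heterogeneous
tissue maps, muscle fibers and viscoelasticity are documented
non-features.

First Piola–Kirchhoff stress and its derivative are implemented in closed
form (P = μ(F − F⁻ᵀ) + λ log J F⁻ᵀ and the corresponding 9×9 blocks) and
are checked against central finite differences in the tests. States with
J ≤ 0 are *non-evaluable* (the log barrier is undefined); evaluation
raises, and the line search treats such trial states as infinite energy.

**Hessian definiteness.** Each 12×12 element block is eigen-projected to
eigenvalues ≥ 0 before assembly (toggleable via `spd_project=False`,
which the finite-difference tests use). Newton's quadratic model must be
solvable under compression; projection is the standard guard. At the rest
pose the Hessian coincides with the linear-elasticity stiffness matrix for
the same Lamé constants, which the suite asserts against an independent
B-matrix assembly on a two-tet mesh.

## Bones and planned transforms

Fragments are rigid: center-of-mass position x_b plus rotation R_b, with
an incremental axis-angle θ_b in the tangent space during a solve, giving
the linearized map x = R_b X − (R_b X)×θ_b + x_b. Accepting an increment
applies the exact exponential map followed by a polar re-projection. In
all shipped experiments fragments are *prescribed* (the plan drives them);
free fragments (6 solved DoFs appended to z) are supported behind the
`prescribed=False` flag with a Tikhonov term 1e-8·(max reduced diagonal)
on their block, because an unloaded, gravity-free fragment is otherwise
indeterminate. The center of mass comes from divergence-theorem integrals
over the closed fragment surface (area centroid for open surfaces); any
fixed reference point would be correct, the COM simply conditions the
rotation block best.

Planned transforms are interpolated geodesically — the target's axis-angle
and translation scaled by k/substeps — so every substep pose is a valid
rigid transform; 10 substeps by default. How intermediate poses are
interpolated is a free choice of this implementation.

## Coupling constraints

Constrained soft DoFs satisfy S x = A z + c with S a pure selection
matrix; reconstruction x = S̃ᵀz + Sᵀ(Az + c) makes every iterate feasible
by construction. Fixed tissue: A = 0, c = rest position. Tissue bonded to
a prescribed fragment: A = 0, c = blended rigid image of the node,
refreshed each substep. Coupling to free fragments fills A-rows with the
weighted linearized rigid map. Only nodes on the matched tissue–bone
interface are ever coupled; interior nodes stay free.

**Face groups.** The tissue-side interface mesh shares its vertices with
the volume mesh. Each interface face is labeled with the fragment whose
surface is nearest to its centroid (ties within 1e-9 mm go to the
lexicographically smallest fragment id, for determinism); vertices
incident to faces of two or more labels form the cut-interface set.

**Smooth coupling (LBS).** A coupled node at Euclidean distance d from
the nearest cut-interface vertex weighs its own fragment
0.5 + 0.5·min(d, r)/r with r = 10 mm (1 cm) and gives the complement to
the nearest fragment across the cut; on the cut both fragments weigh 0.5,
beyond r the node is rigidly bonded. Distance is point-to-cut-vertex
Euclidean, not geodesic: cuts are near-planar and the difference is
second-order at the 1 cm scale. Weights are computed once in the rest
pose (consistent with a constant A). Where three or more fragments meet,
only the two nearest are blended and renormalized. Positions are blended
(standard LBS), not rotations.

## Contact

Sliding contact is a one-sided quadratic penalty. Per penetrating soft
surface vertex: witness = closest point on the obstacle, normal = outward
gradient of a voxelized signed distance field (1 mm default resolution,
trilinear interpolation, rebuilt when a prescribed fragment moves). With
the contact set frozen, V = ½k‖Uᵀ(Bx+d)‖² is a true quadratic with a
constant PSD Hessian; the set is refreshed at the start of every Newton
iteration. Only penetrating pairs are active — an equality treatment
would glue the surfaces instead of letting them slide. The penalty
stiffness default is k = 1e4 (kPa·mm per unit violation), chosen so slab
fixture penetrations stay below 0.1 mm; the residual penetration decays
as O(1/k), which the suite verifies over k = 1e2…1e5 with stiffness
continuation (each solve warm-started from the previous k) — at very
high k a cold-started penalty solve can chatter between contact sets.

## Solver

Each substep minimizes V_soft + V_contact over z. One Newton iteration:
assemble (H, g), reduce via (S̃ + AᵀS) H (S̃ᵀ + SᵀA), solve with a sparse
LU factorization (systems at coarse planning scale are small enough that
a direct, deterministic solve is preferable), then a backtracking Armijo
line search (c = 1e-4, shrink 0.5) on the true energy; non-evaluable
trials count as +∞. If the Newton direction fails the descent test the
step falls back to steepest descent scaled to at most 1 mm per DoF.
Convergence: ‖Jᵀg‖∞ ≤ grad_tol·(1 + |V|/s) with grad_tol = 1e-6 and
s = E·(mean tet volume)^{2/3}, making the criterion mesh-size
independent; iteration cap 50 per substep. These values are this
package's defaults — the underlying method prescribes none. Substeps are
warm-started from the previous solution; the whole solver is
deterministic (no randomness anywhere).

## Synthetic scenes

`make_slab_scene` emulates the geometric invariants of prepared clinical
scenes without any patient data: a structured tissue slab (each hex split
into 5 tets with alternating parity so neighboring cells share diagonals
conformally), axis-aligned bone blocks embedded as voids whose boundary
triangles are *vertex-identical* with the tissue mesh — the analogue of
the Boolean-difference guarantee that tissue and bone surfaces match
exactly — and grid-snapped cut planes that split blocks into watertight
fragments (cut cross-sections are capped with a strip triangulation that
uses only perimeter grid nodes). Optional seeded jitter (≤ 20% of the
cell size) perturbs interior nodes only, so irregular meshes can be
tested while the interface stays exact. One cut plane per block is
supported in capped (closed-surface) form.

What the fixtures do **not** emulate: curved anatomy, thin lips and
nostril topology, sliding of skin over teeth, mesh grading, and
segmentation noise. Passing tests therefore demonstrate correctness of
the mechanics, constraints, solver and metrics — not clinical accuracy on
real faces, which requires patient meshes.

Default study conditions used throughout tests and the acceptance script:
60×20×20 mm slab at 5 mm cells (900 tets) with a 30×10×5 mm block cut at
its mid-plane, 4 mm fragment advancement, 10 substeps; the Newton-budget
check uses a finer 64×24×18 mm slab at ~3.4k tets. These sizes keep every
check at desk scale while remaining in the coarse-mesh regime the method
targets.

## Validation pipeline

Fragment transforms are recovered with plain point-to-point ICP (closest
point on the target surface, Procrustes/SVD update with reflection guard,
max 100 iterations, RMS-change tolerance 1e-8 mm, no outlier trimming —
the metric variant and trimming policy are free choices here). Error maps
use signed closest-point distance with the generalized winding number
deciding inside/outside; negative error means the simulated surface lies
inside the reference. Cumulative curves are **area-weighted** (one third
of incident face area per vertex) over 1 mm-spaced thresholds 1–8 mm,
with vertex counting available behind a flag; 3 mm is reported as the
clinical threshold, and exported error overlays record a ±4 mm color-map
range. The ROI is a caller-supplied vertex mask (no automatic neck or
occiput detection).

## Numerical and I/O choices

- 0-based indices internally; OBJ and TetGen bases converted at I/O.
  The TetGen index base is inferred from the first node record.
- Tet orientation: (a,b,c,d) with dot(cross(b−a, c−a), d−a) > 0; inverted
  input tets are repaired by swapping two indices, volumes below
  1e-9 mm³ are rejected.
- STL import welds duplicate vertices at 1e-6 mm (far below any mesh
  resolution); OBJ group tags carry face-group labels.
- Closest-point queries scan all triangles exactly (chunked); at the
  mesh sizes involved this is faster to trust than a spatial index.
  Inside/outside uses the generalized winding number at threshold 0.5.
- Legacy-ASCII VTK output with `%.17g` formatting round-trips exactly.
- File formats (OBJ/STL/PLY surfaces, TetGen volumes, legacy VTK output)
  are an interoperability decision of this package.

## Known limitations

- Homogeneous material only; per-element materials are an extension
  point, not implemented.
- No friction, no continuous collision detection; soft–soft contact uses
  nearest-vertex witnesses and is configured per surface pair.
- Penalty contact admits O(1/k) penetration by construction.
- ICP assumes rough initial overlap (no global registration) and can
  stall on rotationally symmetric fragments.
- Fixtures use axis-aligned blocks and grid-snapped cuts; arbitrary cut
  planes classify faces correctly but leave fragment surfaces uncapped.
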