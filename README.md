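# orthosim

Soft-tissue simulation for **orthognathic surgical planning**: predict how
the face deforms when cut bone fragments (maxilla, mandible, chin) are
rigidly repositioned according to a surgical plan.

The package is aimed at researchers in surgical simulation and computational
biomechanics who want a complete, testable reference pipeline: a nonlinear
tetrahedral FEM for the facial soft tissue, rigid-body bone fragments driven
by planned transforms, exact constraint-based tissue–bone coupling with
smooth blending across osteotomy cuts, penalty sliding contact, and the
quantitative validation loop (ICP fragment registration + signed
closest-point error maps). No patient data is required or distributed:
every component is exercised on synthetic slab-and-block scenes that
reproduce the geometric structure of the clinical setup, including the
matched tissue–bone interface meshing.

## Model

The soft tissue is a homogeneous Neo-Hookean continuum (E = 100 kPa,
ν = 0.47 by default), discretized with linear tetrahedra, one integration
point per element:

```
Ψ(F) = μ/2 (tr(FᵀF) − 3) − μ log det F + λ/2 (log det F)²
V_soft(x) = Σᵢ wᵢ Ψ(Fᵢ) − f_extᵀ x
```

with Lamé constants μ, λ from (E, ν), wᵢ the rest tet volumes, and gravity
deliberately omitted (the tissue is imaged in its gravity-loaded state).
Bones are rigid bodies parameterized by center of mass x_b and rotation
R_b, with an incremental tangent-space rotation θ_b during solves; they
contribute no elastic energy. Tissue fixing and tissue–bone coupling are
expressed as exact linear constraints

```
S x = A z + c,      x = S̃ᵀ z + Sᵀ(A z + c)
```

where S selects the constrained DoFs and S̃ its complement, so each Newton
iteration of the constrained quasistatic problem

```
min_x  V_soft(x) + V_contact(x)   s.t.   coupling constraints
```

reduces to the single linear system
`(S̃ + AᵀS) H (S̃ᵀ + SᵀA) z = −(S̃ + AᵀS)(g + H Sᵀ c)` followed by an Armijo
line search. At a bone cut the tissue follows a linear-blend-skinning (LBS)
mix of the two adjacent fragments: weight 0.5/0.5 on the cut, ramping
linearly to 1.0/0.0 over 1 cm. Contact is a one-sided quadratic penalty
`½ k ‖Uᵀ(Bx + d)‖²` on signed penetration measured in a voxelized signed
distance field. Planned transforms are split into 10 substeps, each solved
to equilibrium with warm starts.

Validation mirrors clinical practice: fragment transforms are recovered by
point-to-point ICP between pre- and post-operative fragment surfaces, and
predictions are scored by signed closest-point distance (negative = inside
the reference), summarized as the area percentage of the surface within
1 mm-spaced thresholds — 3 mm being the clinically accepted limit.

## Worked example

```python
import numpy as np
from orthosim import (FixtureSpec, make_slab_scene, make_advance_plan,
                      run_plan, SolverSettings, SurfaceMesh,
                      compute_error_map, error_report)

# 60x20x20 mm tissue slab; an embedded 30x10x5 mm bone block is cut at
# x = 30 mm into two fragments; the slab's top face is fixed.
spec = FixtureSpec(
    slab_dimensions=[60.0, 20.0, 20.0], grid_resolution=(12, 4, 4),
    bone_blocks=[([15.0, 5.0, 5.0], [45.0, 15.0, 10.0])],
    cut_planes=[[([30.0, 10.0, 7.5], [1.0, 0.0, 0.0])]],
    fixed_region="zmax",
)
scene = make_slab_scene(spec)

# advance the distal fragment 4 mm, split into 10 substeps
plans = make_advance_plan(scene, "block0_1", advance_mm=(4.0, 0.0, 0.0))
deformed, log = run_plan(scene, plans, SolverSettings())
disp = np.linalg.norm(deformed.rest_positions - scene.mesh.rest_positions, axis=1)
print(f"max tissue displacement: {disp.max():.2f} mm")

# score the deformed boundary against the pre-operative surface
sim = SurfaceMesh(deformed.rest_positions, scene.mesh.boundary_surface.faces)
ref = SurfaceMesh(scene.mesh.rest_positions, scene.mesh.boundary_surface.faces)
summary = error_report(compute_error_map(sim, ref))
print(f"{summary['pct_within_clinical']:.1f}% of the surface moved < 3 mm")
```

Output:

```
max tissue displacement: 4.05 mm
94.6% of the surface moved < 3 mm
```

The 900-tet scene solves in 74 Newton iterations over the 10 substeps. The
tissue bonded to the advanced fragment follows its full 4 mm motion, the
LBS band spreads the transition smoothly across the cut, and the fixed top
face holds still — so ~95% of the surface stays within the 3 mm clinical
threshold while the region over the moving fragment carries the planned
displacement.

A command-line interface wraps the same pipeline:

```bash
orthosim fixtures make-slab --spec spec.json --out-dir scene/
orthosim simulate --scene scene/scene.json --out result.vtk --log log.csv
orthosim register --source pre_frag.obj --target post_frag.obj --out transform.json
orthosim validate --sim result.vtk --reference postop.obj --out report/
```

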