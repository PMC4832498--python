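# Methods

## Model and assumptions

The body is an incompressible fluid enclosed by a closed, consistently
oriented triangular surface. All mechanics lives on the surface:

* every pair of surface vertices is connected by a Hookean fiber whose
  stiffness is proportional to the mean of the two vertex areas and inverse
  to the rest length, divided by the vertex's number of connections so the
  modulus Y stays a material constant independent of mesh density;
* edge-adjacent vertices additionally interact through a surface-tension
  term γ with an inverse-square length dependence;
* the fluid contributes a single pressure-variation unknown P coupled to all
  displacement components through the volume-conservation constraint
  Σᵢ Sᵢ·uᵢ = 0, which mimics the cross-axis coupling of a stress tensor.

The solution is quasi-static: each load increment is an equilibrium solve;
inertia, waves and vibrations are outside the model, as is any body not
well approximated by a fluid-filled membrane. Self-contact and contact with
obstacles are not detected; contact loads enter as prescribed per-vertex
forces.

## Geometry

Face area vectors are half cross products, outward by winding. Vertex area
vectors are face-vector sums scaled by one *global* constant
C = Σ|Aᵢ| / Σᵢ|Σₖ Aₖ|, so the vertex total equals the face total
identically; this is why the package reports a single surface area. In 2D
the "faces" are boundary edges, the area vector is the outward edge normal
times the edge length, and the same normalization applies over the two
incident edges (reproducing |Sᵢ| = 35 on the 30×40 rectangle).

The published area table for the 642-vertex sphere lists a vertex total
(12.5037) slightly below the face total (12.5065). Under the normalization
above the two sums cannot differ; our construction (golden-ratio
icosahedron, midpoint subdivision with radial projection) reproduces the
face total to all printed digits and reports the same value for the vertex
total, 2·10⁻⁴ relative away from the published vertex figure.

## Concave fiber culling

Fibers must not leave the solid. Two tests run once on the undeformed
geometry (connectivity is frozen afterwards):

1. **Local outward test.** At endpoint i, the fiber direction is compared
   against every incident face normal: any significantly negative
   Aₖ·(sᵢ − sⱼ) means the fiber exits through face k. This half-space
   intersection logic is valid only where the surface is locally convex; at
   a vertex on a reflex edge the inward directions form a *union* of
   half-spaces and the rule would cull strictly interior fibers (e.g. the
   chord from an L-prism arm tip to the opposite notch corner). The test is
   therefore applied only at endpoints with no incident reflex edge.
2. **Segment–triangle test.** The open segment is tested against every face
   not incident to either endpoint (with a bounding-box prefilter). A
   crossing requires a strict transversal plane crossing (coplanar segments
   and endpoint-on-plane contacts are excluded) but uses *inclusive*
   barycentric containment: a transversal hit on a triangle's boundary edge
   still means the chord touches the surface. A strictly interior chord can
   never do this, so convex bodies lose no fibers, while in-plane escapes —
   cap-plane chords shortcutting across a notch, which graze non-incident
   wall faces exactly on their edges — are correctly removed.

On L-prisms of several proportions the resulting culled set matches a
winding-number (solid-angle) point-in-polyhedron oracle sampled at the
chord quartiles for every fiber the oracle can classify decisively; chords
lying exactly on a face are undecidable for any inside/outside oracle and
convention-dependent.

After culling, the per-vertex effective connection count replaces N−1 in
the stiffness denominator. A vertex with fewer than two connections is an
assembly error.

## The linear system

Unknown ordering is x-block, y-block, (z-block), then P. Fiber and surface
couplings appear as negative off-diagonals with the positive row sum on the
diagonal (restoring form), so uniform translations are annihilated; on a
closed surface Σ Aᵢ = 0 also kills the volume row, leaving per-axis rigid
translations as the expected null modes until boundary conditions are
applied. The pressure column and the volume row both carry +Sᵢ — the
symmetric convention matching the published worked matrix; with it the sign
of the solved P is opposite to the outward-pushing pressure of the force
balance written with −Sᵢ, which affects no displacement.

Per-axis moduli Y_x, Y_y, Y_z scale their axis blocks (the simplest reading
of the anisotropic formulation). The surface-tension denominator uses the
squared distance, as published, even though this makes γ's unit force/length
only when areas and lengths balance; a published breast parameter set pairs
γ = 48 MN/m with Y = 48 kPa, six orders apart, which we take as a printing
artifact and do not use in the synthetic analog (see below).

Boundary conditions overwrite the diagonal of each constrained degree of
freedom with a penalty (default 10⁹, configurable); a warning is emitted if
the penalty is within 10³ of the largest coupling. Penalty leakage is
load-dependent: the constrained corner of the worked rectangle moves
< 10⁻⁶ of the free maximum, while the heavily loaded sphere cap moves a few
10⁻⁶ of it.

## Incremental solution

Loads ramp linearly over n increments. Every increment rebuilds the
right-hand side on the *current* geometry — updated vertex areas Sᵢ and
vertical drops hᵢ (hydrostatic term ρ hᵢ Δa Sᵢ) — and solves for the
incremental displacements, which are added to the positions.

* `linear_reuse` (default): the matrix is assembled once from the reference
  configuration and its LU factorization (scipy, partial pivoting) is reused
  for every increment, including decompression. This is the fast path for
  linear materials.
* `nonlinear_refactor`: the matrix is reassembled each increment from the
  current geometry; a user-supplied stiffness rule may map the previous
  increment's pair-displacement magnitudes to Y_ij (the shipped default is
  the constant, linear law, since no specific functional form is canonical).

The two modes agree to under 1 % of the radius at moderate deformation
(|u| ≈ 0.13 R on the test sphere); at extreme single-run deformations
(|u| ≈ 0.9 R) they genuinely diverge, as the constant-matrix assumption is
then outside its regime.

After each solve the volume residual |Σ Sᵢ·uᵢ|, normalized by Σ|Sᵢ|·max|u|,
is asserted below 10⁻⁸ (it sits at machine precision in practice) and the
linear-solve residual below 10⁻⁸·(1+max|B|). Singular factorizations (no
boundary conditions) raise with a hint to constrain the rigid mode.

## Reversibility metric

Decompression applies the same ramp with the opposite sign starting from
the deformed state. Because the right-hand side is discretized along the
load path, a full cycle does not return exactly to the start; the mean
residual displacement normalized by the initial bounding-box diagonal
(expressed in percent) measures this first-order error and falls like 1/n.

The synthetic protocol: a 162-vertex unit icosphere, top cap of height
0.2 m fixed, ρ = 1000 kg/m³, gravity ramped to 10 m/s², Y = 48 kPa and
γ = 0 (the published companion γ is dimensionally implausible, and the
simplest analog omits surface tension as the worked rectangle does).
Measured residuals: 4.97 % (n = 1), 0.41 % (n = 10), 0.042 % (n = 100) —
log–log slope ≈ −1, confirming first-order convergence. The absolute
percentage at n = 1 is geometry- and stiffness-dependent: the single-step
hydrostatic load here (ρg·2R = 20 kPa against Y = 48 kPa) drives a ~0.66 R
deformation, larger than a clinically compressed breast, so the analog's
n = 1 residual is larger than the ~3 % reported for patient geometries.
Only the order of magnitude and the 1/n scaling transfer across geometries.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| penalty | 1e9 | constrained-DOF diagonal (units of the stiffness entries) |
| n_steps | 10 | load increments per ramp |
| volume_residual_tolerance | 1e-8 | per-increment conservation guard |
| outward-test tolerance | 1e-9 (relative) | keeps surface chords against rounding noise |
| intersection tolerance | 1e-12 | plane/barycentric classification noise floor |
| OBJ precision | 10 decimals | round-trip fidelity of written meshes |

Degenerate (zero-area) faces are flagged and contribute zero area vectors
rather than aborting, since scanned meshes contain slivers. Coincident
vertices are a hard error (zero-length fibers). The matrix is stored dense:
the all-pairs fiber graph is dense by construction, and the intended mesh
sizes (≤ ~10³ vertices) make dense LU the right tool.

## What the generators emulate — and what they do not

The fixture generators (rectangle, Platonic solids, icospheres, L-prisms)
reproduce published validation geometries exactly and provide concave test
bodies. They do not emulate scanned anatomy: no noise, slivers, holes,
self-intersections or registration artifacts, and no real material
heterogeneity. Passing tests therefore demonstrate the correctness of the
formulation and solver on clean closed meshes, not clinical accuracy on
patient data, which requires scan-based validation outside this package's
scope (the pipeline consumes such surfaces via OBJ once they are closed and
oriented).

Everything is deterministic; no random numbers are used anywhere in the
pipeline, and randomized tests fix their seeds.
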