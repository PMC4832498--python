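# fiberfluid

Quasi-static deformation of soft biological tissue modeled as an
incompressible fluid enclosed by a fiber-networked surface mesh.

Many soft organs (breast, liver) behave mechanically like a fluid volume
wrapped in fibrous tissue. `fiberfluid` implements a fast surface-only
deformation method for such bodies, aimed at surgical planning, image-guided
intervention and simulation research: instead of a volumetric mesh, every
pair of surface vertices is joined by a Hookean elastic fiber, the enclosed
fluid enforces a volume-conservation constraint, and each load increment is
a single dense linear solve.

## The model

The surface is a closed triangular mesh with vertices **s**ᵢ (i = 1..N).
Each face carries an outward area vector **A**ᵢ (half cross product of two
edges) and each vertex an area vector

  **S**ᵢ = C Σₖ **A**ₖ  over incident faces,  C = Σ|**A**ᵢ| / Σᵢ|Σₖ **A**ₖ|,

normalized so that Σ|**S**ᵢ| equals the true surface area. Quasi-static
equilibrium of fiber forces, fluid pressure and external loads gives, per
vertex and axis,

  Σ_{j≠i} Y (|Sᵢ|+|Sⱼ|)(uᵢ − uⱼ) / (2(N−1)|sᵢ−sⱼ|)
   + Σ_k γ (|Sᵢ|+|Sₖ|)(uᵢ − uₖ) / (2|sᵢ−sₖ|²) + P Sᵢ
   = Fᵢᶜᵒⁿᵗᵃᶜᵗ + ρ hᵢ a Sᵢ,

together with the volume-conservation equation Σᵢ **S**ᵢ·**u**ᵢ = 0, where
P is the internal pressure variation, Y the (optionally per-axis) Young's
modulus, γ the surface tension acting between edge-adjacent vertices, ρ the
fluid density, a the gravitational acceleration and hᵢ the vertical drop
from the topmost vertex. The factor N−1 keeps Y discretization-independent;
on concave bodies fibers whose chord leaves the solid are culled (an
outward-normal test plus a segment–triangle intersection test) and N−1 is
replaced by the per-vertex effective connection count. Fixed vertices are
imposed by overwriting their diagonal entries with a 10⁹ penalty. The
(dN+1)-square system is LU-factorized once and the factorization reused
across load increments for linear materials; a nonlinear stress–strain rule
triggers per-step reassembly.

## Worked example

The classic four-vertex check: a rectangle with corners (±15, ±20), Y = 360,
upward forces of 1680 on both upper corners, lower-left corner fixed and
lower-right corner sliding horizontally:

```sh
python examples/rectangle_worked_example.py
```

prints the vertex areas |**S**ᵢ| = 35, the full 9×9 system matrix
(diagonal 329, couplings −105/−84/−140, pressure column ±28/±21, penalties
10⁹) and the solved shape

```
deformed corner positions:
[[ 11.          25.33333501]
 [ 11.         -19.99999832]
 [-15.         -19.99999832]
 [-15.          25.33333501]]
pressure variation P = 32.000
```

— the rectangle narrows to x = 11 on the right while the top rises to
y ≈ 25.3, preserving the enclosed area: the work done by the corner forces
is redistributed through the fluid. Other scripts in `examples/` cover the
area validation table, a sphere sagging under ramped gravity, concave fiber
culling on an L-prism, and the load–unload reversibility study.

A thin CLI wraps the same library:

```sh
fiberfluid fixture icosphere --subdiv 2 -o sphere.obj
fiberfluid areas sphere.obj
fiberfluid validate
fiberfluid deform config.yaml      # see src/fiberfluid/config.py for schema
fiberfluid revtest config.yaml -n 1 -n 10 -n 100
```

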