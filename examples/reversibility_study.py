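"""Discretization error of the incremental scheme: load–unload residual.

A 162-vertex unit sphere (top cap fixed, Y = 48 kPa, ρ = 1000 kg/m³) is
compressed by ramping gravity to 10 m/s² in n increments and then
decompressed in n increments.  The mean residual vertex displacement,
normalized by the bounding-box diagonal, measures how far the cycle fails to
return to the start; it shrinks like 1/n.
"""

import numpy as np

import fiberfluid as ff

mesh = ff.make_icosphere(2, 1.0)
material = ff.MaterialParams(young_modulus=48000.0, fluid_density=1000.0)
load = ff.LoadCase(gravity=10.0, constraints=ff.fixed_cap_constraints(mesh, 0.2))
fibers = ff.prepare_fibers(mesh)

residuals = {}
for n in (1, 10, 100):
    _, final = ff.compress_decompress_cycle(
        mesh, material, load, ff.SolverOptions(n_steps=n), fibers
    )
    res = ff.reversibility_error(mesh, final.deformed_mesh())
    residuals[n] = res.percent
    print(f"n = {n:3d} increments : residual = {res.percent:.4f} %")

slopes = np.diff(np.log10(list(residuals.values())))
print(f"\nlog–log slope per decade of n: {slopes.round(3).tolist()}")
print(
    "The residual drops roughly tenfold per tenfold increase in increments "
    "(first-order scheme): the continuous load path is recovered as n → ∞."
)
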