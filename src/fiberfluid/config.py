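"""YAML run configuration for the command-line pipeline.

Schema (vertex numbers are 1-based, as in OBJ files)::

    mesh:
      fixture: icosphere        # or  path: surface.obj
      subdivisions: 2
      radius: 1.0
      # rectangle takes half_width / half_height; platonic solids take radius
    material:
      young_modulus: 3000.0     # scalar or [Yx, Yy, Yz]
      surface_tension: 0.0
      fluid_density: 1000.0
    load:
      gravity: 10.0
      contact_forces:
        - {vertex: 1, force: [-300.0, -300.0, -300.0]}
      contact_mode: final_step  # or ramp (default)
      constraints:
        - {vertex: 3, axes: [x, y]}
      fixed_cap_height: 0.2     # fixes every vertex in the top cap
      penalty: 1.0e9
    solver:
      mode: linear_reuse        # or nonlinear_refactor
      n_steps: 10
    output:
      mesh: deformed.obj
      table: steps.csv
      log: run.log
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .assembly import AXES, LoadCase, MaterialParams, fixed_cap_constraints
from .mesh import (
    TriangleMesh,
    make_icosphere,
    make_lprism,
    make_platonic,
    make_rectangle,
    read_obj,
)
from .solver import SolverOptions

__all__ = ["RunConfig", "load_config", "build_fixture"]

_PLATONIC = {"tetrahedron", "octahedron", "icosahedron"}


def build_fixture(name: str, **params: float) -> TriangleMesh:
    """Instantiate a named fixture geometry."""
    name = name.lower()
    if name == "rectangle":
        return make_rectangle(
            params.get("half_width", 15.0), params.get("half_height", 20.0)
        )
    if name in _PLATONIC:
        return make_platonic(name, params.get("radius", 1.0))
    if name == "icosphere":
        return make_icosphere(
            int(params.get("subdivisions", 2)), params.get("radius", 1.0)
        )
    if name == "lprism":
        return make_lprism(
            params.get("leg", 2.0),
            params.get("thickness", 1.0),
            params.get("depth", 1.0),
        )
    raise ValueError(f"unknown fixture {name!r}")


@dataclass
class RunConfig:
    mesh: TriangleMesh
    material: MaterialParams
    load: LoadCase
    options: SolverOptions
    output_mesh: Path | None
    output_table: Path | None
    output_log: Path | None


def _build_mesh(section: dict) -> TriangleMesh:
    if ("path" in section) == ("fixture" in section):
        raise ValueError("mesh section needs exactly one of 'path' or 'fixture'")
    if "path" in section:
        return read_obj(section["path"])
    params = {k: v for k, v in section.items() if k != "fixture"}
    return build_fixture(section["fixture"], **params)


def _build_load(section: dict, mesh: TriangleMesh) -> LoadCase:
    n, dim = mesh.n_vertices, mesh.dim
    forces = None
    for entry in section.get("contact_forces", []) or []:
        if forces is None:
            forces = np.zeros((n, dim))
        vi = int(entry["vertex"]) - 1
        if not (0 <= vi < n):
            raise ValueError(f"contact force vertex {vi + 1} out of range 1..{n}")
        vec = np.asarray(entry["force"], dtype=float)
        if vec.shape != (dim,):
            raise ValueError(f"contact force must have {dim} components")
        forces[vi] += vec
    constraints: list[tuple[int, int]] = []
    for entry in section.get("constraints", []) or []:
        vi = int(entry["vertex"]) - 1
        if not (0 <= vi < n):
            raise ValueError(f"constraint vertex {vi + 1} out of range 1..{n}")
        for ax in entry.get("axes", list(AXES)[: dim]):
            constraints.append((vi, AXES[ax]))
    if "fixed_cap_height" in section:
        constraints += fixed_cap_constraints(mesh, float(section["fixed_cap_height"]))
    return LoadCase(
        contact_forces=forces,
        gravity=float(section.get("gravity", 0.0)),
        constraints=constraints,
        penalty=float(section.get("penalty", 1e9)),
        contact_mode=section.get("contact_mode", "ramp"),
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mesh = _build_mesh(raw.get("mesh", {}))
    mat_raw = raw.get("material", {})
    material = MaterialParams(
        young_modulus=mat_raw.get("young_modulus", 0.0),
        surface_tension=mat_raw.get("surface_tension", 0.0),
        fluid_density=mat_raw.get("fluid_density", 0.0),
    )
    load = _build_load(raw.get("load", {}), mesh)
    sol_raw = raw.get("solver", {})
    options = SolverOptions(
        mode=sol_raw.get("mode", "linear_reuse"),
        n_steps=int(sol_raw.get("n_steps", 10)),
    )
    options.check()
    load.check(mesh.n_vertices, mesh.dim)
    out = raw.get("output", {})
    as_path = lambda key: Path(out[key]) if key in out else None
    return RunConfig(
        mesh, material, load, options, as_path("mesh"), as_path("table"), as_path("log")
    )
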