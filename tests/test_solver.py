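"""Linear solves, load ramping, decompression and cycle reversibility."""

import numpy as np
import pytest

import fiberfluid as ff
from conftest import rectangle_load, rectangle_system


def gaussian_elimination(a, b):
    """Independent dense solver: naive Gaussian elimination with partial
    pivoting (no library calls)."""
    a = a.astype(float).copy()
    b = b.astype(float).copy()
    n = len(b)
    for col in range(n):
        piv = col + int(np.argmax(np.abs(a[col:, col])))
        a[[col, piv]] = a[[piv, col]]
        b[[col, piv]] = b[[piv, col]]
        for row in range(col + 1, n):
            f = a[row, col] / a[col, col]
            a[row, col:] -= f * a[col, col:]
            b[row] -= f * b[col]
    x = np.zeros(n)
    for row in range(n - 1, -1, -1):
        x[row] = (b[row] - a[row, row + 1 :] @ x[row + 1 :]) / a[row, row]
    return x


class TestSolveSystem:
    def test_rectangle_worked_solution(self, rectangle):
        system = rectangle_system(rectangle)
        u, p = ff.solve_system(system)
        positions = rectangle.vertices + u
        # right corners end at x = 11; upper corners at y ≈ 25 (paper rounds)
        assert positions[0, 0] == pytest.approx(11.0, abs=1e-9)
        assert positions[1, 0] == pytest.approx(11.0, abs=1e-9)
        assert positions[0, 1] == pytest.approx(25.0, abs=0.5)
        assert positions[3, 1] == pytest.approx(25.0, abs=0.5)

    def test_zero_rhs_zero_solution(self, rectangle):
        system = rectangle_system(rectangle)
        system.rhs = np.zeros_like(system.rhs)
        u, p = ff.solve_system(system)
        np.testing.assert_array_equal(u, 0.0)
        assert p == 0.0

    def test_matches_independent_gaussian_elimination(self, rectangle):
        rng = np.random.default_rng(7)
        system = rectangle_system(rectangle)
        system.rhs = rng.normal(size=9) * 100
        u, p = ff.solve_system(system)
        x = gaussian_elimination(system.matrix, system.rhs)
        np.testing.assert_allclose(np.r_[u.T.ravel(), p], x, atol=1e-10 * np.abs(x).max())

    def test_singular_unconstrained_system_raises(self, icosphere1):
        fa, topo, va = ff.surface_geometry(icosphere1)
        fibers = ff.build_fibers(icosphere1)
        system = ff.assemble_matrix(
            icosphere1, va, fibers, topo,
            ff.MaterialParams(young_modulus=3000.0), ff.LoadCase(),
        )
        with pytest.raises(ff.SolverError, match="boundary"):
            ff.solve_system(system)


@pytest.fixture(scope="module")
def sphere_setup(request):
    mesh = ff.make_icosphere(2, 1.0)
    fibers = ff.prepare_fibers(mesh)
    mat = ff.MaterialParams(young_modulus=48000.0, fluid_density=1000.0)
    load = ff.LoadCase(gravity=10.0, constraints=ff.fixed_cap_constraints(mesh, 0.2))
    return mesh, fibers, mat, load


class TestRunQuasistatic:
    def test_rectangle_single_step_matches_direct_solve(self, rectangle):
        state = ff.run_quasistatic(
            rectangle,
            ff.MaterialParams(young_modulus=360.0),
            rectangle_load(),
            ff.SolverOptions(n_steps=1),
        )
        assert state.positions[0, 0] == pytest.approx(11.0, abs=1e-9)
        assert state.positions[0, 1] == pytest.approx(25.0, abs=0.5)

    def test_zero_load_is_identity(self, icosphere1):
        state = ff.run_quasistatic(
            icosphere1,
            ff.MaterialParams(young_modulus=3000.0),
            ff.LoadCase(constraints=[(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]),
            ff.SolverOptions(n_steps=3),
        )
        np.testing.assert_allclose(state.positions, icosphere1.vertices, atol=1e-12)
        assert state.pressure_variation == 0.0

    def test_displacements_linear_in_load(self, rectangle):
        mat = ff.MaterialParams(young_modulus=360.0)
        load1 = rectangle_load()
        load2 = rectangle_load()
        load2.contact_forces = 2.0 * load1.contact_forces
        opts = ff.SolverOptions(n_steps=1)
        u1 = ff.run_quasistatic(rectangle, mat, load1, opts).cumulative_displacement
        u2 = ff.run_quasistatic(rectangle, mat, load2, opts).cumulative_displacement
        np.testing.assert_allclose(u2, 2.0 * u1, rtol=1e-9, atol=1e-12)

    def test_volume_residual_small_every_step(self, sphere_setup):
        mesh, fibers, mat, load = sphere_setup
        state = ff.run_quasistatic(mesh, mat, load, ff.SolverOptions(n_steps=5), fibers)
        assert len(state.history) == 5
        assert all(rec.volume_residual < 1e-8 for rec in state.history)

    def test_fixed_vertices_barely_move(self, sphere_setup):
        """Penalty leakage is load/penalty-ratio limited: with the 1e9
        penalty and the strong gravity load the cap still moves several
        orders of magnitude less than the free surface."""
        mesh, fibers, mat, load = sphere_setup
        state = ff.run_quasistatic(mesh, mat, load, ff.SolverOptions(n_steps=2), fibers)
        fixed = sorted({vi for vi, _ in load.constraints})
        free = [i for i in range(mesh.n_vertices) if i not in fixed]
        u = np.linalg.norm(state.cumulative_displacement, axis=1)
        assert u[fixed].max() < 1e-5 * u[free].max()

    def test_force_equilibrium_at_unconstrained_vertices(self, rectangle):
        """The assembled internal forces balance the applied loads: A·x = B
        holds row-wise, so K·u + S·P equals the contact forces."""
        system = rectangle_system(rectangle)
        u, p = ff.solve_system(system)
        x = np.r_[u.T.ravel(), p]
        residual = system.matrix @ x - system.rhs
        free_rows = [0, 1, 3, 4, 7, 8]
        assert np.abs(residual[free_rows]).max() < 1e-8 * 1680

    def test_linear_and_nonlinear_modes_agree_for_linear_material(self, sphere_setup):
        """With a linear material and moderate deformation (|u| ≈ 0.13 R) the
        fast reused-factorization path tracks the per-step refactor path to
        under 1 % of the radius."""
        mesh, fibers, mat, _ = sphere_setup
        load = ff.LoadCase(gravity=2.0, constraints=ff.fixed_cap_constraints(mesh, 0.2))
        n = 100
        lin = ff.run_quasistatic(mesh, mat, load, ff.SolverOptions("linear_reuse", n), fibers)
        non = ff.run_quasistatic(
            mesh, mat, load, ff.SolverOptions("nonlinear_refactor", n), fibers
        )
        diff = np.linalg.norm(lin.positions - non.positions, axis=1).max()
        assert diff < 0.01

    def test_stiffness_rule_changes_the_response(self, sphere_setup):
        mesh, fibers, mat, load = sphere_setup

        def hardening(pair_disp):
            return 48000.0 * (1.0 + 5.0 * pair_disp)

        soft = ff.run_quasistatic(
            mesh, mat, load, ff.SolverOptions("nonlinear_refactor", 5), fibers
        )
        hard_mat = ff.MaterialParams(
            young_modulus=48000.0, fluid_density=1000.0, stiffness_rule=hardening
        )
        hard = ff.run_quasistatic(
            mesh, hard_mat, load, ff.SolverOptions("nonlinear_refactor", 5), fibers
        )
        assert (
            np.abs(hard.cumulative_displacement).max()
            < np.abs(soft.cumulative_displacement).max()
        )


class TestDecompress:
    def test_zero_load_cycle_exact_identity(self, icosphere1):
        mat = ff.MaterialParams(young_modulus=3000.0)
        load = ff.LoadCase(constraints=[(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)])
        comp, final = ff.compress_decompress_cycle(
            icosphere1, mat, load, ff.SolverOptions(n_steps=2)
        )
        np.testing.assert_allclose(final.positions, icosphere1.vertices, atol=1e-12)

    def test_single_step_cycle_residual_a_few_percent(self, sphere_setup):
        mesh, fibers, mat, load = sphere_setup
        _, final = ff.compress_decompress_cycle(
            mesh, mat, load, ff.SolverOptions(n_steps=1), fibers
        )
        res = ff.reversibility_error(mesh, final.deformed_mesh())
        assert 0.005 < res.mean_normalized_residual < 0.10

    def test_cycle_residual_scales_inversely_with_steps(self, sphere_setup):
        """First-order reversibility: the load–unload residual drops ≈10× per
        10× more increments (log–log slope −1 ± 0.3)."""
        mesh, fibers, mat, load = sphere_setup
        residuals = []
        for n in (1, 10, 100):
            _, final = ff.compress_decompress_cycle(
                mesh, mat, load, ff.SolverOptions(n_steps=n), fibers
            )
            residuals.append(
                ff.reversibility_error(mesh, final.deformed_mesh()).mean_normalized_residual
            )
        assert residuals[0] > residuals[1] > residuals[2]
        slopes = np.diff(np.log10(residuals))
        assert np.all(np.abs(slopes + 1.0) < 0.3)
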