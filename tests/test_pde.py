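"""Pseudo-spectral solvers: heat oracles, conservation, duality, refinement."""

import itertools

import numpy as np
import pytest

from modfluct.grid import GridField, TorusGrid, norms, wrapped_gaussian
from modfluct.pde import (
    TestFunction,
    solve_dual_backward,
    solve_forward,
    solve_linearized_forward,
)

SIGMA = 1.0


def rel_l2(a: np.ndarray, b: np.ndarray, grid) -> float:
    return norms(GridField(a - b, grid))["l2"] / norms(GridField(b, grid))["l2"]


def periodized_gaussian_bump(grid, center, var):
    """Closed-form heat evolution of a unit-amplitude Gaussian bump, with images."""
    pts = np.stack(grid.meshes, axis=-1)
    out = np.zeros((grid.n,) * grid.d)
    for shift in itertools.product((-1, 0, 1), repeat=grid.d):
        dx = pts - np.asarray(center) + np.asarray(shift) * grid.L
        out += np.exp(-np.sum(dx**2, axis=-1) / (2 * var))
    return out


@pytest.fixture(scope="module")
def limit_solution(u0_field, tables):
    """Attractive limit-equation solve reused across duality tests."""
    return solve_forward(u0_field, tables.Phi_symbol, SIGMA, 1, 0.01, 0.5,
                         snapshot_stride=10, tag="limit")


class TestForward:
    def test_heat_equation_closed_form(self, grid32, u0_field):
        T = 0.5
        sol = solve_forward(u0_field, np.zeros((32,) * 3), SIGMA, 0, 0.01, T)
        exact = wrapped_gaussian(grid32, 0.0, np.sqrt(1.0 + 2 * SIGMA * T))
        assert rel_l2(sol.snapshots[-1].values, exact.values, grid32) < 1e-3
        assert np.abs(sol.mass_series - 1.0).max() < 1e-12

    def test_mass_conservation_interacting(self, limit_solution):
        assert np.abs(limit_solution.mass_series - 1.0).max() < 1e-12
        assert not limit_solution.blew_up
        assert limit_solution.min_series.min() > -1e-6

    def test_repulsive_supnorm_nonincreasing(self, u0_field, tables):
        sol = solve_forward(u0_field, tables.Phi_symbol, SIGMA, -1, 0.01, 0.3,
                            snapshot_stride=5)
        sups = [np.abs(s.values).max() for s in sol.snapshots]
        assert np.all(np.diff(sups) <= 1e-10)

    def test_translation_equivariance(self, grid32, tables):
        u0 = wrapped_gaussian(grid32, 0.0, 1.0)
        shifted = GridField(np.roll(u0.values, 4, axis=0), grid32)
        a = solve_forward(u0, tables.Phi_symbol, SIGMA, 1, 0.01, 0.1)
        b = solve_forward(shifted, tables.Phi_symbol, SIGMA, 1, 0.01, 0.1)
        assert np.allclose(
            np.roll(a.snapshots[-1].values, 4, axis=0), b.snapshots[-1].values,
            atol=1e-11,
        )

    def test_refinement_order(self, u0_field, tables):
        finals = []
        for dt in (0.02, 0.01, 0.005):
            sol = solve_forward(u0_field, tables.Phi_symbol, SIGMA, 1, dt, 0.2,
                                snapshot_stride=max(int(0.2 / dt), 1))
            finals.append(sol.snapshots[-1].values)
        g = u0_field.grid
        e1 = norms(GridField(finals[0] - finals[1], g))["l2"]
        e2 = norms(GridField(finals[1] - finals[2], g))["l2"]
        assert np.log2(e1 / e2) >= 1.8

    def test_negative_initial_data_rejected(self, grid32):
        bad = GridField(-np.ones((32,) * 3), grid32)
        with pytest.raises(ValueError):
            solve_forward(bad, np.zeros((32,) * 3), SIGMA, 0, 0.01, 0.1)


class TestDualBackward:
    def test_terminal_condition_exact(self, limit_solution, tables, grid32):
        phi = TestFunction(center=(1.0, 0.0, 0.0), width=1.0)
        dual = solve_dual_backward(limit_solution, phi, 0.5, tables.Phi_symbol,
                                   SIGMA, 1, 0.01)
        assert np.array_equal(dual.field_at(0.5).values, phi.on_grid(grid32).values)

    def test_constant_terminal_data_stays_constant(self, limit_solution, tables, grid32):
        ones = GridField(np.ones((32,) * 3), grid32)
        dual = solve_dual_backward(limit_solution, ones, 0.5, tables.Phi_symbol,
                                   SIGMA, 1, 0.01)
        for snap in dual.snapshots:
            assert np.abs(snap.values - 1.0).max() < 1e-12

    def test_heat_semigroup_closed_form(self, grid32, u0_field):
        # kappa = 0: the dual flow is the plain heat semigroup applied to phi
        T = 0.5
        u_sol = solve_forward(u0_field, np.zeros((32,) * 3), SIGMA, 0, 0.01, T)
        phi = TestFunction(center=(1.0, 0.0, 0.0), width=1.0)
        dual = solve_dual_backward(u_sol, phi, T, np.zeros((32,) * 3), SIGMA, 0, 0.01)
        var = 1.0 + 2 * SIGMA * T
        exact = (1.0 / var) ** 1.5 * periodized_gaussian_bump(grid32, (1.0, 0, 0), var)
        assert rel_l2(dual.field_at(0.0).values, exact, grid32) < 1e-3

    def test_duality_pairing_conserved(self, limit_solution, tables, grid32, u0_field):
        """<h(s), T(s)> is constant when h solves the linearized forward flow.

        This adjointness is the defining property of the dual backward
        evolution; it holds at snapshot times to near machine precision.
        """
        phi = TestFunction(center=(1.0, 0.0, 0.0), width=1.0)
        dual = solve_dual_backward(limit_solution, phi, 0.5, tables.Phi_symbol,
                                   SIGMA, 1, 0.01)
        h = solve_linearized_forward(limit_solution, u0_field, tables.Phi_symbol,
                                     SIGMA, 1, 0.01, 0.5)
        hd = grid32.h**3
        pair = [
            float(np.sum(h.field_at(s).values * dual.field_at(s).values) * hd)
            for s in (0.0, 0.1, 0.3, 0.5)
        ]
        assert (max(pair) - min(pair)) / abs(pair[0]) < 1e-6

    def test_free_pairing_with_solution_conserved(self, grid32, u0_field):
        # for kappa = 0 the heat flow is self-adjoint, so <u, T> is constant
        T = 0.4
        u_sol = solve_forward(u0_field, np.zeros((32,) * 3), SIGMA, 0, 0.01, T)
        phi = TestFunction(center=(1.0, 0.0, 0.0), width=1.0)
        dual = solve_dual_backward(u_sol, phi, T, np.zeros((32,) * 3), SIGMA, 0, 0.01)
        hd = grid32.h**3
        pair = [
            float(np.sum(u_sol.field_at(s).values * dual.field_at(s).values) * hd)
            for s in (0.0, 0.2, 0.4)
        ]
        assert (max(pair) - min(pair)) / abs(pair[0]) < 1e-6

    def test_coverage_guard(self, u0_field, tables):
        short = solve_forward(u0_field, tables.Phi_symbol, SIGMA, 1, 0.01, 0.1)
        with pytest.raises(ValueError):
            solve_dual_backward(short, TestFunction(), 0.5, tables.Phi_symbol,
                                SIGMA, 1, 0.01)


class TestTestFunction:
    def test_gaussian_grid_matches_pointwise(self, grid32):
        phi = TestFunction(center=(1.0, -2.0, 0.5), width=0.9, amplitude=2.0)
        pts = np.array([[1.0, -2.0, 0.5], [0.0, 0.0, 0.0]])
        vals = phi(pts, grid32.L)
        assert vals[0] == pytest.approx(2.0)
        assert phi.on_grid(grid32).values.max() <= 2.0 + 1e-12

    def test_coordinate_window_support(self, grid32):
        phi = TestFunction(kind="coordinate_window", center=(0.0, 0.0, 0.0), width=1.5)
        pts = np.array([[1.6, 0, 0], [0.0, 4.0, -4.0]])
        vals = phi(pts, grid32.L)
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(np.exp(0.0), rel=1e-12)  # center value 1

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            TestFunction(kind="spline")(np.zeros((1, 3)), 10.0)
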