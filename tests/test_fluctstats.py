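"""Fluctuation statistics: sampling identities, CLT machinery, diagnostics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from modfluct.dynamics import SimulationConfig, sample_initial, wrap
from modfluct.fluctstats import (
    FluctuationSamples,
    clt_test,
    estimate_rate,
    iid_identity_value,
    lln_probability,
    pair_fluctuation,
    predicted_variance,
    smoothed_error,
    smoothed_field,
    solve_intermediate_pde,
)
from modfluct.grid import GridField, norms, spectral_convolve, wrapped_gaussian
from modfluct.pde import TestFunction, solve_dual_backward, solve_forward

PHI = TestFunction(center=(1.0, 0.0, 0.0), width=1.0)


def draw_iid(rng, N, L=10.0, s0=1.0):
    return wrap(s0 * rng.standard_normal((N, 3)), L)


class TestIidSamplingIdentity:
    @pytest.mark.parametrize("N", [100, 1000])
    def test_matches_closed_form(self, tables, u0_field, N):
        """Monte-Carlo E||Z*(mu-u)||^2 equals (1/N)(||Z||^2 - ||Z*u||^2)."""
        pred = iid_identity_value(tables, u0_field, N)
        g_smooth = spectral_convolve(u0_field, tables.Z_eta_symbol)
        rng = np.random.default_rng(101)
        vals = []
        for _ in range(200):
            f = smoothed_field(draw_iid(rng, N), tables)
            vals.append(norms(GridField(f.values - g_smooth.values, tables.grid))["l2"] ** 2)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - pred) < 3 * se

    def test_continuum_standin_vanishes(self, tables, u0_field):
        # replacing the histogram by ubar itself zeroes the error field
        f = spectral_convolve(u0_field, tables.Z_eta_symbol)
        g = spectral_convolve(u0_field, tables.Z_eta_symbol)
        assert norms(GridField(f.values - g.values, tables.grid))["l2"] == 0.0


@pytest.fixture(scope="module")
def record(tables):
    from modfluct.dynamics import simulate_interacting

    config = SimulationConfig(N=128, T=0.1, dt=0.01, snapshot_stride=5, seed=11)
    ubar = solve_intermediate_pde(config, tables)
    times, snaps = simulate_interacting(config, tables, config.rng(0))
    return smoothed_error(times, snaps, ubar, tables)


class TestSmoothedError:
    def test_nonnegative_and_mean_free(self, record):
        assert np.all(record.l2_sq >= 0.0)
        assert np.all(record.h1_sq >= 0.0)
        assert record.mean_residual < 1e-12

    def test_sup_and_dissipation(self, record):
        assert record.sup_l2_sq == record.l2_sq.max()
        assert record.dissipation >= 0.0


class TestPairFluctuation:
    def test_constant_observable_cancels(self, u0_field, rng):
        ones = TestFunction(kind="constant", amplitude=1.0)
        X = draw_iid(rng, 400)
        assert abs(pair_fluctuation(X, u0_field, ones)) < np.sqrt(400) * 1e-12

    def test_linearity(self, u0_field, rng):
        X = draw_iid(rng, 300)
        phi1 = TestFunction(center=(1.0, 0, 0), width=1.0)
        phi2 = TestFunction(center=(-1.0, 0.5, 0), width=1.4)

        class Combo:
            def __call__(self, pts, L):
                return 2.0 * phi1(pts, L) - 0.5 * phi2(pts, L)

            def on_grid(self, grid):
                return GridField(
                    2.0 * phi1.on_grid(grid).values - 0.5 * phi2.on_grid(grid).values,
                    grid,
                )

        combo = pair_fluctuation(X, u0_field, Combo())
        parts = 2.0 * pair_fluctuation(X, u0_field, phi1) - 0.5 * pair_fluctuation(
            X, u0_field, phi2
        )
        assert combo == pytest.approx(parts, abs=1e-12)

    def test_initial_time_variance(self, u0_field, grid32):
        """Replicate variance of <F(0), phi> matches <u0,phi^2> - <u0,phi>^2."""
        rng = np.random.default_rng(55)
        vals = np.array(
            [pair_fluctuation(draw_iid(rng, 500), u0_field, PHI) for _ in range(200)]
        )
        phig = PHI.on_grid(grid32).values
        hd = grid32.h**3
        m1 = float((u0_field.values * phig).sum() * hd)
        m2 = float((u0_field.values * phig**2).sum() * hd)
        target = m2 - m1**2
        se = target * np.sqrt(2.0 / (vals.size - 1))
        assert abs(vals.var(ddof=1) - target) < 3 * se
        assert stats.kstest(vals, stats.norm(0, np.sqrt(target)).cdf).pvalue > 0.01


class TestPredictedVariance:
    def test_constant_observable_gives_zero(self, tables, u0_field):
        T = 0.2
        u_sol = solve_forward(u0_field, tables.Phi_symbol, 1.0, 1, 0.01, T)
        ones = TestFunction(kind="constant")
        dual = solve_dual_backward(u_sol, ones, T, tables.Phi_symbol, 1.0, 1, 0.01)
        total, init, dyn = predicted_variance(u_sol, dual, u0_field, ones, 1.0, T)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_zero_horizon_reduces_to_initial_term(self, tables, u0_field, grid32):
        u_sol = solve_forward(u0_field, tables.Phi_symbol, 1.0, 1, 0.01, 0.05)
        dual = solve_dual_backward(u_sol, PHI, 0.0, tables.Phi_symbol, 1.0, 1, 0.01)
        total, init, dyn = predicted_variance(u_sol, dual, u0_field, PHI, 1.0, 0.0)
        phig = PHI.on_grid(grid32).values
        hd = grid32.h**3
        m1 = float((u0_field.values * phig).sum() * hd)
        m2 = float((u0_field.values * phig**2).sum() * hd)
        assert dyn == 0.0
        assert total == pytest.approx(m2 - m1**2, rel=1e-12)

    def test_free_gaussian_quadrature_oracle(self, grid32, u0_field):
        """kappa = 0: every factor is an explicit Gaussian, so the variance
        can be rebuilt from closed-form heat evolutions on a fine time grid."""
        import itertools

        sigma, T = 1.0, 0.3
        zero = np.zeros((32,) * 3)
        # stride 1: the time-quadrature of the dynamic term must resolve the
        # integrand for a 1e-3 comparison against the closed form
        u_sol = solve_forward(u0_field, zero, sigma, 0, 0.01, T, snapshot_stride=1)
        dual = solve_dual_backward(u_sol, PHI, T, zero, sigma, 0, 0.01, snapshot_stride=1)
        total, _, _ = predicted_variance(u_sol, dual, u0_field, PHI, sigma, T)

        pts = np.stack(grid32.meshes, axis=-1)
        hd = grid32.h**3

        def images(center, var):
            out = np.zeros((32,) * 3)
            for sh in itertools.product((-1, 0, 1), repeat=3):
                dx = pts - np.asarray(center) + np.asarray(sh) * 10.0
                out += np.exp(-np.sum(dx**2, axis=-1) / (2 * var))
            return out

        def grad_sq_T(s):
            # T(s) = amp * exp(-|x-c|^2 / (2 v)), v = w^2 + 2 sigma (T - s)
            v = 1.0 + 2 * sigma * (T - s)
            amp = (1.0 / v) ** 1.5
            grad = np.zeros((32,) * 3 + (3,))
            for sh in itertools.product((-1, 0, 1), repeat=3):
                dx = pts - np.array([1.0, 0, 0]) + np.asarray(sh) * 10.0
                g = amp * np.exp(-np.sum(dx**2, axis=-1) / (2 * v))
                grad = grad + (-dx / v) * g[..., None]
            return np.sum(grad**2, axis=-1)

        s_grid = np.linspace(0.0, T, 61)
        integrand = []
        for s in s_grid:
            u_var = 1.0 + 2 * sigma * s
            u_s = images(0.0, u_var) * (2 * np.pi * u_var) ** -1.5
            integrand.append(float((u_s * grad_sq_T(s)).sum() * hd))
        dyn = 2 * sigma * np.trapezoid(integrand, s_grid)
        T0v = (1.0 / (1.0 + 2 * sigma * T)) ** 1.5 * images(
            (1.0, 0, 0), 1.0 + 2 * sigma * T
        )
        m1 = float((u0_field.values * T0v).sum() * hd)
        m2 = float((u0_field.values * T0v**2).sum() * hd)
        oracle = m2 - m1**2 + dyn
        assert total == pytest.approx(oracle, rel=1e-3)


class TestCltTest:
    def test_calibrated_on_its_null(self):
        rng = np.random.default_rng(77)
        pred = 0.04
        samples = FluctuationSamples(
            t=0.0, phi=PHI, values=rng.normal(0, np.sqrt(pred), 200),
            predicted_variance=pred, predicted_initial_part=pred,
            predicted_dynamic_part=0.0,
        )
        out = clt_test(samples)
        assert out["ks_pvalue"] > 0.01
        assert abs(out["variance_zscore"]) < 3

    def test_degenerate_branch(self):
        samples = FluctuationSamples(
            t=0.0, phi=TestFunction(kind="constant"), values=np.zeros(50),
            predicted_variance=0.0, predicted_initial_part=0.0,
            predicted_dynamic_part=0.0,
        )
        out = clt_test(samples)
        assert out["degenerate"]
        assert out["max_abs_sample"] == 0.0

    def test_requires_thirty_replicates(self):
        samples = FluctuationSamples(
            t=0.0, phi=PHI, values=np.zeros(10), predicted_variance=1.0,
            predicted_initial_part=1.0, predicted_dynamic_part=0.0,
        )
        with pytest.raises(ValueError):
            clt_test(samples)


class TestRateFit:
    def test_fixed_radius_free_particles_scale_inverse_n(self, tables):
        """With eta fixed and kappa = 0 the i.i.d. identity forces slope 1."""
        config = SimulationConfig(
            N=100, kappa=0, sigma=1.0, beta=0.05, eta=0.75, dt=0.01, T=0.02,
            snapshot_stride=2, seed=21, test_mode=True,
        )
        fit = estimate_rate(config, [100, 200, 400, 800], replicas=6, seed=21)
        assert abs(fit.slope - 1.0) < 3 * fit.slope_se

    def test_guards(self, tables):
        config = SimulationConfig(N=64, seed=1)
        with pytest.raises(ValueError):
            estimate_rate(config, [64, 128], replicas=4)
        with pytest.raises(ValueError):
            estimate_rate(config, [64, 128, 256], replicas=1)


class TestLlnProbability:
    def test_zero_threshold_exponent_never_exceeds(self, tables):
        # theta = 0: threshold 1 dwarfs the O(N^-1/2) deviation
        config = SimulationConfig(N=128, T=0.05, dt=0.01, snapshot_stride=5, seed=31)
        ubar = solve_intermediate_pde(config, tables)
        out = lln_probability(config, tables, ubar, theta=0.0, replicas=20)
        assert out["probability"] == 0.0
        assert np.all(out["sup_deviations"] > 0.0)
        assert out["threshold"] == 1.0

    def test_replica_floor(self, tables):
        config = SimulationConfig(N=64, seed=1)
        ubar = solve_intermediate_pde(config, tables)
        with pytest.raises(ValueError):
            lln_probability(config, tables, ubar, theta=0.2, replicas=5)
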