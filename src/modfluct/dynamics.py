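"""Stochastic particle dynamics on the torus.

Two systems are simulated with the Euler--Maruyama scheme:

* the interacting system, in which particle ``i`` feels the pairwise drift
  ``(kappa/N) sum_j grad V^eta(X_i - X_j)`` evaluated from the radial kernel
  tables with the minimum-image convention (the self term contributes exactly
  zero because ``grad V^eta(0) = 0``), and
* the intermediate system of independent particles driven by the precomputed
  mean-field drift ``kappa * (grad V^eta * ubar^eta)(t, x)``, interpolated
  linearly in time between stored PDE snapshots and multilinearly in space.

Both systems can be coupled through shared Brownian increments, which makes
the pathwise distance ``max_i |X_i - Xbar_i|`` a measurable statistic for
mean-field convergence diagnostics.  All randomness flows through a single
``numpy.random.Generator`` so that runs replay bit-exactly under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm as _norm

from .grid import GridField, TorusGrid, interpolate_field, min_image

__all__ = [
    "SimulationConfig",
    "ParticleEnsemble",
    "CoupledEnsembles",
    "BoxOverflowError",
    "sample_initial",
    "drift_interacting",
    "step_euler_maruyama",
    "simulate_interacting",
    "intermediate_drift_fields",
    "simulate_intermediate",
    "simulate_coupled",
    "coupling_statistic",
    "interaction_energy",
]


class BoxOverflowError(ValueError):
    """Initial density has too much mass outside the periodic box."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one particle/PDE run.

    ``eta`` defaults to the moderate coupling ``N**-beta`` (box units).  The
    initial density is an isotropic Gaussian of width ``s0`` wrapped onto the
    torus; ``tail_tol`` bounds the mass the unwrapped Gaussian places outside
    the box (a fidelity guard for comparing with whole-space theory).
    """

    N: int
    d: int = 3
    lam: float = 0.5
    kappa: int = 1
    sigma: float = 1.0
    beta: float = 0.05
    eta: float | None = None
    dt: float = 0.01
    T: float = 0.5
    seed: int = 0
    L: float = 10.0
    n: int = 32
    s0: float = 1.0
    center: tuple[float, ...] | None = None
    snapshot_stride: int = 10
    tail_tol: float = 1e-5
    test_mode: bool = False

    @property
    def eta_value(self) -> float:
        return float(self.N) ** (-self.beta) if self.eta is None else self.eta

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def center_value(self) -> np.ndarray:
        if self.center is None:
            return np.zeros(self.d)
        return np.asarray(self.center, dtype=float)

    def make_grid(self) -> TorusGrid:
        return TorusGrid(L=self.L, n=self.n, d=self.d)

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent generator for a named stream, derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, *stream)))

    @property
    def save_steps(self) -> list[int]:
        steps = list(range(0, self.n_steps + 1, self.snapshot_stride))
        if steps[-1] != self.n_steps:
            steps.append(self.n_steps)
        return steps


@dataclass
class ParticleEnsemble:
    """Positions of N particles on the torus at one instant."""

    X: np.ndarray
    t: float = 0.0

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class CoupledEnsembles:
    """Interacting and intermediate snapshots driven by shared noise."""

    times: np.ndarray
    X_snapshots: list[np.ndarray]
    Xbar_snapshots: list[np.ndarray]
    shared_noise: bool = True
    L: float = 0.0


def wrap(X: np.ndarray, L: float) -> np.ndarray:
    return np.mod(X + L / 2, L) - L / 2


def gaussian_tail_mass(s0: float, L: float, d: int) -> float:
    """Mass of the (unwrapped) isotropic Gaussian outside the box."""
    p_in = 1.0 - 2.0 * _norm.sf(L / 2 / s0)
    return float(1.0 - p_in**d)


def sample_initial(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> ParticleEnsemble:
    """Draw N i.i.d. particles from the wrapped Gaussian initial density."""
    tail = gaussian_tail_mass(config.s0, config.L, config.d)
    if tail > config.tail_tol:
        raise BoxOverflowError(
            f"initial Gaussian places mass {tail:.3g} outside the box "
            f"(tolerance {config.tail_tol:.3g}); enlarge L or shrink s0"
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    X = config.center_value + config.s0 * rng.standard_normal((config.N, config.d))
    return ParticleEnsemble(X=wrap(X, config.L), t=0.0)


def drift_interacting(ensemble: ParticleEnsemble, tables, kappa: int,
                      chunk: int = 256) -> np.ndarray:
    """Pairwise drift ``(kappa/N) sum_j grad V^eta(X_i - X_j)``.

    Displacements use the minimum-image convention; gradients come from the
    radial tables.  The row-chunked evaluation keeps the N x N displacement
    block at a bounded memory footprint.
    """
    X = ensemble.X
    N = ensemble.N
    L = tables.grid.L if tables.grid is not None else None
    out = np.empty_like(X)
    for lo in range(0, N, chunk):
        D = X[lo : lo + chunk, None, :] - X[None, :, :]
        if L is not None:
            D = min_image(D, L)
        G = tables.grad_V(D)
        if not np.all(np.isfinite(G)):
            raise FloatingPointError("non-finite kernel gradient lookup")
        out[lo : lo + chunk] = G.sum(axis=1)
    return (kappa / N) * out


def step_euler_maruyama(X: np.ndarray, drift: np.ndarray, sigma: float, dt: float,
                        L: float, rng: np.random.Generator | None = None,
                        increments: np.ndarray | None = None) -> np.ndarray:
    """One Euler--Maruyama step ``X + drift*dt + sqrt(2 sigma dt) G``, wrapped.

    ``increments`` allows reusing the standard-normal draws of a coupled
    partner system; otherwise they are drawn from ``rng``.
    """
    if increments is None:
        if sigma > 0:
            if rng is None:
                raise ValueError("rng required when sigma > 0 and no increments given")
            increments = rng.standard_normal(X.shape)
        else:
            increments = 0.0
    return wrap(X + drift * dt + np.sqrt(2.0 * sigma * dt) * increments, L)


def simulate_interacting(config: SimulationConfig, tables,
                         rng: np.random.Generator,
                         initial: ParticleEnsemble | None = None):
    """Simulate the interacting system; returns (times, snapshots)."""
    ens = sample_initial(config, rng) if initial is None else initial
    X = ens.X.copy()
    save = set(config.save_steps)
    times, snaps = [], []
    if 0 in save:
        times.append(0.0)
        snaps.append(X.copy())
    for step in range(1, config.n_steps + 1):
        if config.kappa == 0:
            drift = np.zeros_like(X)
        else:
            drift = drift_interacting(ParticleEnsemble(X), tables, config.kappa)
        X = step_euler_maruyama(X, drift, config.sigma, config.dt, config.L, rng)
        if step in save:
            times.append(step * config.dt)
            snaps.append(X.copy())
    return np.asarray(times), snaps


def intermediate_drift_fields(tables, ubar_solution, kappa: int):
    """Precompute the drift field ``kappa * grad V^eta * ubar`` per snapshot.

    Returns (times, list of (d, n, ..., n) arrays).
    """
    grid = ubar_solution.snapshots[0].grid
    kcs = grid.k_components
    fields = []
    for snap in ubar_solution.snapshots:
        uhat = np.fft.fftn(snap.values)
        b = np.stack([
            np.fft.ifftn(1j * kc * tables.V_eta_symbol * uhat).real for kc in kcs
        ])
        fields.append(kappa * b)
    return np.asarray(ubar_solution.times), fields


def _drift_at(positions: np.ndarray, t: float, times: np.ndarray, fields, grid) -> np.ndarray:
    """Evaluate the stored drift field at particle positions and time t."""
    if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
        raise ValueError(f"time {t} outside stored drift snapshots [{times[0]}, {times[-1]}]")
    j = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2))
    w = (t - times[j]) / (times[j + 1] - times[j])
    w = float(np.clip(w, 0.0, 1.0))
    out = np.empty_like(positions)
    for comp in range(positions.shape[1]):
        vals = (1.0 - w) * fields[j][comp] + w * fields[j + 1][comp]
        out[:, comp] = interpolate_field(GridField(vals, grid), positions)
    return out


def simulate_intermediate(config: SimulationConfig, tables, ubar_solution,
                          rng: np.random.Generator,
                          initial: ParticleEnsemble | None = None,
                          increments_log: list | None = None):
    """Simulate the independent intermediate particles; returns (times, snapshots).

    When ``increments_log`` is supplied (a list of per-step standard-normal
    arrays), those increments are consumed instead of drawing fresh ones --
    this realizes the noise coupling with an interacting partner run.
    """
    grid = ubar_solution.snapshots[0].grid
    times_b, fields = intermediate_drift_fields(tables, ubar_solution, config.kappa)
    if times_b[0] > 0.0 or times_b[-1] < config.T - 1e-9:
        raise ValueError("ubar snapshots do not cover the simulation horizon")
    ens = sample_initial(config, rng) if initial is None else initial
    X = ens.X.copy()
    save = set(config.save_steps)
    times, snaps = [], []
    if 0 in save:
        times.append(0.0)
        snaps.append(X.copy())
    for step in range(1, config.n_steps + 1):
        t_prev = (step - 1) * config.dt
        drift = _drift_at(X, t_prev, times_b, fields, grid)
        inc = increments_log[step - 1] if increments_log is not None else None
        X = step_euler_maruyama(X, drift, config.sigma, config.dt, config.L, rng,
                                increments=inc)
        if step in save:
            times.append(step * config.dt)
            snaps.append(X.copy())
    return np.asarray(times), snaps


def simulate_coupled(config: SimulationConfig, tables, ubar_solution,
                     rng: np.random.Generator) -> CoupledEnsembles:
    """Run the interacting and intermediate systems on shared noise.

    Both start from the same initial draw and consume identical Brownian
    increments per step, drawn once in particle-major order.
    """
    grid = ubar_solution.snapshots[0].grid
    times_b, fields = intermediate_drift_fields(tables, ubar_solution, config.kappa)
    ens = sample_initial(config, rng)
    X = ens.X.copy()
    Xbar = ens.X.copy()
    save = set(config.save_steps)
    times, xs, xbs = [], [], []
    if 0 in save:
        times.append(0.0)
        xs.append(X.copy())
        xbs.append(Xbar.copy())
    for step in range(1, config.n_steps + 1):
        t_prev = (step - 1) * config.dt
        G = rng.standard_normal(X.shape) if config.sigma > 0 else np.zeros_like(X)
        dX = drift_interacting(ParticleEnsemble(X), tables, config.kappa)
        dXbar = _drift_at(Xbar, t_prev, times_b, fields, grid)
        X = step_euler_maruyama(X, dX, config.sigma, config.dt, config.L, increments=G)
        Xbar = step_euler_maruyama(Xbar, dXbar, config.sigma, config.dt, config.L,
                                   increments=G)
        if step in save:
            times.append(step * config.dt)
            xs.append(X.copy())
            xbs.append(Xbar.copy())
    return CoupledEnsembles(times=np.asarray(times), X_snapshots=xs,
                            Xbar_snapshots=xbs, shared_noise=True, L=config.L)


def coupling_statistic(coupled: CoupledEnsembles) -> np.ndarray:
    """Per-snapshot ``max_i |X_i - Xbar_i|`` with minimum-image distances."""
    if not coupled.shared_noise:
        raise ValueError("coupling statistic requires shared-noise ensembles")
    out = []
    for X, Xbar in zip(coupled.X_snapshots, coupled.Xbar_snapshots):
        D = min_image(X - Xbar, coupled.L)
        out.append(float(np.linalg.norm(D, axis=1).max()))
    return np.asarray(out)


def interaction_energy(X: np.ndarray, tables, L: float) -> float:
    """Interaction energy ``(1/N^2) sum_{i,j} V^eta(X_i - X_j)``."""
    N = X.shape[0]
    total = 0.0
    for lo in range(0, N, 256):
        D = min_image(X[lo : lo + 256, None, :] - X[None, :, :], L)
        total += float(tables.V(np.linalg.norm(D, axis=-1)).sum())
    return total / N**2
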