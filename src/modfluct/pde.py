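"""Pseudo-spectral solvers for the nonlocal aggregation--diffusion equations.

Three initial/terminal-value problems share one integrating-factor scheme
(exact diffusion factor ``exp(-sigma |k|^2 dt)`` in frequency space, explicit
Heun/RK2 for the transport terms, 2/3-rule dealiasing of quadratic products):

* forward:      ``du/dt = sigma Lap u - kappa div(u (grad K * u))`` with
  ``K = V^eta`` (intermediate equation) or ``K = Phi`` (limit equation);
* linearized forward around a stored solution ``u``:
  ``dh/dt = sigma Lap h - kappa div(h (grad K * u)) - kappa div(u (grad K * h))``;
* dual backward: for terminal data ``phi`` at time ``t``,
  ``-dv/ds - sigma Lap v = kappa (grad K * u) . grad v - kappa grad K * (u grad v)``,
  integrated forward in ``tau = t - s``.

The transport terms have zero mean mode, so total mass (respectively the mean
of ``v``) is conserved exactly by the scheme.  Positivity is not enforced;
each snapshot records the field minimum and a blow-up flag is raised when the
sup-norm exceeds a configurable ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridField, TorusGrid, min_image

__all__ = [
    "PDESolution",
    "TestFunction",
    "solve_forward",
    "solve_linearized_forward",
    "solve_dual_backward",
]


@dataclass
class PDESolution:
    """Time-indexed snapshots of one PDE solve."""

    times: np.ndarray
    snapshots: list[GridField]
    mass_series: np.ndarray
    min_series: np.ndarray
    equation_tag: str
    blew_up: bool = False

    def field_at(self, t: float) -> GridField:
        """Linear interpolation in time between stored snapshots."""
        times = self.times
        if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
            raise ValueError(f"time {t} outside stored snapshots [{times[0]}, {times[-1]}]")
        if len(times) == 1:
            return GridField(self.snapshots[0].values.copy(), self.snapshots[0].grid,
                             time_tag=float(times[0]))
        j = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2))
        w = float(np.clip((t - times[j]) / (times[j + 1] - times[j]), 0.0, 1.0))
        vals = (1.0 - w) * self.snapshots[j].values + w * self.snapshots[j + 1].values
        return GridField(vals, self.snapshots[0].grid, time_tag=t)


@dataclass(frozen=True)
class TestFunction:
    """Smooth observable paired against measures and fluctuation fields.

    ``gaussian_bump`` is an isotropic Gaussian (standing in for a Schwartz
    function); ``coordinate_window`` is a compactly supported C-infinity bump
    in the first coordinate; ``constant`` is the degenerate observable used
    by mass-cancellation tests.  All are evaluated with the minimum-image
    convention so grid samples and particle evaluations agree on the torus.
    """

    __test__ = False  # name collides with pytest's collection heuristic

    kind: str = "gaussian_bump"
    center: tuple[float, ...] | float = 0.0
    width: float = 1.0
    amplitude: float = 1.0

    def __call__(self, points: np.ndarray, L: float) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        d = points.shape[-1]
        if self.kind == "constant":
            return np.full(points.shape[:-1], self.amplitude)
        center = np.broadcast_to(np.asarray(self.center, dtype=float), (d,))
        dx = min_image(points - center, L)
        if self.kind == "gaussian_bump":
            r2 = np.sum(dx**2, axis=-1)
            return self.amplitude * np.exp(-r2 / (2.0 * self.width**2))
        if self.kind == "coordinate_window":
            s = dx[..., 0] / self.width
            out = np.zeros(s.shape)
            inside = np.abs(s) < 1.0
            out[inside] = np.exp(1.0 - 1.0 / (1.0 - s[inside] ** 2))
            return self.amplitude * out
        raise ValueError(f"unknown test-function kind {self.kind!r}")

    def on_grid(self, grid: TorusGrid) -> GridField:
        pts = np.stack(grid.meshes, axis=-1)
        return GridField(self(pts, grid.L), grid)


def _grad_conv(uhat: np.ndarray, symbol: np.ndarray, grid: TorusGrid) -> list[np.ndarray]:
    """Components of grad K * u from the spectral representation of u."""
    return [np.fft.ifftn(1j * kc * symbol * uhat).real for kc in grid.k_components]


def _forward_rhs(uhat, symbol, kappa, grid, mask):
    """Dealiased transport term -kappa div(u (grad K * u)) in frequency space."""
    um = uhat * mask
    u_r = np.fft.ifftn(um).real
    vel = _grad_conv(um, symbol, grid)
    out = np.zeros_like(uhat)
    for kc, v in zip(grid.k_components, vel):
        out -= kappa * 1j * kc * (np.fft.fftn(u_r * v) * mask)
    return out


def _march(uhat0, rhs, sigma, grid, dt, n_steps, save_steps, tag, sup_ceiling):
    """Integrating-factor Heun loop shared by all three solvers.

    ``rhs(uhat, step_time)`` returns the non-stiff part in frequency space.
    """
    E = np.exp(-sigma * grid.k_sq * dt)
    uhat = uhat0.copy()
    hd = grid.h**grid.d
    times, snaps, mass, mins = [], [], [], []

    def _save(step):
        vals = np.fft.ifftn(uhat).real
        times.append(step * dt)
        snaps.append(GridField(vals, grid, time_tag=step * dt))
        mass.append(float(vals.sum() * hd))
        mins.append(float(vals.min()))

    save = set(save_steps)
    blew_up = False
    if 0 in save:
        _save(0)
    for step in range(1, n_steps + 1):
        t0 = (step - 1) * dt
        a1 = rhs(uhat, t0)
        upred = E * (uhat + dt * a1)
        a2 = rhs(upred, t0 + dt)
        uhat = E * uhat + 0.5 * dt * (E * a1 + a2)
        if step in save:
            _save(step)
            if abs(snaps[-1].values).max() > sup_ceiling:
                blew_up = True
                break
    return PDESolution(
        times=np.asarray(times), snapshots=snaps, mass_series=np.asarray(mass),
        min_series=np.asarray(mins), equation_tag=tag, blew_up=blew_up,
    )


def _save_steps(n_steps: int, stride: int) -> list[int]:
    steps = list(range(0, n_steps + 1, stride))
    if steps[-1] != n_steps:
        steps.append(n_steps)
    return steps


def solve_forward(u0: GridField, kernel_symbol: np.ndarray, sigma: float,
                  kappa: int, dt: float, T: float, snapshot_stride: int = 10,
                  sup_ceiling: float = 1e6, tag: str = "intermediate") -> PDESolution:
    """Solve the nonlocal diffusion equation forward from density ``u0``."""
    grid = u0.grid
    if np.any(u0.values < -1e-10):
        raise ValueError("initial density must be nonnegative")
    n_steps = int(round(T / dt))
    mask = grid.dealias_mask
    rhs = lambda uhat, t: _forward_rhs(uhat, kernel_symbol, kappa, grid, mask)
    return _march(np.fft.fftn(u0.values), rhs, sigma, grid, dt, n_steps,
                  _save_steps(n_steps, snapshot_stride), tag, sup_ceiling)


def solve_linearized_forward(u_solution: PDESolution, h0: GridField,
                             kernel_symbol: np.ndarray, sigma: float, kappa: int,
                             dt: float, T: float, snapshot_stride: int = 10,
                             sup_ceiling: float = 1e8) -> PDESolution:
    """Solve the equation linearized around a stored solution ``u``."""
    grid = h0.grid
    n_steps = int(round(T / dt))
    mask = grid.dealias_mask

    def rhs(hhat, t):
        u = u_solution.field_at(t).values
        uhat = np.fft.fftn(u) * mask
        hm = hhat * mask
        h_r = np.fft.ifftn(hm).real
        u_r = np.fft.ifftn(uhat).real
        vel_u = _grad_conv(uhat, kernel_symbol, grid)
        vel_h = _grad_conv(hm, kernel_symbol, grid)
        out = np.zeros_like(hhat)
        for kc, vu, vh in zip(grid.k_components, vel_u, vel_h):
            out -= kappa * 1j * kc * (np.fft.fftn(h_r * vu + u_r * vh) * mask)
        return out

    return _march(np.fft.fftn(h0.values), rhs, sigma, grid, dt, n_steps,
                  _save_steps(n_steps, snapshot_stride), "linearized", sup_ceiling)


def solve_dual_backward(u_solution: PDESolution, phi, t: float,
                        kernel_symbol: np.ndarray, sigma: float, kappa: int,
                        dt: float, snapshot_stride: int = 10,
                        sup_ceiling: float = 1e8) -> PDESolution:
    """Solve the dual backward linearized problem with terminal data ``phi``.

    Substituting ``tau = t - s`` turns the backward problem into the forward
    equation ``dv/dtau = sigma Lap v + kappa (grad K * u(s)) . grad v
    - kappa grad K . (u(s) grad v)`` which is integrated with the same
    integrating-factor scheme.  Snapshot times are reported in ``s`` and
    sorted increasingly, so ``field_at(t)`` returns ``phi`` exactly.
    """
    grid = u_solution.snapshots[0].grid
    if u_solution.times[0] > 1e-12 or u_solution.times[-1] < t - 1e-9:
        raise ValueError("u snapshots do not cover [0, t]")
    phi_field = phi.on_grid(grid) if isinstance(phi, TestFunction) else phi
    n_steps = int(round(t / dt))
    mask = grid.dealias_mask

    def rhs(vhat, tau):
        s = max(t - tau, 0.0)
        u = u_solution.field_at(s).values
        uhat = np.fft.fftn(u) * mask
        u_r = np.fft.ifftn(uhat).real
        vm = vhat * mask
        grad_v = [np.fft.ifftn(1j * kc * vm).real for kc in grid.k_components]
        b = _grad_conv(uhat, kernel_symbol, grid)
        advect = np.zeros_like(u_r)
        out = np.zeros_like(vhat)
        for kc, bj, gj in zip(grid.k_components, b, grad_v):
            advect += bj * gj
            # grad K * (u grad v) contracted over components
            out -= kappa * 1j * kc * kernel_symbol * (np.fft.fftn(u_r * gj) * mask)
        out += kappa * np.fft.fftn(advect) * mask
        return out

    sol = _march(np.fft.fftn(phi_field.values), rhs, sigma, grid, dt, n_steps,
                 _save_steps(n_steps, snapshot_stride), "dual_backward", sup_ceiling)
    # reindex from tau to s = t - tau, ascending in s; terminal slot is phi itself
    s_times = t - sol.times
    order = np.argsort(s_times)
    snaps = [sol.snapshots[j] for j in order]
    for s, snap in zip(s_times[order], snaps):
        snap.time_tag = float(s)
    snaps[-1] = GridField(phi_field.values.copy(), grid, time_tag=float(t))
    return PDESolution(
        times=s_times[order], snapshots=snaps,
        mass_series=sol.mass_series[order], min_series=sol.min_series[order],
        equation_tag="dual_backward", blew_up=sol.blew_up,
    )
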