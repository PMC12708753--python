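"""Periodic torus grids and fields.

All continuum objects live on the periodic box ``[-L/2, L/2)^d``.  Fields are
node-centered real arrays; convolutions are evaluated spectrally with kernels
given by their continuum Fourier symbols sampled on the discrete wavenumber
lattice ``k = 2*pi*m/L``.  With the numpy FFT convention the Fourier
coefficients of a field are ``fftn(v)/n**d``, so convolution with a kernel of
continuum symbol ``K(k)`` is simply ``ifftn(fftn(v) * K)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

__all__ = [
    "TorusGrid",
    "GridField",
    "min_image",
    "spectral_convolve",
    "deposit_particles",
    "interpolate_field",
    "norms",
    "gradient",
    "wrapped_gaussian",
]


def min_image(dx: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image representative of a displacement on the torus."""
    return dx - L * np.round(dx / L)


@dataclass
class TorusGrid:
    """Uniform node-centered grid on the periodic box ``[-L/2, L/2)^d``."""

    L: float = 10.0
    n: int = 32
    d: int = 3

    def __post_init__(self) -> None:
        if self.n < 2 or (self.n & (self.n - 1)) != 0:
            raise ValueError(f"n must be a power of two, got {self.n}")
        if self.d < 1:
            raise ValueError("d must be positive")
        if self.d * np.log2(self.n) > 48:
            raise ValueError("grid too large: d*log2(n) > 48")

    @property
    def h(self) -> float:
        return self.L / self.n

    @cached_property
    def axis(self) -> np.ndarray:
        """Node coordinates along one axis."""
        return -self.L / 2 + self.h * np.arange(self.n)

    @cached_property
    def k_axis(self) -> np.ndarray:
        return 2 * np.pi * np.fft.fftfreq(self.n, d=self.h)

    @cached_property
    def k_components(self) -> list[np.ndarray]:
        """Broadcastable wavenumber component arrays, one per dimension."""
        out = []
        for j in range(self.d):
            shape = [1] * self.d
            shape[j] = self.n
            out.append(self.k_axis.reshape(shape))
        return out

    @cached_property
    def k_sq(self) -> np.ndarray:
        ksq = np.zeros((self.n,) * self.d)
        for kc in self.k_components:
            ksq = ksq + kc**2
        return ksq

    @cached_property
    def k_norm(self) -> np.ndarray:
        return np.sqrt(self.k_sq)

    @cached_property
    def dealias_mask(self) -> np.ndarray:
        """2/3-rule mask for quadratic nonlinearities."""
        k_max = np.abs(self.k_axis).max()
        mask = np.ones((self.n,) * self.d, dtype=bool)
        for kc in self.k_components:
            mask &= np.abs(kc) <= (2.0 / 3.0) * k_max
        return mask

    @cached_property
    def meshes(self) -> list[np.ndarray]:
        return list(np.meshgrid(*([self.axis] * self.d), indexing="ij"))

    def same_as(self, other: "TorusGrid") -> bool:
        return self.L == other.L and self.n == other.n and self.d == other.d


@dataclass
class GridField:
    """Scalar field sampled on a :class:`TorusGrid`."""

    values: np.ndarray
    grid: TorusGrid
    time_tag: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n,) * self.grid.d:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid "
                f"{(self.grid.n,) * self.grid.d}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.grid.h**self.grid.d)

    def with_values(self, values: np.ndarray, time_tag: float | None = None) -> "GridField":
        return GridField(values, self.grid, self.time_tag if time_tag is None else time_tag)


def spectral_convolve(field: GridField, symbol: np.ndarray) -> GridField:
    """Convolve a field with a kernel given by its continuum Fourier symbol."""
    symbol = np.asarray(symbol)
    if symbol.shape != field.values.shape:
        raise ValueError("symbol shape does not match field grid")
    out = np.fft.ifftn(np.fft.fftn(field.values) * symbol).real
    return field.with_values(out)


def _cic_weights(positions: np.ndarray, grid: TorusGrid):
    """Base indices and fractional offsets for cloud-in-cell assignment."""
    s = (positions + grid.L / 2) / grid.h
    i0 = np.floor(s).astype(np.int64)
    frac = s - i0
    return i0, frac


def deposit_particles(positions: np.ndarray, grid: TorusGrid, scheme: str = "CIC",
                      time_tag: float = 0.0) -> GridField:
    """Deposit particle positions onto the grid as a probability density.

    Each particle carries total weight ``1/(N*h^d)`` so that the resulting
    field integrates to exactly one.  ``NGP`` assigns to the nearest node,
    ``CIC`` splits the weight multilinearly over the 2^d surrounding nodes.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != grid.d:
        raise ValueError(f"positions must be (N, {grid.d})")
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite particle positions")
    N = positions.shape[0]
    values = np.zeros((grid.n,) * grid.d)
    w0 = 1.0 / (N * grid.h**grid.d)
    scheme = scheme.upper()
    if scheme == "NGP":
        s = (positions + grid.L / 2) / grid.h
        idx = np.mod(np.round(s).astype(np.int64), grid.n)
        np.add.at(values, tuple(idx.T), w0)
    elif scheme == "CIC":
        i0, frac = _cic_weights(positions, grid)
        for corner in itertools.product((0, 1), repeat=grid.d):
            idx = np.mod(i0 + np.array(corner), grid.n)
            w = w0 * np.ones(N)
            for j, c in enumerate(corner):
                w = w * (frac[:, j] if c else 1.0 - frac[:, j])
            np.add.at(values, tuple(idx.T), w)
    else:
        raise ValueError(f"unknown deposition scheme {scheme!r}")
    return GridField(values, grid, time_tag)


def interpolate_field(field: GridField, positions: np.ndarray) -> np.ndarray:
    """Multilinear (CIC) interpolation of a grid field at particle positions."""
    grid = field.grid
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != grid.d:
        raise ValueError(f"positions must be (N, {grid.d})")
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite particle positions")
    i0, frac = _cic_weights(positions, grid)
    out = np.zeros(positions.shape[0])
    for corner in itertools.product((0, 1), repeat=grid.d):
        idx = np.mod(i0 + np.array(corner), grid.n)
        w = np.ones(positions.shape[0])
        for j, c in enumerate(corner):
            w = w * (frac[:, j] if c else 1.0 - frac[:, j])
        out += w * field.values[tuple(idx.T)]
    return out


def gradient(field: GridField) -> list[GridField]:
    """Spectral gradient, one field per coordinate direction."""
    vhat = np.fft.fftn(field.values)
    return [
        field.with_values(np.fft.ifftn(1j * kc * vhat).real)
        for kc in field.grid.k_components
    ]


def norms(field: GridField) -> dict[str, float]:
    """L1, L2, Linf norms and the H1 seminorm (spectral derivative)."""
    g = field.grid
    hd = g.h**g.d
    v = field.values
    vhat = np.fft.fftn(v)
    h1_sq = hd / g.n**g.d * float(np.sum(g.k_sq * np.abs(vhat) ** 2))
    return {
        "l1": float(hd * np.abs(v).sum()),
        "l2": float(np.sqrt(hd * np.sum(v**2))),
        "h1_semi": float(np.sqrt(h1_sq)),
        "linf": float(np.abs(v).max()),
    }


def wrapped_gaussian(grid: TorusGrid, center: np.ndarray | float = 0.0,
                     width: float = 1.0, normalize: bool = True,
                     images: int = 1) -> GridField:
    """Isotropic Gaussian density periodized over the box.

    Image shifts up to ``images`` boxes per dimension are summed; for
    ``width <= L/4`` a single layer of images is accurate to ~1e-12.  With
    ``normalize`` the discrete mass is rescaled to exactly one.
    """
    center = np.broadcast_to(np.asarray(center, dtype=float), (grid.d,))
    v = np.zeros((grid.n,) * grid.d)
    norm_const = (2 * np.pi * width**2) ** (-grid.d / 2)
    for shift in itertools.product(range(-images, images + 1), repeat=grid.d):
        r2 = np.zeros_like(v)
        for j, m in enumerate(grid.meshes):
            r2 = r2 + (m - center[j] + shift[j] * grid.L) ** 2
        v += np.exp(-r2 / (2 * width**2))
    v *= norm_const
    if normalize:
        v /= v.sum() * grid.h**grid.d
    return GridField(v, grid)
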