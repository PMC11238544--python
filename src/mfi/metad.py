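"""Metadynamics bias: hill deposition and grid evaluation.

The history-dependent bias is a sum of separable (diagonal) Gaussian kernels

    V(s) = sum_i w_i exp(-sum_a wrap(s - c_i)_a^2 / (2 sigma_{i,a}^2))

deposited every ``pace`` steps.  In the well-tempered variant the deposited
height shrinks as ``w0 * exp(-V(s_now) / ((gamma - 1) kT))`` where ``V`` is
the bias accumulated *before* the new deposit, evaluated at the deposit point
(the convention used by the common MD plugins).  Plain metadynamics is the
``gamma -> inf`` limit (constant heights).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import Grid, ScalarField, VectorField, wrap_displacement

__all__ = [
    "Hill",
    "HillsLog",
    "MetaDParams",
    "deposit_hill",
    "bias_at",
    "bias_on_grid",
    "bias_gradient_on_grid",
    "BiasState",
]


@dataclass(frozen=True)
class Hill:
    center: tuple
    sigma: tuple
    height: float
    time: float


@dataclass
class MetaDParams:
    """Hill-deposition parameters.

    height: initial hill height w0 (energy units, > 0)
    sigma: per-axis Gaussian width
    pace: integration steps between deposits (>= 1)
    bias_factor: gamma > 1 for well-tempered; None for plain metadynamics
    """

    height: float
    sigma: tuple
    pace: int
    bias_factor: float | None = None

    def __post_init__(self):
        self.sigma = tuple(float(s) for s in np.atleast_1d(self.sigma))
        if self.height <= 0:
            raise ValueError("initial hill height must be > 0")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("hill widths must be > 0")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if self.bias_factor is not None and not self.bias_factor > 1:
            raise ValueError("bias_factor must be > 1 (or None for plain MetaD)")


@dataclass
class HillsLog:
    """Time-ordered deposited hills plus tempering metadata.

    Stored columnar: ``centers (n, ndim)``, ``sigmas (n, ndim)``,
    ``heights (n,)``, ``times (n,)``.  ``bias_factor`` is None for plain
    metadynamics.  ``pace_time`` is the time between deposits (tau).
    """

    ndim: int
    centers: np.ndarray
    sigmas: np.ndarray
    heights: np.ndarray
    times: np.ndarray
    bias_factor: float | None = None
    kT: float = 1.0
    pace_time: float | None = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, self.ndim)
        self.sigmas = np.asarray(self.sigmas, dtype=float).reshape(-1, self.ndim)
        self.heights = np.asarray(self.heights, dtype=float).ravel()
        self.times = np.asarray(self.times, dtype=float).ravel()
        n = len(self.times)
        if not (len(self.centers) == len(self.sigmas) == len(self.heights) == n):
            raise ValueError("hill columns must have equal length")
        if n and np.any(np.diff(self.times) <= 0):
            raise ValueError("hill times must be strictly increasing")
        if np.any(self.sigmas <= 0):
            raise ValueError("hill widths must be > 0")
        if np.any(self.heights < 0):
            raise ValueError("hill heights must be nonnegative")
        if self.bias_factor is not None and not self.bias_factor > 1:
            raise ValueError("bias_factor must be > 1 when present")

    @classmethod
    def empty(cls, ndim, bias_factor=None, kT=1.0, pace_time=None) -> "HillsLog":
        z = np.zeros((0, ndim))
        return cls(ndim, z, z.copy(), np.zeros(0), np.zeros(0), bias_factor, kT, pace_time)

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        for k in range(len(self)):
            yield Hill(tuple(self.centers[k]), tuple(self.sigmas[k]), float(self.heights[k]), float(self.times[k]))

    def _upto(self, upto_time):
        if upto_time is None:
            return len(self)
        return int(np.searchsorted(self.times, upto_time, side="right"))


def bias_at(log: HillsLog, s, grid: Grid | None = None, upto_time=None) -> float | np.ndarray:
    """Bias value at point(s) ``s`` from hills with time <= upto_time."""
    n = log._upto(upto_time)
    pts = np.atleast_2d(np.asarray(s, dtype=float).reshape(-1, log.ndim))
    v = np.zeros(len(pts))
    for k in range(n):
        d = _wrapped_diff(pts, log.centers[k], grid)
        v += log.heights[k] * np.exp(-0.5 * np.sum((d / log.sigmas[k]) ** 2, axis=1))
    arr = np.asarray(s, dtype=float)
    return float(v[0]) if arr.ndim <= 1 else v


def _wrapped_diff(pts, center, grid):
    d = pts - center
    if grid is not None:
        for ax, p in enumerate(grid.period):
            if p is not None:
                d[:, ax] -= p * np.round(d[:, ax] / p)
    return d


def deposit_hill(log: HillsLog, s_now, params: MetaDParams, time: float, grid: Grid | None = None) -> HillsLog:
    """Append a hill at ``s_now``; well-tempered height uses the current bias."""
    s_now = np.asarray(s_now, dtype=float).reshape(log.ndim)
    if params.bias_factor is None:
        h = params.height
    else:
        v_cur = bias_at(log, s_now, grid=grid)
        h = params.height * np.exp(-v_cur / ((params.bias_factor - 1.0) * log.kT))
    return HillsLog(
        log.ndim,
        np.vstack([log.centers, s_now[None, :]]),
        np.vstack([log.sigmas, np.asarray(params.sigma, dtype=float)[None, :]]),
        np.append(log.heights, h),
        np.append(log.times, time),
        log.bias_factor,
        log.kT,
        log.pace_time,
    )


class BiasState:
    """Running bias value and gradient fields, updated hill-by-hill.

    Adding hills one at a time yields fields identical (to ~1e-12) to a batch
    evaluation; this is the streaming path used when walking time windows.
    The gradient convention is +dV/ds (consumers subtract it from the kernel
    force term).
    """

    def __init__(self, grid: Grid):
        self.grid = grid
        self.value = grid.zeros()
        self.grad = tuple(grid.zeros() for _ in range(grid.ndim))
        self._meshes = grid.meshes()

    def add_hill(self, center, sigma, height) -> None:
        if height == 0.0:
            return
        center = np.atleast_1d(np.asarray(center, dtype=float))
        sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        d = []
        expo = np.zeros(self.grid.shape)
        for a in range(self.grid.ndim):
            da = self._meshes[a] - center[a]
            p = self.grid.period[a]
            if p is not None:
                da = da - p * np.round(da / p)
            d.append(da)
            expo += (da / sigma[a]) ** 2
        e = height * np.exp(-0.5 * expo)
        self.value += e
        for a in range(self.grid.ndim):
            # dV/ds_a of the Gaussian kernel
            g = self.grad[a]
            g -= d[a] / sigma[a] ** 2 * e

    def snapshot(self) -> tuple[ScalarField, VectorField]:
        return (
            ScalarField(self.grid, self.value.copy()),
            VectorField(self.grid, tuple(g.copy() for g in self.grad)),
        )


def bias_on_grid(log: HillsLog, grid: Grid, upto_time=None) -> ScalarField:
    """Accumulated bias V(s) on the grid from hills with time <= upto_time."""
    st = BiasState(grid)
    for k in range(log._upto(upto_time)):
        st.add_hill(log.centers[k], log.sigmas[k], log.heights[k])
    return ScalarField(grid, st.value)


def bias_gradient_on_grid(log: HillsLog, grid: Grid, upto_time=None) -> VectorField:
    """+dV/ds on the grid from hills with time <= upto_time."""
    st = BiasState(grid)
    for k in range(log._upto(upto_time)):
        st.add_hill(log.centers[k], log.sigmas[k], log.heights[k])
    return VectorField(grid, st.grad)
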