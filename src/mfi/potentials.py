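"""Closed-form potentials and static biases with exact gradients.

These serve two roles: ground-truth free-energy surfaces for the bundled
Langevin toy systems (so reconstructions can be scored against an exact
reference), and static bias building blocks (harmonic restraints, walls)
that can be combined with metadynamics.

All potentials are pure functions of the CV vector: ``value`` and
``gradient`` are deterministic and safe under concurrent evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, ScalarField, VectorField, wrap_displacement

__all__ = [
    "Potential",
    "Polynomial2D",
    "Multiwell1D",
    "HarmonicBias",
    "WallBias",
    "builtin_potential",
    "reference_fes",
    "DOUBLEWELL_2D_COEFFS",
]


class Potential:
    """Base class: a differentiable scalar function of the CV vector."""

    ndim: int = 1

    def value(self, s) -> np.ndarray | float:
        raise NotImplementedError

    def gradient(self, s) -> np.ndarray:
        raise NotImplementedError

    # -- grid helpers -------------------------------------------------
    def value_on_grid(self, grid: Grid) -> ScalarField:
        pts = grid.nodes()
        return ScalarField(grid, np.asarray(self.value(pts)).reshape(grid.shape))

    def gradient_on_grid(self, grid: Grid) -> VectorField:
        g = np.asarray(self.gradient(grid.nodes()))
        return VectorField(grid, tuple(g[:, a].reshape(grid.shape) for a in range(grid.ndim)))


def _pts(s, ndim):
    """Coerce input to (N, ndim); remember whether a single point was given."""
    a = np.asarray(s, dtype=float)
    single = a.ndim <= 1
    if ndim == 1 and a.ndim == 0:
        a = a[None]
    pts = np.atleast_2d(a) if a.ndim <= 1 else a.reshape(-1, ndim)
    if ndim == 1 and pts.shape[1] != 1:
        pts = pts.reshape(-1, 1)
    if pts.shape[1] != ndim:
        raise ValueError(f"expected {ndim}-vector CV points")
    return pts, single


@dataclass(frozen=True)
class Polynomial2D(Potential):
    """2D polynomial: sum of ``c * s1**i * s2**j`` terms keyed by ``(i, j)``."""

    coefficients: dict

    @property
    def ndim(self) -> int:
        return 2

    def value(self, s):
        pts, single = _pts(s, 2)
        x, y = pts[:, 0], pts[:, 1]
        v = np.zeros(len(pts))
        for (i, j), c in self.coefficients.items():
            v += c * x**i * y**j
        return float(v[0]) if single else v

    def gradient(self, s):
        pts, single = _pts(s, 2)
        x, y = pts[:, 0], pts[:, 1]
        gx = np.zeros(len(pts))
        gy = np.zeros(len(pts))
        for (i, j), c in self.coefficients.items():
            if i > 0:
                gx += c * i * x ** (i - 1) * y**j
            if j > 0:
                gy += c * j * x**i * y ** (j - 1)
        g = np.stack([gx, gy], axis=1)
        return g[0] if single else g


@dataclass(frozen=True)
class Multiwell1D(Potential):
    """1D potential: Gaussian wells plus centered polynomial terms.

    ``wells`` is a sequence of ``(depth, center, width)`` triples contributing
    ``-depth * exp(-(s-center)^2 / (2 width^2))``; ``poly_terms`` is a sequence
    of ``(coef, center, power)`` contributing ``coef * (s-center)**power``.
    A quartic double well is ``poly_terms=[(1, 0, 4), (-2, 0, 2)]``.
    """

    wells: tuple = ()
    poly_terms: tuple = ()
    bounds: tuple = (-1.5, 1.5)

    @property
    def ndim(self) -> int:
        return 1

    def value(self, s):
        pts, single = _pts(s, 1)
        x = pts[:, 0]
        v = np.zeros(len(x))
        for depth, c, w in self.wells:
            v -= depth * np.exp(-((x - c) ** 2) / (2 * w**2))
        for c0, cen, p in self.poly_terms:
            v += c0 * (x - cen) ** p
        return float(v[0]) if single else v

    def gradient(self, s):
        pts, single = _pts(s, 1)
        x = pts[:, 0]
        g = np.zeros(len(x))
        for depth, c, w in self.wells:
            g += depth * (x - c) / w**2 * np.exp(-((x - c) ** 2) / (2 * w**2))
        for c0, cen, p in self.poly_terms:
            if p > 0:
                g += c0 * p * (x - cen) ** (p - 1)
        out = g[:, None]
        return out[0] if single else out


@dataclass(frozen=True)
class HarmonicBias(Potential):
    """Harmonic restraint ``sum_a 0.5 kappa_a (s_a - center_a)^2``.

    On periodic axes (pass ``grid``) the displacement uses the minimum image.
    """

    center: tuple
    kappa: tuple
    grid: Grid | None = None

    def __post_init__(self):
        c = tuple(float(v) for v in np.atleast_1d(self.center))
        k = np.atleast_1d(np.asarray(self.kappa, dtype=float)).ravel()
        if k.size == 1 and len(c) > 1:
            k = np.full(len(c), k[0])
        if k.size != len(c):
            raise ValueError("kappa must be scalar or match center length")
        if np.any(k < 0):
            raise ValueError("kappa must be nonnegative")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "kappa", tuple(float(v) for v in k))

    @property
    def ndim(self) -> int:
        return len(self.center)

    def _disp(self, pts):
        if self.grid is not None:
            return wrap_displacement(pts, np.asarray(self.center), self.grid).reshape(pts.shape)
        return pts - np.asarray(self.center)

    def value(self, s):
        pts, single = _pts(s, self.ndim)
        d = self._disp(pts)
        v = 0.5 * (np.asarray(self.kappa) * d**2).sum(axis=1)
        return float(v[0]) if single else v

    def gradient(self, s):
        pts, single = _pts(s, self.ndim)
        g = np.asarray(self.kappa) * self._disp(pts)
        return g[0] if single else g


@dataclass(frozen=True)
class WallBias(Potential):
    """One-sided restraining wall ``kappa * max(0, ±(s_axis - threshold))^exponent``.

    Zero value and gradient on the allowed side.  ``side`` is ``"upper"``
    (restrains s > threshold) or ``"lower"``.
    """

    axis: int = 0
    threshold: float = 0.0
    side: str = "upper"
    kappa: float = 1.0
    exponent: int = 2
    ndim_: int = 1

    def __post_init__(self):
        if self.side not in ("upper", "lower"):
            raise ValueError("side must be 'upper' or 'lower'")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")

    @property
    def ndim(self) -> int:
        return self.ndim_

    def _excess(self, pts):
        x = pts[:, self.axis]
        return np.maximum(0.0, x - self.threshold) if self.side == "upper" else np.maximum(0.0, self.threshold - x)

    def value(self, s):
        pts, single = _pts(s, self.ndim)
        v = self.kappa * self._excess(pts) ** self.exponent
        return float(v[0]) if single else v

    def gradient(self, s):
        pts, single = _pts(s, self.ndim)
        sign = 1.0 if self.side == "upper" else -1.0
        d = self._excess(pts)
        g = np.zeros_like(pts)
        g[:, self.axis] = sign * self.kappa * self.exponent * d ** (self.exponent - 1)
        return g[0] if single else g


# ---------------------------------------------------------------------------
# built-ins
# ---------------------------------------------------------------------------

# Two-dimensional double-well model potential widely used as an enhanced
# sampling benchmark; keys are (power of s1, power of s2).
DOUBLEWELL_2D_COEFFS = {
    (4, 0): 1.35,
    (3, 1): 1.90,
    (2, 2): 3.93,
    (2, 0): -6.44,
    (1, 3): -1.90,
    (1, 1): 5.59,
    (1, 0): 1.33,
    (0, 4): 1.35,
    (0, 2): -5.56,
    (0, 1): 0.90,
    (0, 0): 18.59,
}

# Default 1D multiwell profile on [-0.2, 1.2]: several interconverting basins
# below s = 0.5 plus one metastable state near s = 0.8, confined by a steep
# polynomial envelope.
_MULTIWELL_1D_WELLS = (
    (4.0, 0.05, 0.06),
    (3.0, 0.20, 0.06),
    (4.5, 0.32, 0.06),
    (3.5, 0.45, 0.06),
    (2.5, 0.80, 0.07),
)
_MULTIWELL_1D_POLY = ((60.0, 0.5, 8),)

_BUILTINS = {
    "doublewell_2d": lambda: Polynomial2D(dict(DOUBLEWELL_2D_COEFFS)),
    "multiwell_1d": lambda: Multiwell1D(
        wells=_MULTIWELL_1D_WELLS, poly_terms=_MULTIWELL_1D_POLY, bounds=(-0.2, 1.2)
    ),
    "quartic_doublewell_1d": lambda: Multiwell1D(
        poly_terms=((1.0, 0.0, 4), (-2.0, 0.0, 2)), bounds=(-1.8, 1.8)
    ),
}


def builtin_potential(name: str) -> Potential:
    """Return a named built-in potential (see ``_BUILTINS`` keys)."""
    try:
        return _BUILTINS[name]()
    except KeyError:
        raise KeyError(
            f"unknown potential {name!r}; available: {sorted(_BUILTINS)}"
        ) from None


def reference_fes(potential: Potential, grid: Grid) -> ScalarField:
    """Potential evaluated on every node, gauge-shifted so min over grid is 0."""
    f = potential.value_on_grid(grid)
    return f.shifted_to_zero_min()
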