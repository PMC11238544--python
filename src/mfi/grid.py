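"""Collective-variable space discretization and field/trajectory containers.

A :class:`Grid` is a rectilinear, node-centered lattice over a 1- or
2-dimensional CV domain.  On an aperiodic axis the ``nbins`` nodes include
both bounds (spacing ``(max - min)/(nbins - 1)``).  On a periodic axis the
domain is half-open ``[min, max)``: node 0 sits at ``min``, there is no node
at ``max``, and the period is ``max - min``.

All fields produced by this package (densities, forces, free energies,
error maps) live on these nodes, stored with axis 0 = first CV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "ScalarField",
    "VectorField",
    "CVTrajectory",
    "make_grid",
    "wrap_displacement",
    "wrap_into_domain",
    "write_fields_txt",
    "read_fields_txt",
    "save_fields_npz",
    "load_fields_npz",
]

MIN_BINS = 8


def _as_axis_tuple(x, ndim, cast):
    """Normalize a scalar or per-axis sequence to an ndim tuple."""
    if np.isscalar(x) or isinstance(x, bool):
        return tuple(cast(x) for _ in range(ndim))
    t = tuple(cast(v) for v in x)
    if len(t) != ndim:
        raise ValueError(f"expected {ndim} per-axis values, got {len(t)}")
    return t


@dataclass(frozen=True)
class Grid:
    """Rectilinear node-centered lattice over the CV domain."""

    bounds: tuple[tuple[float, float], ...]
    nbins: tuple[int, ...]
    periodic: tuple[bool, ...]

    def __post_init__(self):
        if not 1 <= self.ndim <= 2:
            raise ValueError("only 1- and 2-dimensional CV spaces are supported")
        for (lo, hi), n in zip(self.bounds, self.nbins):
            if not hi > lo:
                raise ValueError(f"inverted or degenerate bounds ({lo}, {hi})")
            if n < MIN_BINS:
                raise ValueError(f"nbins must be >= {MIN_BINS}, got {n}")

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.nbins

    @property
    def nnodes(self) -> int:
        return int(np.prod(self.nbins))

    @property
    def spacing(self) -> tuple[float, ...]:
        out = []
        for (lo, hi), n, per in zip(self.bounds, self.nbins, self.periodic):
            out.append((hi - lo) / n if per else (hi - lo) / (n - 1))
        return tuple(out)

    @property
    def period(self) -> tuple[float | None, ...]:
        return tuple(
            (hi - lo) if per else None
            for (lo, hi), per in zip(self.bounds, self.periodic)
        )

    def axis(self, a: int) -> np.ndarray:
        """Node coordinates along axis ``a`` (exact, no cumulative drift)."""
        lo, _ = self.bounds[a]
        return lo + np.arange(self.nbins[a]) * self.spacing[a]

    def meshes(self) -> tuple[np.ndarray, ...]:
        """Per-axis coordinate arrays of full grid shape ('ij' indexing)."""
        return tuple(np.meshgrid(*(self.axis(a) for a in range(self.ndim)), indexing="ij"))

    def nodes(self) -> np.ndarray:
        """All node coordinates, shape ``(nnodes, ndim)``."""
        return np.stack([m.ravel() for m in self.meshes()], axis=1)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)


def make_grid(bounds, nbins, periodic=False) -> Grid:
    """Build a :class:`Grid` from per-axis bounds/bin counts/periodic flags.

    ``bounds`` is ``(lo, hi)`` for 1D or a sequence of such pairs for 2D;
    ``nbins`` and ``periodic`` may be scalars (broadcast) or per-axis.
    """
    b = np.asarray(bounds, dtype=float)
    if b.ndim == 1:
        b = b[None, :]
    if b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("bounds must be (lo, hi) or a sequence of (lo, hi) pairs")
    ndim = b.shape[0]
    nb = _as_axis_tuple(nbins, ndim, int)
    per = _as_axis_tuple(periodic, ndim, bool)
    return Grid(tuple((float(lo), float(hi)) for lo, hi in b), nb, per)


def wrap_displacement(a, b, grid: Grid) -> np.ndarray:
    """Minimum-image displacement ``a - b`` (plain subtraction on aperiodic axes).

    Accepts single points ``(ndim,)`` or stacks ``(..., ndim)``; for 1D grids
    scalars are accepted too.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    scalar_1d = grid.ndim == 1 and a.ndim == 0 and b.ndim == 0
    d = np.atleast_1d(a - b).astype(float)
    arr = d.reshape(-1, grid.ndim) if d.shape[-1] == grid.ndim else d.reshape(-1, 1)
    for ax, p in enumerate(grid.period):
        if p is not None:
            arr[:, ax] -= p * np.round(arr[:, ax] / p)
    out = arr.reshape(d.shape)
    return float(out.ravel()[0]) if scalar_1d else out


def wrap_into_domain(x, grid: Grid) -> np.ndarray:
    """Wrap points into ``[lo, hi)`` on periodic axes; aperiodic axes untouched."""
    x = np.array(x, dtype=float, copy=True)
    pts = x.reshape(-1, grid.ndim)
    for ax, p in enumerate(grid.period):
        if p is not None:
            lo = grid.bounds[ax][0]
            pts[:, ax] = lo + np.mod(pts[:, ax] - lo, p)
    return x


@dataclass
class ScalarField:
    """One real value per grid node."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def shifted_to_zero_min(self, mask=None) -> "ScalarField":
        m = np.ones(self.grid.shape, bool) if mask is None else mask
        return ScalarField(self.grid, self.values - np.min(self.values[m]))


@dataclass
class VectorField:
    """One real value per grid node per CV axis (e.g. a mean-force field)."""

    grid: Grid
    components: tuple[np.ndarray, ...]

    def __post_init__(self):
        comps = tuple(np.asarray(c, dtype=float) for c in self.components)
        if len(comps) != self.grid.ndim:
            raise ValueError("one component per CV axis required")
        for c in comps:
            if c.shape != self.grid.shape:
                raise ValueError("component shape does not match grid")
        self.components = comps


@dataclass
class CVTrajectory:
    """Time-ordered CV samples from one biased simulation."""

    times: np.ndarray
    samples: np.ndarray
    stride: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        s = np.asarray(self.samples, dtype=float)
        if s.ndim == 1:
            s = s[:, None]
        self.samples = s
        if self.times.ndim != 1 or len(self.times) != len(self.samples):
            raise ValueError("times and samples must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite CV samples")

    @property
    def ndim(self) -> int:
        return self.samples.shape[1]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_CV_NAMES = ("s1", "s2")


def _grid_header(grid: Grid, names) -> list[str]:
    lines = ["#! FIELDS " + " ".join(list(_CV_NAMES[: grid.ndim]) + list(names))]
    for a in range(grid.ndim):
        cv = _CV_NAMES[a]
        lo, hi = grid.bounds[a]
        lines.append(f"#! SET min_{cv} {lo!r}")
        lines.append(f"#! SET max_{cv} {hi!r}")
        lines.append(f"#! SET nbins_{cv} {grid.nbins[a]}")
        lines.append(f"#! SET periodic_{cv} {'true' if grid.periodic[a] else 'false'}")
    return lines


def write_fields_txt(path, grid: Grid, fields: dict[str, np.ndarray]) -> None:
    """Write named per-node fields to a plain-text grid file.

    Format: a ``#! FIELDS`` header naming coordinate and value columns,
    ``#! SET`` lines fixing bounds/nbins/periodicity, then one row per node
    (coordinates followed by values) at full double precision, so a
    write→read round trip is bit-exact.
    """
    names = list(fields)
    cols = [m.ravel() for m in grid.meshes()]
    for name in names:
        v = np.asarray(fields[name], dtype=float)
        if v.shape != grid.shape:
            raise ValueError(f"field {name!r} shape mismatch")
        cols.append(v.ravel())
    buf = io.StringIO()
    buf.write("\n".join(_grid_header(grid, names)) + "\n")
    for row in zip(*cols):
        buf.write(" ".join(repr(float(x)) for x in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_fields_txt(path) -> tuple[Grid, dict[str, np.ndarray]]:
    """Read a grid file written by :func:`write_fields_txt`."""
    meta: dict[str, str] = {}
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line[2:].split()
                if parts[0] == "FIELDS":
                    names = parts[1:]
                elif parts[0] == "SET":
                    meta[parts[1]] = parts[2]
                continue
            vals = line.split()
            if len(vals) != len(names):
                raise ValueError(f"{path}: ragged row at line {lineno}")
            rows.append([float(v) for v in vals])
    if not names:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    ndim = 2 if "min_s2" in meta else 1
    bounds, nbins, periodic = [], [], []
    for a in range(ndim):
        cv = _CV_NAMES[a]
        bounds.append((float(meta[f"min_{cv}"]), float(meta[f"max_{cv}"])))
        nbins.append(int(meta[f"nbins_{cv}"]))
        periodic.append(meta[f"periodic_{cv}"] == "true")
    grid = Grid(tuple(bounds), tuple(nbins), tuple(periodic))
    data = np.asarray(rows, dtype=float)
    if data.shape[0] != grid.nnodes:
        raise ValueError(f"{path}: expected {grid.nnodes} rows, found {data.shape[0]}")
    out = {}
    for j, name in enumerate(names[ndim:], start=ndim):
        out[name] = data[:, j].reshape(grid.shape)
    return grid, out


def save_fields_npz(path, grid: Grid, fields: dict[str, np.ndarray]) -> None:
    """Binary (.npz) container for bit-exact round-tripping of grid fields."""
    payload = {
        "bounds": np.asarray(grid.bounds, dtype=float),
        "nbins": np.asarray(grid.nbins, dtype=np.int64),
        "periodic": np.asarray(grid.periodic, dtype=bool),
        "names": np.asarray(list(fields)),
    }
    for name, v in fields.items():
        payload["field_" + name] = np.asarray(v, dtype=float)
    np.savez(path, **payload)


def load_fields_npz(path) -> tuple[Grid, dict[str, np.ndarray]]:
    with np.load(path, allow_pickle=False) as z:
        grid = Grid(
            tuple((float(lo), float(hi)) for lo, hi in z["bounds"]),
            tuple(int(n) for n in z["nbins"]),
            tuple(bool(p) for p in z["periodic"]),
        )
        fields = {str(n): z["field_" + str(n)] for n in z["names"]}
    return grid, fields
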