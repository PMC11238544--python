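"""Mean force estimation from biased time windows, and merging across runs.

For a time window of constant bias the unbiased mean force (stored with the
sign convention of dF/ds) is estimated as

    f_i(s) = -kT d ln p_i(s) / ds  -  sum_b dV_b(s)/ds

where p_i is a Gaussian kernel-density estimate of the configurations
sampled in the window and the sum runs over every bias acting during the
window (the frozen metadynamics snapshot plus any static restraints or
walls).  Window estimates are aggregated as a weighted average with weights
proportional to p_i, kept as streaming sums so the estimate, its variance,
and merges across independent simulations are all exact single-pass
operations:

    sumW   = sum_i p_i            sumWF  = sum_i p_i f_i
    sumWF2 = sum_i p_i f_i^2      sumW2  = sum_i p_i^2

Merging M independent simulations uses the same weighted average at the
simulation level, with each run weighted by its cumulative biased density
P_j = sumW_j; because the accumulators are additive, splitting a trajectory
at a window boundary and recombining reproduces the unsplit result exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import CVTrajectory, Grid, ScalarField, VectorField
from .metad import BiasState, HillsLog

__all__ = [
    "KDEParams",
    "Window",
    "ForceAccumulator",
    "SimulationForceRecord",
    "window_density",
    "window_kde_force",
    "window_mean_force",
    "kernel_sums",
    "accumulate",
    "combine_simulations",
    "windows_from_logs",
    "analyze_simulation",
    "default_bandwidth",
    "UNDERFLOW_FLOOR",
]

# Unscaled kernel sums below this are treated as "unexplored in this window":
# the window contributes zero weight there (never NaN).
UNDERFLOW_FLOOR = 1e-300


@dataclass
class KDEParams:
    """Kernel-density parameters: per-axis bandwidth h and height scale f_c.

    The density prefactor is ``f_c / prod(h)`` so that densities computed
    with different bandwidths or sampling rates stay mutually combinable.
    """

    bandwidth: tuple
    fc: float = 1.0

    def __post_init__(self):
        self.bandwidth = tuple(float(h) for h in np.atleast_1d(self.bandwidth))
        if any(h <= 0 for h in self.bandwidth) or self.fc <= 0:
            raise ValueError("bandwidth and fc must be > 0")


def default_bandwidth(grid: Grid, metad_sigma=None, samples=None) -> tuple:
    """Default per-axis KDE bandwidth: half the hill width when available,
    else a Silverman-style scale from the sample spread, floored at one
    grid spacing."""
    if metad_sigma is not None:
        h = 0.5 * np.atleast_1d(np.asarray(metad_sigma, dtype=float))
    elif samples is not None and len(samples) > 1:
        s = np.atleast_2d(np.asarray(samples, dtype=float))
        h = 1.06 * s.std(axis=0) * len(s) ** (-0.2)
    else:
        h = 2.0 * np.asarray(grid.spacing)
    return tuple(np.maximum(h, np.asarray(grid.spacing)))


@dataclass
class Window:
    """Samples of one constant-bias time window plus the active bias gradients."""

    index: int
    samples: np.ndarray
    times: np.ndarray
    bias_gradients: list  # list of VectorField (MetaD snapshot, static total, ...)


@dataclass
class ForceAccumulator:
    """Streaming per-node sums enabling exact single-pass weighted statistics."""

    grid: Grid
    sumW: np.ndarray = None
    sumWF: tuple = None
    sumWF2: tuple = None
    sumW2: np.ndarray = None
    hist: np.ndarray = None
    window_count: int = 0

    def __post_init__(self):
        z = self.grid.zeros
        if self.sumW is None:
            self.sumW = z()
        if self.sumWF is None:
            self.sumWF = tuple(z() for _ in range(self.grid.ndim))
        if self.sumWF2 is None:
            self.sumWF2 = tuple(z() for _ in range(self.grid.ndim))
        if self.sumW2 is None:
            self.sumW2 = z()
        if self.hist is None:
            self.hist = z()

    def add_window(self, density: np.ndarray, force: tuple, nsamples_hist: np.ndarray | None = None):
        mask = density > 0
        self.sumW += density
        self.sumW2 += density * density
        for a in range(self.grid.ndim):
            fa = np.where(mask, force[a], 0.0)
            self.sumWF[a][mask] += (density * fa)[mask]
            self.sumWF2[a][mask] += (density * fa * fa)[mask]
        if nsamples_hist is not None:
            self.hist += nsamples_hist
        self.window_count += 1

    @property
    def explored(self) -> np.ndarray:
        return self.sumW > 0

    def mean_force(self) -> VectorField:
        """sumWF / sumW where explored; NaN elsewhere (flagged unexplored)."""
        comps = []
        m = self.explored
        for a in range(self.grid.ndim):
            c = np.full(self.grid.shape, np.nan)
            c[m] = self.sumWF[a][m] / self.sumW[m]
            comps.append(c)
        return VectorField(self.grid, tuple(comps))

    def merged_with(self, other: "ForceAccumulator") -> "ForceAccumulator":
        if other.grid != self.grid:
            raise ValueError("cannot merge accumulators on different grids")
        return ForceAccumulator(
            self.grid,
            self.sumW + other.sumW,
            tuple(a + b for a, b in zip(self.sumWF, other.sumWF)),
            tuple(a + b for a, b in zip(self.sumWF2, other.sumWF2)),
            self.sumW2 + other.sumW2,
            self.hist + other.hist,
            self.window_count + other.window_count,
        )


@dataclass
class SimulationForceRecord:
    """Per-simulation result: accumulator plus derived fields."""

    accumulator: ForceAccumulator
    label: str = ""

    @property
    def grid(self) -> Grid:
        return self.accumulator.grid

    @property
    def cumulative_density(self) -> ScalarField:
        return ScalarField(self.grid, self.accumulator.sumW.copy())

    @property
    def histogram(self) -> ScalarField:
        return ScalarField(self.grid, self.accumulator.hist.copy())

    @property
    def mean_force(self) -> VectorField:
        return self.accumulator.mean_force()

    @property
    def explored(self) -> np.ndarray:
        return self.accumulator.explored


# ---------------------------------------------------------------------------
# kernel sums
# ---------------------------------------------------------------------------


def kernel_sums(samples, grid: Grid, bandwidth, chunk: int = 1024):
    """Unscaled Gaussian-kernel sums over grid nodes.

    Returns ``(denom, nums)`` where ``denom[s] = sum_k K_k(s)`` and
    ``nums[a][s] = sum_k wrap(s - s_k)_a / h_a^2 * K_k(s)`` with
    ``K_k(s) = exp(-sum_a wrap(s - s_k)_a^2 / (2 h_a^2))``.
    """
    s = np.atleast_2d(np.asarray(samples, dtype=float))
    if s.shape[1] != grid.ndim:
        s = s.reshape(-1, grid.ndim)
    h = np.atleast_1d(np.asarray(bandwidth, dtype=float))
    axes = [grid.axis(a) for a in range(grid.ndim)]
    flat = [m.ravel() for m in grid.meshes()]
    nn = grid.nnodes
    denom = np.zeros(nn)
    nums = [np.zeros(nn) for _ in range(grid.ndim)]
    for start in range(0, len(s), chunk):
        blk = s[start : start + chunk]
        d = []
        expo = np.zeros((len(blk), nn))
        for a in range(grid.ndim):
            da = flat[a][None, :] - blk[:, a][:, None]
            p = grid.period[a]
            if p is not None:
                da -= p * np.round(da / p)
            d.append(da)
            expo += (da / h[a]) ** 2
        K = np.exp(-0.5 * expo)
        denom += K.sum(axis=0)
        for a in range(grid.ndim):
            nums[a] += (d[a] / h[a] ** 2 * K).sum(axis=0)
    return denom.reshape(grid.shape), tuple(n.reshape(grid.shape) for n in nums)


def window_density(samples, grid: Grid, kde: KDEParams) -> ScalarField:
    """Biased probability density of a window: scaled Gaussian KDE on the grid."""
    if len(np.atleast_2d(samples)) < 1:
        raise ValueError("window must contain at least one sample")
    denom, _ = kernel_sums(samples, grid, kde.bandwidth)
    scale = kde.fc / np.prod(kde.bandwidth)
    return ScalarField(grid, scale * denom)


def window_kde_force(samples, grid: Grid, kde: KDEParams, kT: float = 1.0) -> VectorField:
    """Kernel force term ``-kT d ln p / ds`` on the grid.

    Nodes where the kernel sum underflows are NaN (undefined, not zero).
    """
    denom, nums = kernel_sums(samples, grid, kde.bandwidth)
    mask = denom > UNDERFLOW_FLOOR
    comps = []
    for a in range(grid.ndim):
        c = np.full(grid.shape, np.nan)
        c[mask] = kT * nums[a][mask] / denom[mask]
        comps.append(c)
    return VectorField(grid, tuple(comps))


def window_mean_force(window: Window, density: ScalarField, kde_force: VectorField) -> VectorField:
    """Unbiased window mean force: kernel term minus every active bias gradient."""
    grid = density.grid
    if kde_force.grid != grid:
        raise ValueError("density and kde_force must share a grid")
    comps = [c.copy() for c in kde_force.components]
    for bg in window.bias_gradients:
        if bg.grid != grid:
            raise ValueError("bias gradient grid mismatch")
        for a in range(grid.ndim):
            comps[a] -= bg.components[a]
    return VectorField(grid, tuple(comps))


def accumulate(acc: ForceAccumulator, density: ScalarField, force: VectorField) -> ForceAccumulator:
    """Add one window's (density, force) into the running sums (in place).

    Nodes where the force is undefined (NaN) contribute zero weight.
    """
    if density.grid != acc.grid or force.grid != acc.grid:
        raise ValueError("grid mismatch in accumulate")
    d = density.values
    finite = np.ones(acc.grid.shape, bool)
    for c in force.components:
        finite &= np.isfinite(c)
    d_eff = np.where(finite, d, 0.0)
    acc.add_window(d_eff, tuple(np.where(finite, c, 0.0) for c in force.components))
    return acc


def combine_simulations(records, label: str = "combined") -> SimulationForceRecord:
    """Merge independent simulations by their cumulative biased densities.

    The combined mean force is ``sum_j P_j <f>_j / sum_j P_j`` per node; the
    merged accumulators are field-wise sums, and the explored region is the
    union of the per-simulation explored regions.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one simulation record")
    acc = records[0].accumulator
    for r in records[1:]:
        acc = acc.merged_with(r.accumulator)
    return SimulationForceRecord(acc, label=label)


# ---------------------------------------------------------------------------
# window streaming
# ---------------------------------------------------------------------------


def _sample_histogram(samples, grid: Grid) -> np.ndarray:
    """Count samples per nearest grid node (the biased histogram H_j)."""
    s = np.atleast_2d(np.asarray(samples, dtype=float))
    idx = []
    for a in range(grid.ndim):
        lo = grid.bounds[a][0]
        i = np.round((s[:, a] - lo) / grid.spacing[a]).astype(int)
        if grid.periodic[a]:
            i = np.mod(i, grid.nbins[a])
        else:
            i = np.clip(i, 0, grid.nbins[a] - 1)
        idx.append(i)
    hist = np.zeros(grid.shape)
    np.add.at(hist, tuple(idx), 1.0)
    return hist


def windows_from_logs(
    colvar: CVTrajectory,
    hills: HillsLog | None,
    static_biases,
    grid: Grid,
    kde: KDEParams,
    kT: float = 1.0,
):
    """Partition a trajectory into constant-bias windows and stream estimates.

    Yields ``(Window, density, force)`` per window, ready for
    :func:`accumulate`.  Window ``i`` covers ``[t_i, t_i + tau)`` (half-open:
    a sample exactly at ``t_i + tau`` belongs to window ``i+1``) and its
    metadynamics gradient is built from hills with deposition time <= t_i.
    With no hills the whole trajectory is a single window (the umbrella
    sampling limit).
    """
    if np.any(colvar.times < 0):
        raise ValueError("timeline diagnostic: samples predate the first window")
    if colvar.ndim != grid.ndim:
        raise ValueError("trajectory/grid dimensionality mismatch")

    static_grad = None
    if static_biases:
        comps = [grid.zeros() for _ in range(grid.ndim)]
        for b in static_biases:
            g = b.gradient_on_grid(grid)
            for a in range(grid.ndim):
                comps[a] += g.components[a]
        static_grad = VectorField(grid, tuple(comps))

    if hills is None or len(hills) == 0:
        widx = np.zeros(len(colvar.times), dtype=int)
        nwin = 1
        hill_times = np.zeros(0)
    else:
        hill_times = hills.times
        widx = np.searchsorted(hill_times, colvar.times, side="right")
        nwin = int(widx.max()) + 1

    state = BiasState(grid)
    boundaries = np.searchsorted(widx, np.arange(nwin + 1))
    for i in range(nwin):
        a, b = boundaries[i], boundaries[i + 1]
        if a == b:
            if i > 0 and hills is not None and i <= len(hills):
                state.add_hill(hills.centers[i - 1], hills.sigmas[i - 1], hills.heights[i - 1])
            continue
        if i > 0 and hills is not None and i <= len(hills):
            state.add_hill(hills.centers[i - 1], hills.sigmas[i - 1], hills.heights[i - 1])
        samples = colvar.samples[a:b]
        times = colvar.times[a:b]
        grads = []
        if hills is not None and len(hills) > 0:
            _, gsnap = state.snapshot()
            grads.append(gsnap)
        if static_grad is not None:
            grads.append(static_grad)
        win = Window(index=i, samples=samples, times=times, bias_gradients=grads)
        # single kernel pass serves both the density and the kernel force
        denom, nums = kernel_sums(samples, grid, kde.bandwidth)
        density = ScalarField(grid, kde.fc / np.prod(kde.bandwidth) * denom)
        mask = denom > UNDERFLOW_FLOOR
        comps = []
        for a_ in range(grid.ndim):
            c = np.full(grid.shape, np.nan)
            c[mask] = kT * nums[a_][mask] / denom[mask]
            comps.append(c)
        kforce = VectorField(grid, tuple(comps))
        force = window_mean_force(win, density, kforce)
        yield win, density, force


def analyze_simulation(
    colvar: CVTrajectory,
    hills: HillsLog | None,
    static_biases,
    grid: Grid,
    kde: KDEParams | None = None,
    kT: float = 1.0,
    label: str = "",
) -> SimulationForceRecord:
    """Run the full per-simulation MFI pass and return its force record."""
    if kde is None:
        sigma = hills.sigmas[0] if hills is not None and len(hills) else None
        kde = KDEParams(default_bandwidth(grid, metad_sigma=sigma, samples=colvar.samples))
    acc = ForceAccumulator(grid)
    for win, density, force in windows_from_logs(colvar, hills, static_biases, grid, kde, kT):
        accumulate(acc, density, force)
        acc.hist += _sample_histogram(win.samples, grid)
    return SimulationForceRecord(acc, label=label)
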