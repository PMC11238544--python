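"""On-the-fly and a-posteriori convergence machinery.

Local convergence: the weighted variance of the per-window mean forces,

    Var(s) = BC * ( sumWF2/sumW - (sumWF/sumW)^2 )
    n_eff  = sumW^2 / sumW2            (Kish effective sample size)
    BC     = n_eff / (n_eff - 1)       (Bessel correction of the weighted mean)
    sigma_E = sigma / sqrt(n_eff)      (standard error of the weighted mean)

With equal weights every quantity reduces to its unweighted textbook form.
Per-component standard errors are reduced to one scalar per node by the
Euclidean norm (per-component fields are retained for inspection).

Global convergence: sigma_bar_E (mean of sigma_E over the sampled region),
the explored volume fraction v (nodes whose biased histogram exceeds a
threshold, over the declared domain), and Omega = sigma_bar_E / v —
error per unit explored volume, computable on the fly with no reference.

Across M independent simulations the same weighted-variance form applies at
the simulation level with weights P_j(s) (cumulative biased densities), and
uncorrelated FES errors come from bootstrapping whole simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ForceAccumulator, SimulationForceRecord, combine_simulations, accumulate, _sample_histogram
from .grid import Grid, ScalarField
from .integrate import FESResult, integrate_mean_force

__all__ = [
    "ConvergenceField",
    "ConvergenceSeries",
    "VolumeParams",
    "window_variance",
    "explored_volume",
    "resolve_threshold",
    "global_metric",
    "on_the_fly_series",
    "cross_sim_variance",
    "bootstrap_fes",
    "BootstrapResult",
]


@dataclass
class ConvergenceField:
    """Per-node weighted force statistics; nodes with n_eff <= 1 are NaN."""

    grid: Grid
    sigma_components: tuple
    n_eff: np.ndarray
    sigma_e_components: tuple
    defined: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        """Euclidean norm of the per-component weighted standard deviations."""
        return np.sqrt(sum(c**2 for c in self.sigma_components))

    @property
    def sigma_e(self) -> np.ndarray:
        """Euclidean norm of the per-component standard errors."""
        return np.sqrt(sum(c**2 for c in self.sigma_e_components))


@dataclass
class VolumeParams:
    """Explored-volume definition: histogram threshold over the grid domain.

    ``threshold`` is an absolute count bound; when None it is resolved as
    ``threshold_fraction`` of the mean histogram over nonzero nodes.
    """

    threshold: float | None = None
    threshold_fraction: float = 0.01

    def __post_init__(self):
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.threshold_fraction <= 0:
            raise ValueError("threshold_fraction must be > 0")


def resolve_threshold(H: np.ndarray, vp: VolumeParams) -> float:
    if vp.threshold is not None:
        return float(vp.threshold)
    nz = H[H > 0]
    if nz.size == 0:
        raise ValueError("histogram is empty; cannot resolve a volume threshold")
    return float(vp.threshold_fraction * nz.mean())


def _weighted_stats(sumW, sumW2, sumWF, sumWF2, shape):
    with np.errstate(divide="ignore", invalid="ignore"):
        n_eff = np.where(sumW2 > 0, sumW**2 / np.where(sumW2 > 0, sumW2, 1.0), 0.0)
    defined = n_eff > 1.0
    bc = np.full(shape, np.nan)
    bc[defined] = n_eff[defined] / (n_eff[defined] - 1.0)
    sig_c, sige_c = [], []
    for a in range(len(sumWF)):
        mean = np.full(shape, np.nan)
        m2 = np.full(shape, np.nan)
        mask = sumW > 0
        mean[mask] = sumWF[a][mask] / sumW[mask]
        m2[mask] = sumWF2[a][mask] / sumW[mask]
        var = bc * np.maximum(m2 - mean**2, 0.0)
        s = np.sqrt(var)
        se = np.full(shape, np.nan)
        se[defined] = s[defined] / np.sqrt(n_eff[defined])
        s[~defined] = np.nan
        sig_c.append(s)
        sige_c.append(se)
    return tuple(sig_c), n_eff, tuple(sige_c), defined


def window_variance(acc: ForceAccumulator) -> ConvergenceField:
    """Weighted variance / standard error of the window mean forces."""
    if acc.window_count < 1:
        raise ValueError("accumulator holds no windows")
    sig, n_eff, sige, defined = _weighted_stats(
        acc.sumW, acc.sumW2, acc.sumWF, acc.sumWF2, acc.grid.shape
    )
    return ConvergenceField(acc.grid, sig, n_eff, sige, defined)


def explored_volume(H, vp: VolumeParams) -> float:
    """Fraction of the domain where the biased histogram exceeds the threshold."""
    Hv = H.values if isinstance(H, ScalarField) else np.asarray(H, dtype=float)
    if Hv.size == 0:
        raise ValueError("empty domain")
    if np.any(Hv < 0):
        raise ValueError("histogram must be nonnegative")
    thr = resolve_threshold(Hv, vp)
    v = float(np.count_nonzero(Hv > thr)) / Hv.size
    if v == 0.0:
        raise ValueError(
            f"no node exceeds the histogram threshold {thr}; "
            "explored volume undefined (Omega would diverge)"
        )
    return v


def global_metric(cf: ConvergenceField, H, vp: VolumeParams):
    """Global on-the-fly estimators: (sigma_bar_E, v, Omega = sigma_bar_E / v)."""
    Hv = H.values if isinstance(H, ScalarField) else np.asarray(H, dtype=float)
    thr = resolve_threshold(Hv, vp)
    sampled = (Hv > thr) & cf.defined
    if not sampled.any():
        raise ValueError("no sampled nodes with defined variance")
    sigma_bar = float(np.mean(cf.sigma_e[sampled]))
    v = explored_volume(Hv, vp)
    return sigma_bar, v, sigma_bar / v


@dataclass
class ConvergenceSeries:
    """Checkpointed global convergence metrics (all entries finite)."""

    times: np.ndarray
    sigma_bar: np.ndarray
    volume: np.ndarray
    omega: np.ndarray

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#! FIELDS time sigma_bar_E volume omega\n")
            for row in zip(self.times, self.sigma_bar, self.volume, self.omega):
                fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def on_the_fly_series(
    window_stream,
    checkpoints,
    vp: VolumeParams,
    grid: Grid,
    acc: ForceAccumulator | None = None,
) -> tuple[ForceAccumulator, ConvergenceSeries]:
    """Single-pass accumulation with convergence metrics at checkpoints.

    ``checkpoints`` is an iterable of window counts (after how many processed
    windows to record) or None for every window.  No lookahead: each record
    uses only the history up to that window.  Returns the final accumulator
    and the series; the final checkpoint equals a from-scratch batch result.
    """
    acc = acc if acc is not None else ForceAccumulator(grid)
    cps = None if checkpoints is None else sorted(set(int(c) for c in checkpoints))
    times, sb, vol, om = [], [], [], []
    processed = 0
    last_time = 0.0
    for win, density, force in window_stream:
        accumulate(acc, density, force)
        acc.hist += _sample_histogram(win.samples, grid)
        processed += 1
        last_time = float(win.times[-1])
        if cps is None or processed in cps:
            try:
                s, v, o = global_metric(window_variance(acc), acc.hist, vp)
            except ValueError:
                continue  # too little history for a defined variance yet
            times.append(last_time)
            sb.append(s)
            vol.append(v)
            om.append(o)
    series = ConvergenceSeries(np.asarray(times), np.asarray(sb), np.asarray(vol), np.asarray(om))
    return acc, series


def cross_sim_variance(records) -> ConvergenceField:
    """Weighted variance of per-simulation mean forces across M >= 2 runs.

    Weights are the cumulative biased densities P_j(s); the effective sample
    size and Bessel correction take the same form as for windows, now at the
    simulation level.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two independent simulations")
    grid = records[0].grid
    for r in records[1:]:
        if r.grid != grid:
            raise ValueError("records must share a grid")
    ndim = grid.ndim
    sumW = grid.zeros()
    sumW2 = grid.zeros()
    sumWF = [grid.zeros() for _ in range(ndim)]
    sumWF2 = [grid.zeros() for _ in range(ndim)]
    for r in records:
        P = r.accumulator.sumW
        mf = r.mean_force
        ok = r.explored
        P_eff = np.where(ok, P, 0.0)
        sumW += P_eff
        sumW2 += P_eff**2
        for a in range(ndim):
            fa = np.where(ok, mf.components[a], 0.0)
            sumWF[a] += P_eff * fa
            sumWF2[a] += P_eff * fa**2
    sig, n_eff, sige, defined = _weighted_stats(sumW, sumW2, tuple(sumWF), tuple(sumWF2), grid.shape)
    return ConvergenceField(grid, sig, n_eff, sige, defined)


@dataclass
class BootstrapResult:
    mean_fes: ScalarField
    std_fes: ScalarField
    common_mask: np.ndarray
    std_series: np.ndarray  # running mean(std) after 2, 3, ... n_boot replicates


def bootstrap_fes(records, n_boot: int = 100, seed: int = 0, method: str = "auto",
                  vp: VolumeParams | None = None) -> BootstrapResult:
    """Bootstrap over whole simulations: resample M records with replacement,
    combine, integrate, and take the per-node spread after gauge alignment.

    Windows within a run are never resampled (they are correlated); only the
    independent simulations are.  Gauge: each replicate FES is mean-aligned
    over the region explored by every record.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("bootstrap requires at least two simulations")
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    grid = records[0].grid
    vp = vp if vp is not None else VolumeParams()
    common = np.ones(grid.shape, bool)
    pooled_hist = grid.zeros()
    for r in records:
        common &= r.explored
        pooled_hist += r.accumulator.hist
    if pooled_hist.max() > 0:
        # gauge/statistics region: sampled by the pooled ensemble, not mere
        # kernel tails of individual records
        common &= pooled_hist > resolve_threshold(pooled_hist, vp)
    if not common.any():
        raise ValueError("records share no commonly explored region")

    rng = np.random.default_rng(seed)
    M = len(records)
    reps = np.empty((n_boot,) + grid.shape)
    for bidx in range(n_boot):
        idx = rng.integers(0, M, M)
        merged = combine_simulations([records[i] for i in idx])
        res = integrate_mean_force(merged.mean_force, mask=merged.explored, method=method)
        vals = res.fes.values.copy()
        vals -= np.nanmean(vals[common])
        reps[bidx] = vals

    mean = np.nanmean(reps, axis=0)
    std = np.nanstd(reps, axis=0, ddof=1)
    series = np.array(
        [np.nanmean(np.nanstd(reps[: k + 1], axis=0, ddof=1)[common]) for k in range(1, n_boot)]
    )
    return BootstrapResult(ScalarField(grid, mean), ScalarField(grid, std), common, series)
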