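"""Biased Langevin dynamics on analytic potentials.

The toy systems identify configuration space with CV space: the simulated
particle position *is* the collective variable.  The integrator is BAOAB
splitting for underdamped Langevin dynamics (good configurational accuracy
at moderate time steps); setting ``friction = 0`` through the low-level core
recovers plain velocity Verlet, which is used in tests of the symplectic
part.  Each run owns one explicitly seeded RNG and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _simcore
from .grid import CVTrajectory, Grid, wrap_into_domain
from .metad import HillsLog, MetaDParams
from .potentials import HarmonicBias, Multiwell1D, Polynomial2D, Potential, WallBias

__all__ = ["LangevinParams", "SimOutput", "run_langevin", "run_campaign", "TrajectoryEscaped"]


class TrajectoryEscaped(RuntimeError):
    """Trajectory left the declared CV domain beyond the allowed margin.

    Usually signals a missing confining wall or an unstable time step."""


@dataclass
class LangevinParams:
    kT: float = 1.0
    friction: float = 1.0
    mass: float = 1.0
    dt: float = 0.005
    nsteps: int = 100_000
    initial_position: object = "random"  # ndim-vector or "random" (uniform in domain)
    seed: int = 0
    sample_stride: int = 10
    domain_margin: float = 1.0

    def __post_init__(self):
        if self.dt <= 0 or self.nsteps < 1 or self.friction <= 0 or self.kT <= 0:
            raise ValueError("require dt > 0, nsteps >= 1, friction > 0, kT > 0")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass
class SimOutput:
    trajectory: CVTrajectory
    hills: HillsLog
    static_biases: list
    params_echo: dict


def _potential_arrays(potential: Potential):
    """Flatten a potential into the parameter arrays of the jitted core."""
    e = np.zeros(0)
    ei = np.zeros(0, dtype=np.int64)
    if isinstance(potential, Multiwell1D):
        wells = np.asarray(potential.wells, dtype=float).reshape(-1, 3)
        poly = np.asarray(potential.poly_terms, dtype=float).reshape(-1, 3)
        return dict(
            kind=0, p2i=ei, p2j=ei, p2c=e,
            gA=wells[:, 0].copy(), gc=wells[:, 1].copy(), gw=wells[:, 2].copy(),
            p1c=poly[:, 0].copy(), p1cen=poly[:, 1].copy(),
            p1p=poly[:, 2].astype(np.int64),
        )
    if isinstance(potential, Polynomial2D):
        keys = sorted(potential.coefficients)
        return dict(
            kind=1,
            p2i=np.asarray([k[0] for k in keys], dtype=np.int64),
            p2j=np.asarray([k[1] for k in keys], dtype=np.int64),
            p2c=np.asarray([potential.coefficients[k] for k in keys], dtype=float),
            gA=e, gc=e, gw=e, p1c=e, p1cen=e, p1p=ei,
        )
    raise TypeError(
        "the simulator supports Multiwell1D (1D) and Polynomial2D (2D) potentials"
    )


def _bias_arrays(static_biases, ndim):
    harm_c, harm_k = [], []
    wall_ax, wall_thr, wall_sgn, wall_k, wall_p = [], [], [], [], []
    for b in static_biases or ():
        if isinstance(b, HarmonicBias):
            harm_c.append(b.center)
            harm_k.append(b.kappa)
        elif isinstance(b, WallBias):
            wall_ax.append(b.axis)
            wall_thr.append(b.threshold)
            wall_sgn.append(1.0 if b.side == "upper" else -1.0)
            wall_k.append(b.kappa)
            wall_p.append(b.exponent)
        else:
            raise TypeError(f"unsupported static bias {type(b).__name__}")
    return dict(
        harm_c=np.asarray(harm_c, dtype=float).reshape(-1, ndim),
        harm_k=np.asarray(harm_k, dtype=float).reshape(-1, ndim),
        wall_ax=np.asarray(wall_ax, dtype=np.int64),
        wall_thr=np.asarray(wall_thr, dtype=float),
        wall_sgn=np.asarray(wall_sgn, dtype=float),
        wall_k=np.asarray(wall_k, dtype=float),
        wall_p=np.asarray(wall_p, dtype=np.int64),
    )


def run_langevin(
    potential: Potential,
    static_biases,
    metad: MetaDParams | None,
    params: LangevinParams,
    domain: Grid,
) -> SimOutput:
    """Integrate one biased Langevin trajectory in the CV domain of ``domain``.

    Total force is ``-grad(potential + static biases + current MetaD bias)``;
    the MetaD bias is updated every ``metad.pace`` steps (None disables it).
    Stored samples are taken every ``sample_stride`` steps.  Deterministic for
    a fixed seed.  Raises :class:`TrajectoryEscaped` when the trajectory
    leaves the domain by more than ``domain_margin`` on an aperiodic axis.
    """
    ndim = domain.ndim
    if potential.ndim != ndim:
        raise ValueError("potential dimensionality does not match the domain")
    pot = _potential_arrays(potential)
    bias = _bias_arrays(static_biases, ndim)

    lo = np.asarray([b[0] for b in domain.bounds])
    hi = np.asarray([b[1] for b in domain.bounds])
    periodic = np.asarray(domain.periodic, dtype=np.bool_)

    if isinstance(params.initial_position, str):
        if params.initial_position != "random":
            raise ValueError("initial_position must be a vector or 'random'")
        rng = np.random.default_rng(params.seed)
        x0 = lo + rng.random(ndim) * (hi - lo)
    else:
        x0 = np.asarray(params.initial_position, dtype=float).reshape(ndim)
    x0 = wrap_into_domain(x0, domain)

    use_metad = metad is not None
    if use_metad and len(metad.sigma) != ndim:
        raise ValueError("MetaD sigma dimensionality mismatch")

    samples, hc, hh, ht, nh, status = _simcore.langevin_metad_core(
        pot["kind"], ndim,
        pot["p2i"], pot["p2j"], pot["p2c"],
        pot["gA"], pot["gc"], pot["gw"], pot["p1c"], pot["p1cen"], pot["p1p"],
        bias["harm_c"], bias["harm_k"],
        bias["wall_ax"], bias["wall_thr"], bias["wall_sgn"], bias["wall_k"], bias["wall_p"],
        lo, hi, periodic, params.domain_margin,
        use_metad,
        metad.height if use_metad else 0.0,
        np.asarray(metad.sigma, dtype=float) if use_metad else np.ones(ndim),
        metad.pace if use_metad else 1,
        (metad.bias_factor if metad.bias_factor is not None else 0.0) if use_metad else 0.0,
        params.kT,
        params.kT, params.friction, params.mass, params.dt,
        params.nsteps, params.sample_stride, x0, params.seed,
    )
    if status == _simcore.STATUS_ESCAPED:
        raise TrajectoryEscaped(
            f"trajectory (seed {params.seed}) left the CV domain by more than "
            f"{params.domain_margin}; consider adding walls or reducing dt"
        )

    stride_t = params.sample_stride * params.dt
    times = stride_t * np.arange(1, len(samples) + 1)
    traj = CVTrajectory(times, samples, stride_t)
    hills = HillsLog(
        ndim,
        hc, np.tile(np.asarray(metad.sigma, dtype=float), (nh, 1)) if use_metad else np.zeros((0, ndim)),
        hh, ht,
        bias_factor=metad.bias_factor if use_metad else None,
        kT=params.kT,
        pace_time=metad.pace * params.dt if use_metad else None,
    ) if use_metad else HillsLog.empty(ndim, kT=params.kT)

    echo = {
        "params": asdict(params) if not isinstance(params.initial_position, str) else {
            **asdict(params), "initial_position": "random", "resolved_x0": [float(v) for v in x0],
        },
        "metad": None if not use_metad else {
            "height": metad.height, "sigma": list(metad.sigma),
            "pace": metad.pace, "bias_factor": metad.bias_factor,
        },
        "domain": {"bounds": list(map(list, domain.bounds)), "periodic": list(domain.periodic)},
        "potential": type(potential).__name__,
        "n_static_biases": len(static_biases or ()),
    }
    return SimOutput(traj, hills, list(static_biases or ()), echo)


def run_campaign(run_specs) -> list[SimOutput]:
    """Run a list of independent simulations.

    Each spec is a dict with keys ``potential``, ``static_biases``, ``metad``,
    ``params``, ``domain`` (the arguments of :func:`run_langevin`).  Seeds must
    be distinct across runs; results are order-independent.
    """
    seeds = [spec["params"].seed for spec in run_specs]
    if len(set(seeds)) != len(seeds):
        raise ValueError(f"duplicate seeds in campaign: {sorted(seeds)}")
    return [
        run_langevin(
            spec["potential"],
            spec.get("static_biases", ()),
            spec.get("metad"),
            spec["params"],
            spec["domain"],
        )
        for spec in run_specs
    ]
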