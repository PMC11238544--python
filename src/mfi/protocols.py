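"""Reference experiment protocols on the bundled toy systems.

These tie the simulator and the analysis stack into the standard
demonstrations: many short well-tempered metadynamics runs on the 2D
double-well benchmark (optionally half of them carrying localized harmonic
restraints), an umbrella-sampling campaign on a 1D quartic, and a
bootstrap ensemble.  They are what the shipped demo configs and the
acceptance measurements run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .convergence import (
    VolumeParams,
    bootstrap_fes,
    global_metric,
    resolve_threshold,
    window_variance,
)
from .grid import Grid, make_grid
from .integrate import aad, integrate_mean_force, largest_component
from .langevin import LangevinParams, run_campaign
from .metad import MetaDParams
from .potentials import HarmonicBias, Multiwell1D, builtin_potential, reference_fes

__all__ = [
    "doublewell_campaign",
    "campaign_convergence_metrics",
    "us_quartic_campaign",
    "CampaignMetrics",
]

# Frozen study conditions for the 2D double-well campaign (see docs/methods.md)
DOUBLEWELL_KT = 1.0
DOUBLEWELL_METAD = dict(height=1.0, sigma=(0.25, 0.25), pace=200, bias_factor=10.0)
DOUBLEWELL_LANGEVIN = dict(friction=1.0, mass=1.0, dt=0.005, sample_stride=10)
DOUBLEWELL_BANDWIDTH = (0.125, 0.125)
# centers of the localized restraints bridging the two basins
TRANSITION_RESTRAINT_CENTERS = ((0.0, 0.0), (-0.6, 0.6), (0.6, -0.6))
TRANSITION_RESTRAINT_KAPPA = (2.0, 2.0)


def doublewell_grid(nbins: int = 64) -> Grid:
    return make_grid([(-3.0, 3.0), (-3.0, 3.0)], nbins)


def doublewell_campaign(
    nruns: int = 10,
    nsteps: int = 200_000,
    seed: int = 0,
    nbins: int = 64,
    restrained_runs: int = 0,
):
    """Run short WTmetaD simulations on the 2D double-well benchmark.

    The last ``restrained_runs`` runs additionally carry a 2D harmonic
    restraint centered in the transition region (cycled over
    ``TRANSITION_RESTRAINT_CENTERS``), the protocol used to refine
    poorly sampled saddle regions.  Returns ``(sims, grid)``.
    """
    pot = builtin_potential("doublewell_2d")
    grid = doublewell_grid(nbins)
    mp = MetaDParams(**DOUBLEWELL_METAD)
    specs = []
    for i in range(nruns):
        statics = ()
        if i >= nruns - restrained_runs:
            c = TRANSITION_RESTRAINT_CENTERS[i % len(TRANSITION_RESTRAINT_CENTERS)]
            statics = (HarmonicBias(c, TRANSITION_RESTRAINT_KAPPA),)
        specs.append(
            dict(
                potential=pot,
                static_biases=statics,
                metad=mp,
                domain=grid,
                params=LangevinParams(
                    kT=DOUBLEWELL_KT,
                    nsteps=nsteps,
                    initial_position="random",
                    seed=seed * 1000 + i,
                    **DOUBLEWELL_LANGEVIN,
                ),
            )
        )
    return run_campaign(specs), grid


@dataclass
class CampaignMetrics:
    """Checkpointed on-the-fly metrics side by side with the reference AAD."""

    steps: np.ndarray       # cumulative simulation steps across all runs
    sigma_bar: np.ndarray
    volume: np.ndarray
    omega: np.ndarray
    aad: np.ndarray
    final_record: core.SimulationForceRecord
    final_mask: np.ndarray


def campaign_convergence_metrics(
    sims,
    grid: Grid,
    ncheckpoints: int = 10,
    kT: float = DOUBLEWELL_KT,
    bandwidth=DOUBLEWELL_BANDWIDTH,
    vp: VolumeParams | None = None,
    reference=None,
    method: str = "fd",
) -> CampaignMetrics:
    """Stream all runs' windows round-robin and checkpoint the convergence
    metrics together with the AAD from the analytic reference.

    Round-robin interleaving advances every run in step, so the checkpoint
    axis is the total number of simulation steps of a trivially parallel
    campaign.  Omega and sigma_bar use only the simulation history (no
    reference); the AAD uses the analytic surface and is only available for
    toy models.
    """
    vp = vp if vp is not None else VolumeParams()
    if reference is None:
        reference = reference_fes(builtin_potential("doublewell_2d"), grid)
    kde = core.KDEParams(bandwidth)
    streams = []
    for s in sims:
        streams.append(
            core.windows_from_logs(s.trajectory, s.hills, s.static_biases, grid, kde, kT)
        )
    nwin = min((len(s.hills) + 1) for s in sims)
    steps_per_window = [
        (s.params_echo["params"]["nsteps"] // max(len(s.hills) + 1, 1)) for s in sims
    ]
    cps = sorted(set(np.linspace(1, nwin, ncheckpoints, dtype=int)))
    acc = core.ForceAccumulator(grid)
    out_steps, out_sb, out_v, out_om, out_aad = [], [], [], [], []
    processed = 0
    for iwin in range(nwin):
        for s, stream in zip(sims, streams):
            try:
                win, density, force = next(stream)
            except StopIteration:
                continue
            core.accumulate(acc, density, force)
            acc.hist += core._sample_histogram(win.samples, grid)
        processed += 1
        if processed in cps:
            cf = window_variance(acc)
            sb, v, om = global_metric(cf, acc.hist, vp)
            mask = largest_component(acc.hist > resolve_threshold(acc.hist, vp), grid)
            res = integrate_mean_force(acc.mean_force(), mask=mask, method=method)
            out_steps.append(processed * int(np.mean(steps_per_window)) * len(sims))
            out_sb.append(sb)
            out_v.append(v)
            out_om.append(om)
            out_aad.append(aad(res, reference, mask=mask))
    final_mask = largest_component(acc.hist > resolve_threshold(acc.hist, vp), grid)
    return CampaignMetrics(
        np.asarray(out_steps),
        np.asarray(out_sb),
        np.asarray(out_v),
        np.asarray(out_om),
        np.asarray(out_aad),
        core.SimulationForceRecord(acc, label="campaign"),
        final_mask,
    )


# ---------------------------------------------------------------------------
# umbrella sampling on a 1D quartic
# ---------------------------------------------------------------------------

US_QUARTIC_KT = 1.0
US_QUARTIC_LANGEVIN = dict(friction=1.0, mass=1.0, dt=0.005, sample_stride=5)
US_QUARTIC_KAPPA = 25.0


def us_quartic_campaign(
    nwindows: int = 12,
    steps_per_window: int = 50_000,
    seed: int = 0,
    nbins: int = 256,
    centers_span=(-1.4, 1.4),
    kappa: float = US_QUARTIC_KAPPA,
):
    """Umbrella-sampling campaign on the 1D quartic double well.

    ``nwindows`` harmonic restraints with equally spaced centers, each run
    started at its center.  Returns ``(records, grid, potential)`` where each
    record is the single-window MFI force record of one restraint.
    """
    pot = builtin_potential("quartic_doublewell_1d")
    grid = make_grid((-1.8, 1.8), nbins)
    centers = np.linspace(*centers_span, nwindows)
    specs = []
    for i, c in enumerate(centers):
        specs.append(
            dict(
                potential=pot,
                static_biases=(HarmonicBias((float(c),), (kappa,)),),
                metad=None,
                domain=grid,
                params=LangevinParams(
                    kT=US_QUARTIC_KT,
                    nsteps=steps_per_window,
                    initial_position=[float(c)],
                    seed=seed * 1000 + i,
                    **US_QUARTIC_LANGEVIN,
                ),
            )
        )
    sims = run_campaign(specs)
    # Silverman-style bandwidth from each window's own sample spread
    records = [
        core.analyze_simulation(s.trajectory, None, s.static_biases, grid, None, US_QUARTIC_KT,
                                label=f"window-{i}")
        for i, s in enumerate(sims)
    ]
    return records, grid, pot


def us_replica_ensemble(
    nreplicas: int = 20,
    nsteps: int = 30_000,
    seed: int = 0,
    nbins: int = 256,
    kappa: float = 0.5,
    bandwidth: float = 0.05,
):
    """Exchangeable US replicas on the 1D quartic for bootstrap validation.

    Every replica carries the same soft restraint (centered at the barrier
    top, weak enough that reversible well-to-well crossings stay frequent)
    and differs only in seed and starting well, so the per-simulation mean
    forces are independent draws from one distribution — the regime in which
    bootstrap resampling of whole simulations estimates the FES error.
    Returns ``(records, grid, potential)``.
    """
    pot = builtin_potential("quartic_doublewell_1d")
    grid = make_grid((-1.8, 1.8), nbins)
    specs = [
        dict(
            potential=pot,
            static_biases=(HarmonicBias((0.0,), (kappa,)),),
            metad=None,
            domain=grid,
            params=LangevinParams(
                kT=US_QUARTIC_KT,
                nsteps=nsteps,
                initial_position=[-1.0 if i % 2 else 1.0],
                seed=seed * 1000 + i,
                **US_QUARTIC_LANGEVIN,
            ),
        )
        for i in range(nreplicas)
    ]
    sims = run_campaign(specs)
    kde = core.KDEParams((bandwidth,))
    records = [
        core.analyze_simulation(s.trajectory, None, s.static_biases, grid, kde, US_QUARTIC_KT,
                                label=f"replica-{i}")
        for i, s in enumerate(sims)
    ]
    return records, grid, pot
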