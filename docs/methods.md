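# Methods

## Estimator

The package estimates the mean thermodynamic force in CV space and
integrates it, rather than estimating `F(s)` directly. For each time
window of constant bias, the biased probability density is a separable
Gaussian kernel-density estimate with per-axis bandwidth `h` and prefactor
`f_c / Π_a h_a`. The prefactor makes densities computed with different
bandwidths or sampling rates mutually comparable as weights, which is what
allows windows — and whole simulations — analyzed under different settings
to be merged. The window force is

```
f_i(s) = kT Σ_k (wrap(s − s_k)/h²) K_k / Σ_k K_k  −  Σ_b ∇V_b(s)
```

(the first term is identically `−kT ∇ ln p_i(s)`); the bias sum contains
the metadynamics potential frozen at the window start plus every declared
static bias. On periodic axes all displacements use the minimum image.
Window weights are the *unnormalized* kernel sums, so windows holding more
samples weigh proportionally more and the weighted average reduces to the
pooled-sample estimate when bandwidths agree.

All aggregation is streamed through four per-node accumulators
(`Σp`, `Σp·f`, `Σp·f²`, `Σp²` plus a raw sample histogram). These are
additive, which makes three operations exact by construction: merging
asynchronous simulations (weights `P_j = Σ_i p_i`), splitting a trajectory
at a window boundary and recombining, and computing running variances in a
single pass.

Window convention: window *i* spans `[t_i, t_i + τ)` (half-open; a sample
logged exactly at a deposition time belongs to the newly opened window) and
its metadynamics gradient uses hills with deposition time `≤ t_i`.
Well-tempered heights use the bias accumulated *before* the deposit,
evaluated at the deposit point, the convention of the common MD plugins.

## Numerical choices

* **Undefined vs zero.** Nodes where a window's kernel sum underflows
  (< 1e−300) contribute zero weight; nodes never reached have an undefined
  (NaN) mean force, never zero. Per-node variance requires `n_eff > 1`.
* **Sampled region.** Gaussian tails make `Σp > 0` nearly everywhere, so
  every statistic that claims a region is "explored" uses the biased sample
  histogram against a threshold (default: 1% of the mean count over nonzero
  nodes — deliberately a config knob, since any lower bound is a judgment
  call). Field-wide scores (AAD, bootstrap spreads) additionally restrict to
  the largest connected component: satellite islands carry independent
  integration gauges and would contaminate an average.
* **Integration.** 1D: cumulative trapezoid per contiguous segment. 2D: a
  least-squares solve of the staggered (midpoint) gradient system, either
  as sparse normal equations restricted to the mask (`fd`) or spectrally
  (`fft`) — the normal-equation operator is the 5-point Laplacian with
  Neumann (aperiodic) or periodic boundaries, diagonalized by DCT-II
  respectively Fourier modes; DCT-II is exactly the half-sample mirror
  extension, which avoids wrap-around artifacts. The spectral route solves
  globally on all finite force values (the MFI force is curl-free by
  construction, so unmasked values are consistent), with harmonic
  in-filling of non-finite holes; the mask then selects the reported
  region. Both report an RMS residual of their own gradient operator, so
  curl-carrying input is surfaced, not hidden. Disconnected explored
  components are gauged independently and counted. Gauge: min = 0 over the
  explored region; AAD instead mean-aligns both fields over the mask, to be
  offset-robust.
* **Bandwidth default.** Half the metadynamics hill width when hills are
  present (the hill width is a natural resolution scale the user already
  chose), else a Silverman-style rule from the sample spread, floored at
  one grid spacing; always overridable. Small `h` trades noise for bias:
  the KDE force carries an `O(h²)` systematic component, which is why the
  umbrella-sampling analyses below use explicit narrow bandwidths.
* **Convergence statistics.** Weighted variance with Kish effective sample
  size `n_eff = (Σw)²/Σw²`, Bessel correction `n_eff/(n_eff−1)`, standard
  error `σ/√n_eff`; with equal weights every quantity reduces to the
  unweighted textbook form (property-tested). Vector forces reduce to one
  scalar per node by the Euclidean norm of per-component standard errors;
  per-component fields are kept for inspection. The same structure applies
  across simulations with weights `P_j(s)`. Bootstrap resamples whole
  simulations only — windows within a run are serially correlated.
* **σ_E is a convergence indicator**, not a calibrated error bar: at small
  effective sample sizes the window forces are correlated and the variance
  underestimates. The package therefore validates it only through its
  correlation with the true error (below) and through order-of-magnitude
  bootstrap coverage.

## Simulator

The bundled data source is underdamped Langevin dynamics whose particle
position is the CV (configuration space and CV space coincide). The
integrator is BAOAB splitting — accurate configurational sampling at
moderate time steps; its symplectic part reduces to velocity Verlet in the
zero-friction limit, which the tests use for an energy-drift check. Hills
are deposited inside the integration loop (heights tempered against the
current bias), so trajectories and hill logs are generated jointly and
bit-reproducibly from one explicit seed per run. Trajectories leaving the
declared domain by more than a margin abort loudly — that is a missing-wall
or unstable-time-step diagnostic, not a recoverable state.

Two analytic families serve as ground truth: a 2D double-well quartic
polynomial widely used as an enhanced-sampling benchmark (built-in
`doublewell_2d`; minima near (−1.87, 0.78) and (1.78, −0.83), separated by
a barrier of ~18 kT at kT = 1) and configurable 1D profiles (Gaussian wells
plus centered polynomial terms; built-ins `multiwell_1d`, a five-well
profile on [−0.2, 1.2] with a late metastable state near s = 0.8, and
`quartic_doublewell_1d`, `s⁴ − 2s²`).

## Study conditions (frozen defaults)

The benchmark protocols in `mfi.protocols` fix the following, chosen once
during development so that the campaigns behave qualitatively like real
metadynamics practice (barrier crossings occur, the error decays) and not
revisited:

* **2D campaign** — kT = 1, dt = 0.005, friction 1, mass 1; WTmetaD hills
  w₀ = 1 kT, σ = 0.25, pace 200 steps, bias factor 10; 10 runs × 2·10⁵
  steps, uniform random starts; analysis on a 64×64 grid over [−3,3]² with
  h = 0.125 (= σ_M/2). Every run crosses the barrier under these settings.
* **Umbrella campaign (1D quartic)** — 12 windows, κ = 25, centers spanning
  [−1.4, 1.4], 5·10⁴ steps each, Silverman bandwidth per window.
* **Bootstrap ensemble** — 20 exchangeable replicas with one soft restraint
  (κ = 0.5 at the barrier top) and alternating starting wells, 3·10⁴ steps,
  h = 0.05. Exchangeability is deliberate: bootstrap resampling estimates
  the spread of independent draws from one distribution, which stratified
  single-window records are not.
* Checkpoints default to every window; the campaign analyses record 10
  equally spaced checkpoints. Problem sizes throughout are chosen so the
  full test suite and the measurement script run in minutes on one CPU
  while leaving clear margins to their thresholds.

## What the toy systems do and do not show

The Langevin models share with real MD the entire analysis-side problem:
history-dependent biases, window bookkeeping, merging heterogeneous runs,
convergence estimation. They do *not* emulate high-dimensional hidden
degrees of freedom, CV-dependent diffusion, or imperfect CVs; passing
recovery tests here demonstrates the correctness of the estimator and its
implementation, not that a given bias protocol suffices for a particular
molecular system. Multivariate (non-diagonal) hills and >2D CV spaces are
out of scope; the mean-force-integration route itself becomes impractical
beyond ~3 CVs.

## Validation summary

The test suite checks, among others: exact values and gradients of the
built-in polynomial; split/recombine exactness (≤1e−12 on sampled nodes);
weighted statistics against brute-force oracles (≤1e−12) and their
equal-weight reduction; umbrella recovery of the quartic (AAD < 0.1 kT);
10-run WTmetaD recovery of the 2D double well (final AAD < 1 kT, decreasing
in time; majority over repeated seeds); Pearson r ≥ 0.7 between Ω and
AAD/v (measured ≈ 0.99); integrator round trips (< 1e−6 RMS) and FD/FFT
agreement (AAD < 0.02 on the analytic surface); bootstrap std of identical
records ≡ 0 and 3σ coverage of the true FES error at ≥ 80% of sampled
nodes (majority over seeds). `scripts/acceptance.py` recomputes all of
these quantities from scratch.

## Known limitations

* The bootstrap underestimates error components shared by all replicas
  (bandwidth bias, identical protocols); its one-sided 3σ coverage is the
  honest claim, not calibrated pointwise bars.
* KDE bandwidth bias is `O(h²·F‴)`: steep surfaces analyzed with wide
  kernels acquire systematic force errors. Use `h` well below the scale of
  FES curvature variations.
* Restart handling in the PLUMED readers keeps the later of overlapping
  time blocks (with a loud warning); interleaved multiple-walker files are
  not supported.
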