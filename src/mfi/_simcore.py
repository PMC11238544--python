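"""Numba inner loop for biased underdamped Langevin dynamics.

Potentials and biases are passed as flat parameter arrays so the whole
trajectory (including on-the-fly hill deposition) runs inside one jitted
function.  Two potential kinds are supported:

* kind 0 — 1D: Gaussian wells (depth, center, width) plus centered
  polynomial terms (coef, center, power);
* kind 1 — 2D polynomial: terms (i, j, coef) meaning coef * s1^i * s2^j.

Static biases: per-axis harmonic restraints and one-sided power-law walls.
The metadynamics bias is evaluated by direct summation over deposited hills
with a 6.5-sigma distance cutoff per axis.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_ESCAPED = 1


@njit(cache=True)
def _pot_value_grad(kind, ndim, p2i, p2j, p2c, gA, gc, gw, p1c, p1cen, p1p, x, grad):
    """Potential value at x; gradient written into grad (accumulated from zero)."""
    v = 0.0
    for a in range(ndim):
        grad[a] = 0.0
    if kind == 0:
        s = x[0]
        for k in range(gA.shape[0]):
            d = s - gc[k]
            e = np.exp(-d * d / (2.0 * gw[k] * gw[k]))
            v -= gA[k] * e
            grad[0] += gA[k] * d / (gw[k] * gw[k]) * e
        for k in range(p1c.shape[0]):
            d = s - p1cen[k]
            p = p1p[k]
            v += p1c[k] * d**p
            if p > 0:
                grad[0] += p1c[k] * p * d ** (p - 1)
    else:
        s1 = x[0]
        s2 = x[1]
        for k in range(p2c.shape[0]):
            i = p2i[k]
            j = p2j[k]
            c = p2c[k]
            v += c * s1**i * s2**j
            if i > 0:
                grad[0] += c * i * s1 ** (i - 1) * s2**j
            if j > 0:
                grad[1] += c * j * s1**i * s2 ** (j - 1)
    return v


@njit(cache=True)
def _wrap(d, period, is_per):
    if is_per:
        return d - period * np.round(d / period)
    return d


@njit(cache=True)
def _metad_value_grad(x, nh, hc, hh, sigma_m, periodic, period, ndim, grad):
    """Accumulated hill bias value at x; +dV/ds added into grad. 6.5 sigma cutoff."""
    v = 0.0
    for k in range(nh):
        expo = 0.0
        skip = False
        for a in range(ndim):
            d = _wrap(x[a] - hc[k, a], period[a], periodic[a])
            if np.abs(d) > 6.5 * sigma_m[a]:
                skip = True
                break
            expo += (d / sigma_m[a]) ** 2
        if skip:
            continue
        e = hh[k] * np.exp(-0.5 * expo)
        v += e
        for a in range(ndim):
            d = _wrap(x[a] - hc[k, a], period[a], periodic[a])
            grad[a] += -d / (sigma_m[a] * sigma_m[a]) * e
    return v


@njit(cache=True)
def langevin_metad_core(
    kind, ndim,
    p2i, p2j, p2c,               # 2D polynomial terms
    gA, gc, gw, p1c, p1cen, p1p,  # 1D wells + centered polynomial
    harm_c, harm_k,              # (nharm, ndim)
    wall_ax, wall_thr, wall_sgn, wall_k, wall_p,  # (nwall,)
    lo, hi, periodic, margin,    # domain
    use_metad, w0, sigma_m, pace, gamma, kT_wt,
    kT, friction, mass, dt, nsteps, stride, x0, seed,
):
    """BAOAB underdamped Langevin under potential + static + metadynamics bias.

    Returns (samples, hill_centers, hill_heights, hill_times, nhills, status).
    One RNG seeded per call; noise is drawn once per step in a fixed order so
    the stored-sample stride never affects the path.
    """
    np.random.seed(seed)
    period = np.empty(ndim)
    for a in range(ndim):
        period[a] = hi[a] - lo[a]

    maxh = nsteps // pace + 1 if use_metad else 0
    hc = np.zeros((max(maxh, 1), ndim))
    hh = np.zeros(max(maxh, 1))
    ht = np.zeros(max(maxh, 1))
    nh = 0

    nsamp = nsteps // stride
    samples = np.zeros((nsamp, ndim))
    isamp = 0

    x = x0.copy()
    v = np.empty(ndim)
    for a in range(ndim):
        v[a] = np.sqrt(kT / mass) * np.random.normal()

    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sig_v = np.sqrt(kT / mass)

    pgrad = np.empty(ndim)
    mgrad = np.empty(ndim)
    f = np.empty(ndim)

    # total force at the initial position
    _pot_value_grad(kind, ndim, p2i, p2j, p2c, gA, gc, gw, p1c, p1cen, p1p, x, pgrad)
    for a in range(ndim):
        mgrad[a] = 0.0
    if use_metad:
        _metad_value_grad(x, nh, hc, hh, sigma_m, periodic, period, ndim, mgrad)
    for a in range(ndim):
        f[a] = -pgrad[a] - mgrad[a]
    for m in range(harm_c.shape[0]):
        for a in range(ndim):
            d = _wrap(x[a] - harm_c[m, a], period[a], periodic[a])
            f[a] -= harm_k[m, a] * d
    for m in range(wall_ax.shape[0]):
        a = wall_ax[m]
        d = wall_sgn[m] * (x[a] - wall_thr[m])
        if d > 0.0:
            f[a] -= wall_sgn[m] * wall_k[m] * wall_p[m] * d ** (wall_p[m] - 1)

    status = STATUS_OK
    for n in range(1, nsteps + 1):
        # B (half kick)
        for a in range(ndim):
            v[a] += 0.5 * dt * f[a] / mass
        # A (half drift)
        for a in range(ndim):
            x[a] += 0.5 * dt * v[a]
        # O (thermostat)
        for a in range(ndim):
            v[a] = c1 * v[a] + c2 * sig_v * np.random.normal()
        # A
        for a in range(ndim):
            x[a] += 0.5 * dt * v[a]
        # wrap periodic axes into [lo, hi)
        for a in range(ndim):
            if periodic[a]:
                x[a] = lo[a] + np.mod(x[a] - lo[a], period[a])
        # recompute force at the new position
        _pot_value_grad(kind, ndim, p2i, p2j, p2c, gA, gc, gw, p1c, p1cen, p1p, x, pgrad)
        for a in range(ndim):
            mgrad[a] = 0.0
        if use_metad and nh > 0:
            _metad_value_grad(x, nh, hc, hh, sigma_m, periodic, period, ndim, mgrad)
        for a in range(ndim):
            f[a] = -pgrad[a] - mgrad[a]
        for m in range(harm_c.shape[0]):
            for a in range(ndim):
                d = _wrap(x[a] - harm_c[m, a], period[a], periodic[a])
                f[a] -= harm_k[m, a] * d
        for m in range(wall_ax.shape[0]):
            a = wall_ax[m]
            d = wall_sgn[m] * (x[a] - wall_thr[m])
            if d > 0.0:
                f[a] -= wall_sgn[m] * wall_k[m] * wall_p[m] * d ** (wall_p[m] - 1)
        # B (half kick)
        for a in range(ndim):
            v[a] += 0.5 * dt * f[a] / mass

        # escape check on aperiodic axes
        for a in range(ndim):
            if not periodic[a] and (x[a] < lo[a] - margin or x[a] > hi[a] + margin):
                status = STATUS_ESCAPED
        if status != STATUS_OK:
            break

        # hill deposition (before sample storage at the same step)
        if use_metad and n % pace == 0 and n < nsteps:
            gtmp = np.empty(ndim)
            for a in range(ndim):
                gtmp[a] = 0.0
            vcur = _metad_value_grad(x, nh, hc, hh, sigma_m, periodic, period, ndim, gtmp)
            if gamma > 1.0:
                h = w0 * np.exp(-vcur / ((gamma - 1.0) * kT_wt))
            else:
                h = w0
            for a in range(ndim):
                hc[nh, a] = x[a]
            hh[nh] = h
            ht[nh] = n * dt
            nh += 1
            # refresh the cached force so the new hill acts from the next step
            for a in range(ndim):
                mgrad[a] = 0.0
            _metad_value_grad(x, nh, hc, hh, sigma_m, periodic, period, ndim, mgrad)
            _pot_value_grad(kind, ndim, p2i, p2j, p2c, gA, gc, gw, p1c, p1cen, p1p, x, pgrad)
            for a in range(ndim):
                f[a] = -pgrad[a] - mgrad[a]
            for m in range(harm_c.shape[0]):
                for a in range(ndim):
                    d = _wrap(x[a] - harm_c[m, a], period[a], periodic[a])
                    f[a] -= harm_k[m, a] * d
            for m in range(wall_ax.shape[0]):
                a = wall_ax[m]
                d = wall_sgn[m] * (x[a] - wall_thr[m])
                if d > 0.0:
                    f[a] -= wall_sgn[m] * wall_k[m] * wall_p[m] * d ** (wall_p[m] - 1)

        if n % stride == 0:
            for a in range(ndim):
                samples[isamp, a] = x[a]
            isamp += 1

    return samples[:isamp], hc[:nh], hh[:nh], ht[:nh], nh, status
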