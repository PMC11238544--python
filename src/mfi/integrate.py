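"""Numerical integration of the mean force field into a free-energy surface.

The input is the field dF/ds on the analysis grid (NaN on unexplored
nodes).  1D uses a cumulative trapezoid per contiguous explored segment.
2D offers two routes:

* ``fft`` — least-squares solution of the gradient system in a Fourier
  basis.  Aperiodic axes are mirror (even) extended, which suppresses the
  wrap-around artifacts of naive Fourier integration; periodic axes use the
  plain FFT.  Unexplored nodes are zero-filled for the solve and masked in
  the output.
* ``fd`` — sparse least squares of the staggered finite-difference gradient
  system restricted to explored nodes; disconnected explored components are
  gauged independently and the segment count is reported.

Both methods report a residual (RMS of their own gradient operator applied
to the reconstruction minus the input force over the explored region), so
an inconsistent (curl-carrying) input is surfaced rather than hidden.
The FES gauge is min = 0 over the explored region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .grid import Grid, ScalarField, VectorField

__all__ = [
    "FESResult",
    "integrate_1d",
    "integrate_2d_fft",
    "integrate_2d_fd",
    "integrate_mean_force",
    "aad",
]


@dataclass
class FESResult:
    fes: ScalarField
    explored_mask: np.ndarray
    method: str
    residual: float
    n_segments: int = 1

    @property
    def grid(self) -> Grid:
        return self.fes.grid


def _force_mask(force: VectorField, mask):
    m = np.ones(force.grid.shape, bool) if mask is None else np.asarray(mask, bool).copy()
    for c in force.components:
        m &= np.isfinite(c)
    return m


def integrate_1d(force: VectorField, mask=None) -> FESResult:
    """Cumulative-trapezoid integral of dF/ds over each explored segment."""
    grid = force.grid
    if grid.ndim != 1:
        raise ValueError("integrate_1d requires a 1D grid")
    m = _force_mask(force, mask)
    g = np.where(m, force.components[0], 0.0)
    d = grid.spacing[0]
    fes = np.full(grid.shape, np.nan)
    # contiguous explored segments
    idx = np.flatnonzero(m)
    nseg = 0
    if len(idx):
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for seg in splits:
            nseg += 1
            vals = np.zeros(len(seg))
            vals[1:] = np.cumsum(0.5 * (g[seg[1:]] + g[seg[:-1]]) * d)
            fes[seg] = vals - vals.min()
    if m.any():
        fes[m] -= np.nanmin(fes[m])
    resid = _fd_residual_1d(fes, g, m, d)
    return FESResult(ScalarField(grid, fes), m, "fd", resid, max(nseg, 1))


def _fd_residual_1d(fes, g, m, d):
    errs = []
    idx = np.flatnonzero(m)
    if len(idx) > 1:
        adj = np.diff(idx) == 1
        a = idx[:-1][adj]
        b = idx[1:][adj]
        if len(a):
            pred = (fes[b] - fes[a]) / d
            tgt = 0.5 * (g[a] + g[b])
            errs = pred - tgt
    return float(np.sqrt(np.mean(np.square(errs)))) if len(errs) else 0.0


# ---------------------------------------------------------------------------
# 2D spectral least squares
# ---------------------------------------------------------------------------


def _harmonic_extend(arr, m, grid: Grid) -> np.ndarray:
    """Fill nodes outside the mask by solving the discrete Laplace equation
    with the masked values as Dirichlet data (smooth, curl-poor in-filling
    so the global Fourier solve is not polluted by unexplored nodes)."""
    out = np.where(m, arr, 0.0)
    holes = ~m
    n = int(holes.sum())
    if n == 0 or not m.any():
        return out
    nx, ny = grid.shape
    hid = -np.ones(grid.shape, dtype=np.int64)
    hid[holes] = np.arange(n)
    ii, jj = np.nonzero(holes)
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    deg = np.zeros(n)
    for di, dj, axis in ((1, 0, 0), (-1, 0, 0), (0, 1, 1), (0, -1, 1)):
        ni, nj = ii + di, jj + dj
        if grid.periodic[axis]:
            ni, nj = ni % nx, nj % ny
            ok = np.ones(len(ni), bool)
        else:
            ok = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny)
        src = hid[ii[ok], jj[ok]]
        nbr_hole = holes[ni[ok], nj[ok]]
        np.add.at(deg, src, 1.0)
        # neighbor inside a hole -> matrix entry; else -> rhs
        rows.append(src[nbr_hole])
        cols.append(hid[ni[ok][nbr_hole], nj[ok][nbr_hole]])
        vals.append(-np.ones(int(nbr_hole.sum())))
        np.add.at(b, src[~nbr_hole], arr[ni[ok][~nbr_hole], nj[ok][~nbr_hole]])
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ) + sp.diags(np.maximum(deg, 1.0))
    x = spla.spsolve(A.tocsc(), b)
    out[holes] = x
    return out


def _staggered_rhs(gx, gy, grid: Grid):
    """Normal-equation right-hand side A^T b of the staggered gradient system.

    Edge targets are midpoint averages of the node forces; aperiodic axes use
    open chains (Neumann), periodic axes wrap.
    """
    dx, dy = grid.spacing
    r = np.zeros(grid.shape)
    if grid.periodic[0]:
        e = 0.5 * (gx + np.roll(gx, -1, axis=0))
        r -= e / dx
        r += np.roll(e, 1, axis=0) / dx
    else:
        e = 0.5 * (gx[:-1, :] + gx[1:, :])
        r[:-1, :] -= e / dx
        r[1:, :] += e / dx
    if grid.periodic[1]:
        e = 0.5 * (gy + np.roll(gy, -1, axis=1))
        r -= e / dy
        r += np.roll(e, 1, axis=1) / dy
    else:
        e = 0.5 * (gy[:, :-1] + gy[:, 1:])
        r[:, :-1] -= e / dy
        r[:, 1:] += e / dy
    return r


def _staggered_residual(fes, gx, gy, m, grid: Grid):
    """RMS of the staggered gradient of the reconstruction minus the input
    force over edges internal to the mask."""
    dx, dy = grid.spacing
    errs = []
    ok = m[:-1, :] & m[1:, :]
    if ok.any():
        errs.append(((fes[1:, :] - fes[:-1, :]) / dx - 0.5 * (gx[:-1, :] + gx[1:, :]))[ok])
    ok = m[:, :-1] & m[:, 1:]
    if ok.any():
        errs.append(((fes[:, 1:] - fes[:, :-1]) / dy - 0.5 * (gy[:, :-1] + gy[:, 1:]))[ok])
    if grid.periodic[0]:
        ok = m[-1, :] & m[0, :]
        if ok.any():
            errs.append(((fes[0, :] - fes[-1, :]) / dx - 0.5 * (gx[-1, :] + gx[0, :]))[ok])
    if grid.periodic[1]:
        ok = m[:, -1] & m[:, 0]
        if ok.any():
            errs.append(((fes[:, 0] - fes[:, -1]) / dy - 0.5 * (gy[:, -1] + gy[:, 0]))[ok])
    if not errs:
        return 0.0
    return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))


def integrate_2d_fft(force: VectorField, mask=None) -> FESResult:
    """Fast-transform least squares solve of the gradient system.

    Solves the same staggered least-squares problem as the sparse FD route,
    but spectrally: the normal-equation operator is the 5-point Laplacian
    with Neumann (aperiodic) or periodic boundaries, diagonalized by DCT-II
    modes (the half-sample mirror extension) resp. plain Fourier modes.

    The solve is global: it uses the force field at every node where it is
    finite (the MFI mean force is curl-free by construction, being the
    gradient of ``-kT ln p - V``), harmonically in-filling non-finite holes.
    ``mask`` only restricts the *reported* explored region, the residual and
    the gauge; FES values outside it are NaN.
    """
    grid = force.grid
    if grid.ndim != 2:
        raise ValueError("integrate_2d_fft requires a 2D grid")
    m = _force_mask(force, mask)
    finite = _force_mask(force, None)
    gx = _harmonic_extend(force.components[0], finite, grid)
    gy = _harmonic_extend(force.components[1], finite, grid)

    nx, ny = grid.nbins
    dx, dy = grid.spacing
    r = _staggered_rhs(gx, gy, grid)

    # eigenvalues of the per-axis second-difference operator
    if grid.periodic[0]:
        lam_x = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(nx) / nx)) / dx**2
    else:
        lam_x = (2.0 - 2.0 * np.cos(np.pi * np.arange(nx) / nx)) / dx**2
    if grid.periodic[1]:
        lam_y = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(ny) / ny)) / dy**2
    else:
        lam_y = (2.0 - 2.0 * np.cos(np.pi * np.arange(ny) / ny)) / dy**2

    rhat = r.astype(complex) if any(grid.periodic) else r
    rhat = (scipy.fft.fft(rhat, axis=0) if grid.periodic[0]
            else scipy.fft.dct(rhat, type=2, axis=0))
    rhat = (scipy.fft.fft(rhat, axis=1) if grid.periodic[1]
            else scipy.fft.dct(rhat, type=2, axis=1))
    lam = lam_x[:, None] + lam_y[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        fhat = np.where(lam > 0, rhat / np.where(lam > 0, lam, 1.0), 0.0)
    fhat = (scipy.fft.ifft(fhat, axis=1) if grid.periodic[1]
            else scipy.fft.idct(fhat, type=2, axis=1))
    fhat = (scipy.fft.ifft(fhat, axis=0) if grid.periodic[0]
            else scipy.fft.idct(fhat, type=2, axis=0))
    fes = np.real(fhat).copy()

    if m.any():
        resid = _staggered_residual(fes, gx, gy, m, grid)
        fes[~m] = np.nan
        fes -= np.nanmin(fes[m])
    else:
        resid = 0.0
        fes[:] = np.nan
    return FESResult(ScalarField(grid, fes), m, "fft", resid, 1)


# ---------------------------------------------------------------------------
# 2D sparse finite-difference least squares
# ---------------------------------------------------------------------------


def _edges(grid: Grid, m):
    """Staggered-difference edges between adjacent explored nodes.

    Each edge is ``(id_a, id_b, axis, (ia, ja), (ib, jb))`` linking node a to
    its +1 neighbor b along ``axis``; periodic axes also link last-to-first.
    """
    nx, ny = grid.nbins
    node_id = -np.ones(grid.shape, dtype=np.int64)
    node_id[m] = np.arange(int(m.sum()))
    edges = []
    for axis in range(2):
        ii, jj = np.indices(grid.shape)
        if grid.periodic[axis]:
            ia, ja = ii.ravel(), jj.ravel()
        else:
            keep = (ii < nx - 1) if axis == 0 else (jj < ny - 1)
            ia, ja = ii[keep], jj[keep]
        if axis == 0:
            ib, jb = (ia + 1) % nx, ja
        else:
            ib, jb = ia, (ja + 1) % ny
        ok = m[ia, ja] & m[ib, jb]
        ia, ja, ib, jb = ia[ok], ja[ok], ib[ok], jb[ok]
        edges.append((node_id[ia, ja], node_id[ib, jb], axis, (ia, ja), (ib, jb)))
    return node_id, edges


def integrate_2d_fd(force: VectorField, mask=None) -> FESResult:
    """Sparse least-squares solve of the staggered gradient system on the mask."""
    grid = force.grid
    if grid.ndim != 2:
        raise ValueError("integrate_2d_fd requires a 2D grid")
    m = _force_mask(force, mask)
    n = int(m.sum())
    fes = np.full(grid.shape, np.nan)
    if n == 0:
        return FESResult(ScalarField(grid, fes), m, "fd", 0.0, 0)
    node_id, edges = _edges(grid, m)
    gx, gy = (np.where(m, c, 0.0) for c in force.components)
    gcomp = (gx, gy)

    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    for id_a, id_b, axis, loc_a, loc_b in edges:
        ne = len(id_a)
        if ne == 0:
            continue
        d = grid.spacing[axis]
        r = eq + np.arange(ne)
        rows.append(np.repeat(r, 2))
        cols.append(np.stack([id_b, id_a], axis=1).ravel())
        vals.append(np.tile([1.0 / d, -1.0 / d], ne))
        rhs.append(0.5 * (gcomp[axis][loc_a] + gcomp[axis][loc_b]))
        eq += ne
    if eq:
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(eq, n),
        )
        b = np.concatenate(rhs)
    else:
        A = sp.csr_matrix((0, n))
        b = np.zeros(0)

    # connected components for anchoring / independent gauges
    adj_r = np.concatenate([e[0] for e in edges]) if edges else np.zeros(0, int)
    adj_c = np.concatenate([e[1] for e in edges]) if edges else np.zeros(0, int)
    adj = sp.csr_matrix((np.ones(len(adj_r)), (adj_r, adj_c)), shape=(n, n))
    ncomp, labels = csgraph.connected_components(adj, directed=False)

    anchors = sp.csr_matrix(
        (np.ones(ncomp), (np.arange(ncomp), [int(np.argmax(labels == c)) for c in range(ncomp)])),
        shape=(ncomp, n),
    )
    Afull = sp.vstack([A, anchors]).tocsr()
    bfull = np.concatenate([b, np.zeros(ncomp)])
    AtA = (Afull.T @ Afull).tocsc()
    x = spla.spsolve(AtA, Afull.T @ bfull)

    fes[m] = x
    # independent gauge per connected component: min = 0
    flat_labels = np.full(grid.shape, -1, int)
    flat_labels[m] = labels
    for c in range(ncomp):
        sel = flat_labels == c
        fes[sel] -= fes[sel].min()
    resid = float(np.sqrt(np.mean((A @ x - b) ** 2))) if eq else 0.0
    return FESResult(ScalarField(grid, fes), m, "fd", resid, ncomp)


def integrate_mean_force(force: VectorField, mask=None, method: str = "auto") -> FESResult:
    """Dispatch: 1D trapezoid, or 2D 'fft' (default) / 'fd'."""
    if force.grid.ndim == 1:
        return integrate_1d(force, mask)
    if method in ("auto", "fft"):
        return integrate_2d_fft(force, mask)
    if method == "fd":
        return integrate_2d_fd(force, mask)
    raise ValueError(f"unknown integration method {method!r}")


def largest_component(mask, grid: Grid | None = None) -> np.ndarray:
    """Largest 4-connected component of a boolean mask (periodic axes wrap).

    Satellite islands of a sampled region carry independent integration
    gauges, so field-wide statistics (AAD, bootstrap spreads) are computed
    on the main component.
    """
    from scipy import ndimage

    mask = np.asarray(mask, bool)
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask.copy()
    if grid is not None and any(grid.periodic):
        # merge labels across periodic seams
        parent = {k: k for k in range(1, n + 1)}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        seams = []
        if mask.ndim == 1:
            if grid.periodic[0]:
                seams.append((lab[0], lab[-1]))
        else:
            if grid.periodic[0]:
                seams += list(zip(lab[0, :], lab[-1, :]))
            if grid.periodic[1]:
                seams += list(zip(lab[:, 0], lab[:, -1]))
        for a, b in seams:
            if a and b:
                union(int(a), int(b))
        roots = np.zeros(n + 1, int)
        for k in range(1, n + 1):
            roots[k] = find(k)
        lab = roots[lab]
    labels, counts = np.unique(lab[lab > 0], return_counts=True)
    return lab == labels[np.argmax(counts)]


def aad(fes, reference, mask=None) -> float:
    """Average absolute deviation after gauge alignment over the mask.

    Both fields are shifted to zero mean over the mask before differencing,
    so the arbitrary FES offset does not contribute.
    """
    f = fes.fes.values if isinstance(fes, FESResult) else np.asarray(
        fes.values if isinstance(fes, ScalarField) else fes, dtype=float
    )
    r = np.asarray(reference.values if isinstance(reference, ScalarField) else reference, dtype=float)
    if mask is None:
        mask = np.isfinite(f) & np.isfinite(r)
        if isinstance(fes, FESResult):
            mask &= fes.explored_mask
    else:
        mask = np.asarray(mask, bool) & np.isfinite(f) & np.isfinite(r)
    if not mask.any():
        raise ValueError("empty mask in AAD")
    df = f[mask] - f[mask].mean()
    dr = r[mask] - r[mask].mean()
    return float(np.mean(np.abs(df - dr)))
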