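"""Multidimensional, periodicity-aware WHAM.

The weighted histogram analysis method combines the biased histograms
{n_i(b)} of all windows into one unbiased bin probability

    P(b) = sum_i n_i(b) / sum_i N_i exp(beta (F_i - w_i(b))),

with the per-window offsets determined self-consistently from

    F_i = -(1/beta) ln sum_b P(b) exp(-beta w_i(b)),

iterated until max_i |dF_i| < tol.  The PMF is A(b) = -(1/beta) ln P(b),
shifted so its minimum over sampled bins is zero.  Bins never visited by
any window are masked, not assigned an infinite PMF: the exploration loop
deliberately samples only part of the space and masked bins are excluded
from normalization and parent-selection queries.

All exponentials are taken in log space (logsumexp), so widely separated
windows and deep wells do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .space import ReactionSpace, wrap_point
from .windows import BiasPotential, bias_energy_grid

DEFAULT_TOL = 1e-7       # kJ/mol on max|dF_i|
DEFAULT_MAX_ITER = 100_000
DEFAULT_BINS = 60        # per dihedral dimension over (-pi, pi]


class WhamConvergenceError(RuntimeError):
    def __init__(self, iterations, residual, tol):
        self.iterations, self.residual, self.tol = iterations, residual, tol
        super().__init__(
            f"WHAM did not converge in {iterations} iterations: "
            f"final max|dF| = {residual:.3e} > tol {tol:.1e}"
        )


class WindowOverlapError(RuntimeError):
    """A window shares no occupied bins with the rest (histograms disconnected)."""


class OutOfExploredRegionError(ValueError):
    """PMF query in a bin no window ever visited."""


@dataclass
class HistogramGrid:
    """Per-window histograms on one shared grid.

    counts has shape (n_windows, *bins_per_dim); totals are the raw sample
    counts N_i.  Counts are stored as floats so that exact (Boltzmann-
    integrated) histograms can be supplied in place of sampled ones.
    """

    bin_edges: list          # per-dimension arrays, len bins+1
    counts: np.ndarray
    totals: np.ndarray
    space: ReactionSpace

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple:
        return self.counts.shape[1:]

    @property
    def bin_centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.bin_edges]

    def centers_matrix(self) -> np.ndarray:
        """(n_bins_total, dim) array of all bin centers, C-order."""
        grids = np.meshgrid(*self.bin_centers, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)


@dataclass
class PMFGrid:
    """Binned unbiased PMF with window offsets and convergence metadata."""

    bin_centers: list
    pmf: np.ndarray           # energy per bin; nan where masked
    mask: np.ndarray          # True where the bin is unsampled
    offsets: np.ndarray       # F_i per window
    space: ReactionSpace
    iterations: int = 0
    residual: float = np.nan
    residual_history: np.ndarray = field(default=None)

    @property
    def dim(self) -> int:
        return len(self.bin_centers)

    @property
    def shape(self) -> tuple:
        return self.pmf.shape

    def min_position(self) -> np.ndarray:
        idx = np.unravel_index(np.nanargmin(np.where(self.mask, np.nan,
                                                     self.pmf)), self.shape)
        return np.array([c[i] for c, i in zip(self.bin_centers, idx)])


def default_edges(space: ReactionSpace, bins, ranges=None) -> list:
    """Shared bin edges: principal domain for periodic dims, ranges otherwise."""
    bins = np.broadcast_to(np.asarray(bins, dtype=int), (space.dim,))
    edges = []
    for j in range(space.dim):
        if bins[j] < 10:
            raise ValueError(f"need >= 10 bins per dimension, got {bins[j]}")
        if space.periodic[j]:
            L = space.period[j]
            edges.append(np.linspace(-L / 2, L / 2, bins[j] + 1))
        else:
            if ranges is None or ranges[j] is None:
                raise ValueError(
                    f"non-periodic dimension {j} needs an explicit range")
            lo, hi = ranges[j]
            edges.append(np.linspace(lo, hi, bins[j] + 1))
    return edges


def build_histograms(timeseries: Sequence, space: ReactionSpace,
                     bins=DEFAULT_BINS, ranges=None) -> HistogramGrid:
    """Histogram each window's samples on one shared grid.

    Samples are wrapped into the principal domain first; on periodic
    dimensions the domain endpoints -L/2 and +L/2 fall in the boundary
    bins' shared edge, i.e. binning wraps around.  Non-periodic dimensions
    need `ranges` (per-dimension (lo, hi)); if omitted they default to the
    pooled data range.
    """
    series = []
    for k, ts in enumerate(timeseries):
        X = np.asarray(ts, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] == 0:
            raise ValueError(f"window {k} has an empty time series")
        series.append(wrap_point(space, X))
    if ranges is None and not all(space.periodic):
        pooled = np.vstack(series)
        ranges = [None if space.periodic[j]
                  else (pooled[:, j].min(), pooled[:, j].max() + 1e-12)
                  for j in range(space.dim)]
    edges = default_edges(space, bins, ranges)
    counts = []
    for X in series:
        h, _ = np.histogramdd(X, bins=edges)
        counts.append(h)
    counts = np.asarray(counts, dtype=float)
    totals = np.array([X.shape[0] for X in series], dtype=float)
    return HistogramGrid(bin_edges=edges, counts=counts, totals=totals,
                         space=space)


def _check_overlap(counts2d: np.ndarray):
    occupied = counts2d > 0
    if counts2d.shape[0] < 2:
        return
    for i in range(counts2d.shape[0]):
        others = np.delete(occupied, i, axis=0).any(axis=0)
        if not (occupied[i] & others).any():
            raise WindowOverlapError(
                f"window {i} shares no occupied bins with any other window")


def wham_solve(hist: HistogramGrid, biases: Sequence[BiasPotential],
               space: ReactionSpace | None = None, tol: float = DEFAULT_TOL,
               max_iter: int = DEFAULT_MAX_ITER,
               f_init: np.ndarray | None = None,
               min_counts: float = 0.0,
               coverage: np.ndarray | None = None,
               bias_energies: np.ndarray | None = None,
               accelerate: bool = True) -> PMFGrid:
    """Self-consistent WHAM solve on the histogram grid.

    `f_init` warm-starts the offsets (the explorer passes the previous
    iteration's solution).  Raises WhamConvergenceError if max|dF| does not
    fall below `tol` within `max_iter` sweeps, and WindowOverlapError if
    some window's histogram is disconnected from the rest.

    Bins with pooled counts below `min_counts` are masked as unsampled.
    A stray count in a bin far from every bias center carries an enormous
    unbiasing factor exp(beta*omega) and would otherwise be assigned an
    absurdly low PMF, corrupting the min=0 normalization; explorers over
    sampled data should set this to a few counts (the default 0 only
    drops empty bins and leaves exact/noise-free histograms untouched).
    `coverage` (boolean, bin-grid shape) restricts the solve to bins the
    windows actually cover (e.g. within 2.5 Mahalanobis of a window mean);
    rare-excursion counts outside it are ignored.
    """
    space = space or hist.space
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if len(biases) != hist.n_windows:
        raise ValueError("one bias per window required")
    if np.any(hist.counts.reshape(hist.n_windows, -1).sum(axis=1) == 0):
        raise ValueError("every window must contribute at least one count")

    shape = hist.shape
    counts = hist.counts.reshape(hist.n_windows, -1)
    _check_overlap(counts)
    N = hist.totals
    beta = space.beta
    if bias_energies is None:
        centers = hist.centers_matrix()
        bias_energies = np.stack([bias_energy_grid(b, centers, space)
                                  for b in biases])
    # beta * w_i(b), shape (n_windows, n_bins)
    bw = beta * bias_energies

    M = counts.sum(axis=0)                    # total counts per bin
    sampled = (M > 0) & (M >= min_counts)
    if coverage is not None:
        sampled &= np.asarray(coverage, dtype=bool).ravel()
    if not sampled.any():
        raise ValueError("no sampled bins under the count/coverage limits")
    if min_counts > 0 or coverage is not None:
        # restricted-domain likelihood: each window's effective sample
        # count is what it retains inside the solved bins.  Keeping the
        # raw totals would overweight frontier windows whose excursion
        # counts were cropped, and the per-hop offset bias accumulates
        # along window chains into whole-kJ/mol errors.
        N = counts[:, sampled].sum(axis=1)
        if np.any(N <= 0):
            bad = np.flatnonzero(N <= 0)
            raise ValueError(
                f"windows {bad.tolist()} retain no counts inside the "
                f"cropped domain")
    logM = np.full(M.shape, -np.inf)
    logM[sampled] = np.log(M[sampled])
    logN = np.log(N)

    f = np.zeros(hist.n_windows) if f_init is None else np.asarray(
        f_init, dtype=float).copy()
    residuals = []
    converged = False
    bw_s = np.ascontiguousarray(bw[:, sampled])   # only sampled bins matter
    logM_s = logM[sampled]
    if accelerate and hist.n_windows > 1:
        f = _newton_offsets(f, logN, N, M[sampled], bw_s, beta, tol)
    for it in range(1, max_iter + 1):
        # log denom_b = logsumexp_i [ log N_i + beta f_i - beta w_ib ]
        log_denom = logsumexp(logN[:, None] + beta * f[:, None] - bw_s,
                              axis=0)
        logP_s = logM_s - log_denom
        logP_s -= logsumexp(logP_s)           # normalize over sampled bins
        # f_i = -(1/beta) logsumexp_b [ logP_b - beta w_ib ]
        f_new = -logsumexp(logP_s[None, :] - bw_s, axis=1) / beta
        f_new -= f_new[0]                     # gauge: F_0 = 0
        resid = float(np.max(np.abs(f_new - f)))
        residuals.append(resid)
        f = f_new
        if resid < tol:
            converged = True
            break
    if not converged:
        raise WhamConvergenceError(max_iter, residuals[-1], tol)

    pmf_flat = np.full(M.shape, np.nan)
    pmf_flat[sampled] = -logP_s / beta
    pmf_flat[sampled] -= np.nanmin(pmf_flat[sampled])
    return PMFGrid(bin_centers=hist.bin_centers,
                   pmf=pmf_flat.reshape(shape),
                   mask=~sampled.reshape(shape),
                   offsets=f, space=space, iterations=len(residuals),
                   residual=residuals[-1],
                   residual_history=np.asarray(residuals))


def _newton_offsets(f0, logN, N, M_s, bw_s, beta, f_tol, max_newton=60):
    """Damped Newton solve of the convex WHAM objective.

    The self-consistency equations are the stationarity conditions of
    Phi(g) = sum_b M_b ln sum_i N_i exp(g_i - beta w_ib) - sum_i N_i g_i
    with g_i = beta F_i (gauge-fixed g_0 = 0), which is convex in g:
    grad_i = sum_b M_b W_ib - N_i and Hess_ij = delta_ij sum_b M_b W_ib -
    sum_b M_b W_ib W_jb, where W_ib is the window softmax at bin b.  Direct
    fixed-point iteration converges only linearly and can need thousands
    of sweeps once many windows overlap; Newton reaches machine
    stationarity in a handful of n x n solves, after which the certifying
    self-consistent sweeps terminate immediately.

    When bins are cropped (coverage/min_counts) the retained counts sum to
    sum_b M_b < sum_i N_i and the gauge-fixed fixed point satisfies
    sum_b M_b W_ib = N_i * (sum M / sum N); the linear term uses that
    scaled target so Newton lands exactly on the fixed point.
    """
    g = beta * (np.asarray(f0, float) - f0[0])
    N = N * (M_s.sum() / N.sum())      # cropped-domain target counts

    def parts(gv):
        A = logN[:, None] + gv[:, None] - bw_s
        Amax = A.max(axis=0)
        E = np.exp(A - Amax)
        D = E.sum(axis=0)
        val = float(np.dot(M_s, np.log(D) + Amax) - np.dot(N, gv))
        W = E / D
        return val, W

    val, W = parts(g)
    for _ in range(max_newton):
        WM = W * M_s
        grad = WM.sum(axis=1) - N
        H = np.diag(WM.sum(axis=1)) - WM @ W.T
        try:
            step = np.linalg.solve(H[1:, 1:], -grad[1:])
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        alpha = 1.0
        for _ in range(30):
            g_try = g.copy()
            g_try[1:] += alpha * step
            val_try, W_try = parts(g_try)
            if val_try <= val + 1e-12 * abs(val):
                break
            alpha *= 0.5
        else:
            break
        g, val, W = g_try, val_try, W_try
        # step in F units; well below tol means the SC polish is instant
        if alpha * np.max(np.abs(step)) / beta < 0.01 * f_tol:
            break
    return g / beta


def _bracketing(centers: np.ndarray, x: float, periodic: bool,
                period: float):
    """Indices (i0, i1) of the bin centers bracketing x and the fraction t."""
    n = centers.size
    step = centers[1] - centers[0] if n > 1 else 1.0
    if periodic:
        rel = (x - centers[0]) / step
        i0 = int(np.floor(rel)) % n
        i1 = (i0 + 1) % n
        t = rel - np.floor(rel)
        return i0, i1, t
    if x <= centers[0]:
        return 0, 0, 0.0
    if x >= centers[-1]:
        return n - 1, n - 1, 0.0
    i0 = int(np.searchsorted(centers, x) - 1)
    t = (x - centers[i0]) / (centers[i0 + 1] - centers[i0])
    return i0, i0 + 1, t


def containing_bin(grid: PMFGrid, p) -> tuple:
    """Index of the bin whose cell contains p (nearest center, periodic)."""
    p = wrap_point(grid.space, np.atleast_1d(np.asarray(p, float)))
    idx = []
    for j, centers in enumerate(grid.bin_centers):
        step = centers[1] - centers[0]
        if grid.space.periodic[j]:
            i = int(np.round((p[j] - centers[0]) / step)) % centers.size
        else:
            i = int(np.clip(np.round((p[j] - centers[0]) / step), 0,
                            centers.size - 1))
        idx.append(i)
    return tuple(idx)


def pmf_at(grid: PMFGrid, p) -> float:
    """Multilinear PMF interpolation at p, exact at bin centers.

    The bin containing p must be sampled, else OutOfExploredRegionError.
    Masked corner bins of the interpolation cell are dropped and the
    remaining corner weights renormalized, so queries near the frontier of
    the explored region stay finite.
    """
    p = wrap_point(grid.space, np.atleast_1d(np.asarray(p, float)))
    home = containing_bin(grid, p)
    if grid.mask[home]:
        raise OutOfExploredRegionError(
            f"query {p} falls in an unsampled bin {home}")
    brackets = [
        _bracketing(c, p[j], grid.space.periodic[j], grid.space.period[j])
        for j, c in enumerate(grid.bin_centers)
    ]
    total_w = 0.0
    acc = 0.0
    for corner in np.ndindex(*(2,) * grid.dim):
        idx = tuple(brackets[j][corner[j]] for j in range(grid.dim))
        w = 1.0
        for j in range(grid.dim):
            t = brackets[j][2]
            w *= t if corner[j] == 1 else (1.0 - t)
        if w == 0.0 or grid.mask[idx]:
            continue
        total_w += w
        acc += w * grid.pmf[idx]
    if total_w == 0.0:
        raise OutOfExploredRegionError(
            f"all interpolation corners around {p} are unsampled")
    return float(acc / total_w)
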