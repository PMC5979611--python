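"""Harmonic bias potentials and the Gaussian model of a biased window.

Each umbrella window is one biased run: a harmonic restraint
w(xi) = 1/2 (xi - xi_ref)^T K (xi - xi_ref) (K diagonal) added to the
system, producing a localized biased distribution P^b(xi).  Umbrella
integration approximates P^b by a multivariate normal with the sample mean
and covariance of the run — the second-order cumulant truncation.  The
eigen-decomposition of the covariance (sigma_j^2, e_j) supplies the
principal axes used for candidate-window placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .space import ReactionSpace, minimal_image_displacement, wrap_point

#: windows with a covariance eigenvalue below this are degenerate
MIN_EIGENVALUE = 1e-12


class DegenerateWindowError(ValueError):
    """Window statistics too degenerate for a Mahalanobis metric (singular C)."""


@dataclass(frozen=True)
class BiasPotential:
    """Harmonic restraint centered at `center` with diagonal force constants.

    Force constants are in energy per squared coordinate unit
    (kJ/mol/rad^2 for dihedrals).
    """

    center: np.ndarray
    force_constants: np.ndarray

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.center, dtype=float))
        k = np.broadcast_to(np.asarray(self.force_constants, dtype=float),
                            c.shape).copy()
        if np.any(k <= 0):
            raise ValueError("force constants must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "force_constants", k)

    @property
    def dim(self) -> int:
        return self.center.shape[0]


def bias_energy(bias: BiasPotential, p, space: ReactionSpace) -> float:
    """Harmonic bias energy 1/2 sum_j K_j d_j^2, d the minimal-image p - center."""
    d = minimal_image_displacement(space, np.atleast_1d(np.asarray(p, float)),
                                   bias.center)
    return float(0.5 * np.sum(bias.force_constants * d * d))


def bias_energy_grid(bias: BiasPotential, points: np.ndarray,
                     space: ReactionSpace) -> np.ndarray:
    """Vectorized bias energy for an (n, dim) array of points."""
    pts = np.asarray(points, dtype=float).reshape(-1, bias.dim)
    d = wrap_point(space, pts - bias.center)
    return 0.5 * np.sum(bias.force_constants * d * d, axis=1)


@dataclass(frozen=True)
class WindowStats:
    """Gaussian summary of one biased window.

    Attributes
    ----------
    n_samples : int
        Number of (post-burn-in) samples N_i; enters the WHAM/weighting sums.
    mean : ndarray
        Biased mean <xi>^b, wrapped into the principal domain.
    covariance : ndarray
        Sample covariance C (N-1 normalization), symmetric positive definite.
    eigenvalues : ndarray
        sigma_j^2 sorted descending.
    eigenvectors : ndarray
        Orthonormal axes as columns, eigenvectors[:, j] paired with
        eigenvalues[j].
    """

    n_samples: int
    mean: np.ndarray
    covariance: np.ndarray
    space: ReactionSpace
    eigenvalues: np.ndarray = field(default=None)
    eigenvectors: np.ndarray = field(default=None)

    def __post_init__(self):
        m = np.atleast_1d(np.asarray(self.mean, dtype=float))
        C = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        C = 0.5 * (C + C.T)
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        vals, vecs = np.linalg.eigh(C)
        if vals.min() < MIN_EIGENVALUE:
            raise DegenerateWindowError(
                f"smallest covariance eigenvalue {vals.min():.3e} below "
                f"{MIN_EIGENVALUE:.0e}: degenerate window statistics"
            )
        order = np.argsort(vals)[::-1]
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "covariance", C)
        object.__setattr__(self, "eigenvalues", vals[order])
        object.__setattr__(self, "eigenvectors", vecs[:, order])

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    @property
    def sigmas(self) -> np.ndarray:
        """Principal standard deviations sigma_j (descending)."""
        return np.sqrt(self.eigenvalues)

    def solve_cov(self, d: np.ndarray) -> np.ndarray:
        """C^{-1} d via the eigen-decomposition (stable for small sigma)."""
        V = self.eigenvectors
        return V @ ((V.T @ d) / self.eigenvalues)

    def log_density(self, p, space: ReactionSpace | None = None) -> float:
        """Log of the normal approximation of P^b at p (minimal image)."""
        space = space or self.space
        d = minimal_image_displacement(space,
                                       np.atleast_1d(np.asarray(p, float)),
                                       self.mean)
        q = float(d @ self.solve_cov(d))
        log_det = float(np.sum(np.log(self.eigenvalues)))
        n = self.dim
        return -0.5 * (q + log_det + n * np.log(2.0 * np.pi))


def estimate_window_stats(samples, space: ReactionSpace,
                          reference) -> WindowStats:
    """Sample mean/covariance of a biased run, periodicity-aware.

    Samples are first unwrapped to the periodic image nearest `reference`
    (normally the bias center), then ordinary moments are taken; the mean is
    re-wrapped into the principal domain.  This is valid for the localized,
    near-Gaussian windows the harmonic bias produces and avoids the variance
    distortion circular moments would introduce.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, dim = X.shape
    if dim != space.dim:
        raise ValueError(f"samples have dim {dim}, space has dim {space.dim}")
    if n < dim + 1:
        raise ValueError(f"need at least dim+1={dim + 1} samples, got {n}")
    ref = np.atleast_1d(np.asarray(reference, dtype=float))
    # unwrap: reference + minimal-image displacement of each sample
    disp = wrap_point(space, X - ref)
    U = ref + disp
    mean_unwrapped = U.mean(axis=0)
    dev = U - mean_unwrapped
    C = (dev.T @ dev) / (n - 1)
    try:
        return WindowStats(n_samples=n, mean=wrap_point(space, mean_unwrapped),
                           covariance=C, space=space)
    except DegenerateWindowError as e:
        raise DegenerateWindowError(
            f"degenerate sample statistics ({n} samples): {e}") from e


def biased_density(stats: WindowStats, p,
                   space: ReactionSpace | None = None) -> float:
    """Normal-approximation density of the biased window at p.

    Maximal at the window mean; evaluated through the minimal periodic
    image, so it is single-image (windows are assumed narrow relative to
    the period).
    """
    return float(np.exp(stats.log_density(p, space)))


@dataclass
class WindowRecord:
    """One entry in the explorer's window list.

    Couples the requested bias with the realized window statistics, the
    border flag used by parent selection, and the cached PMF value at the
    window mean from the most recent WHAM solve.
    """

    id: int
    bias: BiasPotential
    stats: WindowStats
    samples: np.ndarray | None = None
    is_border: bool = True
    pmf_value: float | None = None
    parent_id: int | None = None
    deviation_flagged: bool = False
    timeseries_path: str | None = None
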