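"""Reaction-coordinate geometry: periodic wrapping and the Mahalanobis metric.

A reaction coordinate xi is a low-dimensional projection of a molecular
configuration (e.g. the backbone dihedrals phi, psi).  Dihedral components
are periodic; all distance computations therefore go through the minimal
periodic image.  The principal domain of a periodic coordinate with period L
is (-L/2, L/2], so angles live in (-pi, pi] with boundary ties wrapped to
the closed (positive) end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Boltzmann constant in kJ/mol/K; internal energies are kJ/mol.
KB_KJ_PER_MOL_K = 0.0083144621
KCAL_PER_KJ = 1.0 / 4.184
TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ReactionSpace:
    """Geometry and thermodynamic state of the reaction-coordinate space.

    Parameters
    ----------
    dim : int
        Number of reaction-coordinate components.
    periodic : sequence of bool
        Per-dimension periodicity flag (dihedrals are periodic).
    period : sequence of float
        Per-dimension period length (2*pi for angles in radians).  Ignored
        for non-periodic dimensions.
    beta : float
        Inverse temperature 1/(k_B T) in 1/(energy unit).
    energy_unit : str
        Label for reporting, "kJ/mol" or "kcal/mol".
    """

    dim: int
    periodic: tuple = field(default=None)
    period: tuple = field(default=None)
    beta: float = 1.0
    energy_unit: str = "kJ/mol"

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        per = self.periodic
        if per is None:
            per = (False,) * self.dim
        per = tuple(bool(p) for p in np.broadcast_to(per, (self.dim,)))
        object.__setattr__(self, "periodic", per)
        L = self.period
        if L is None:
            L = (TWO_PI,) * self.dim
        L = tuple(float(x) for x in np.broadcast_to(L, (self.dim,)))
        for p, length in zip(per, L):
            if p and length <= 0:
                raise ValueError("period must be > 0 on periodic dimensions")
        object.__setattr__(self, "period", L)

    @property
    def kT(self) -> float:
        return 1.0 / self.beta

    @property
    def periodic_mask(self) -> np.ndarray:
        return np.asarray(self.periodic, dtype=bool)

    @property
    def period_array(self) -> np.ndarray:
        return np.asarray(self.period, dtype=float)


def angular_space(dim: int, temperature: float = 298.0) -> ReactionSpace:
    """All-periodic (-pi, pi] space (dihedral angles) at the given T in K."""
    beta = 1.0 / (KB_KJ_PER_MOL_K * temperature)
    return ReactionSpace(dim=dim, periodic=(True,) * dim,
                         period=(TWO_PI,) * dim, beta=beta)


def _check_dim(space: ReactionSpace, v: np.ndarray, name: str = "vector"):
    if v.shape[-1] != space.dim:
        raise ValueError(
            f"{name} has {v.shape[-1]} components, space has dim {space.dim}"
        )


def wrap_point(space: ReactionSpace, p) -> np.ndarray:
    """Map a raw vector into the principal domain (-L/2, L/2] per periodic dim.

    Non-periodic components pass through unchanged.  The wrap convention
    sends the boundary -L/2 to +L/2 so the principal domain is half-open on
    the negative side.
    """
    p = np.asarray(p, dtype=float)
    _check_dim(space, p, "point")
    out = p.copy()
    mask = space.periodic_mask
    if mask.any():
        L = space.period_array[mask]
        x = out[..., mask]
        # shift so that (-L/2, L/2] maps from [0, L) of (x + L/2) mirrored:
        # wrapped = x - L*floor(x/L + 1/2), then boundary -L/2 -> +L/2
        w = x - L * np.floor(x / L + 0.5)
        w = np.where(w <= -L / 2, w + L, w)
        out[..., mask] = w
    return out


def minimal_image_displacement(space: ReactionSpace, a, b) -> np.ndarray:
    """Component-wise a - b using the nearest periodic image.

    The result lies in (-L/2, L/2] on periodic dimensions, so its norm is
    minimal over all periodic images of a relative to b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_dim(space, a, "a")
    _check_dim(space, b, "b")
    return wrap_point(space, a - b)


def mahalanobis_distance(stats, p, space: ReactionSpace | None = None) -> float:
    """Mahalanobis distance of point p from a window's mean in its metric.

    d(p) = sqrt( (p-m)^T C^{-1} (p-m) ) with the displacement taken through
    the minimal periodic image.  Valid for localized windows (sigma much
    smaller than the period), where a single image carries all the density.
    """
    if space is None:
        space = stats.space
    d = minimal_image_displacement(space, np.asarray(p, float), stats.mean)
    y = stats.solve_cov(d)
    q = float(d @ y)
    # guard tiny negative round-off
    return float(np.sqrt(max(q, 0.0)))
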