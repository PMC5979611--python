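"""Umbrella-integration estimates of the unbiased PMF gradient.

Per window, differentiating the unbiased free energy under the Gaussian
approximation of the biased distribution gives

    g_i(xi) = (1/beta) C_i^{-1} (xi - <xi>_i^b) - K_i (xi - xi_i^ref),

and the window estimates are combined with normalized occupation weights

    p_i(xi) = N_i P_i^b(xi) / sum_j N_j P_j^b(xi).

These gradients drive the exploration decisions only; PMF *values* always
come from WHAM, which is statistically better behaved in several
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .space import ReactionSpace, minimal_image_displacement
from .windows import BiasPotential, WindowRecord, WindowStats

#: windows whose normalized weight falls below this are dropped from sums
WEIGHT_CUTOFF = 1e-12


@dataclass(frozen=True)
class GradientEstimate:
    point: np.ndarray
    gradient: np.ndarray
    per_window_weights: np.ndarray  # aligned with the input window sequence


def window_gradient(stats: WindowStats, bias: BiasPotential, p,
                    space: ReactionSpace) -> np.ndarray:
    """Single-window UI gradient of the unbiased PMF at p."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    d_mean = minimal_image_displacement(space, p, stats.mean)
    d_ref = minimal_image_displacement(space, p, bias.center)
    return stats.solve_cov(d_mean) / space.beta - bias.force_constants * d_ref


def window_log_weights(windows: Sequence[WindowRecord], p,
                       space: ReactionSpace) -> np.ndarray:
    """Unnormalized log weights log(N_i) + log P_i^b(p)."""
    if len(windows) == 0:
        raise ValueError("empty window list")
    return np.array([
        np.log(w.stats.n_samples) + w.stats.log_density(p, space)
        for w in windows
    ])


def window_weights(windows: Sequence[WindowRecord], p,
                   space: ReactionSpace) -> np.ndarray:
    """Normalized occupation weights p_i(p), computed in log space.

    A max-shift normalization avoids underflow from distant windows;
    weights below WEIGHT_CUTOFF are zeroed (their windows contribute
    nothing at double precision anyway) and the rest renormalized.
    """
    logw = window_log_weights(windows, p, space)
    if not np.isfinite(logw).any():
        raise ValueError("all window densities underflow at the query point")
    w = np.exp(logw - logw.max())
    w[w < WEIGHT_CUTOFF] = 0.0
    return w / w.sum()


def combined_gradient(windows: Sequence[WindowRecord], p,
                      space: ReactionSpace) -> GradientEstimate:
    """Weight-averaged UI gradient over all registered windows."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    weights = window_weights(windows, p, space)
    g = np.zeros(space.dim)
    for wi, rec in zip(weights, windows):
        if wi > 0.0:
            g += wi * window_gradient(rec.stats, rec.bias, p, space)
    return GradientEstimate(point=p, gradient=g, per_window_weights=weights)


def directional_gradient(windows: Sequence[WindowRecord], parent_point,
                         candidate_point, space: ReactionSpace) -> float:
    """UI gradient at the parent projected on the parent->candidate direction.

    The direction is the minimal-image displacement, normalized; a steeper
    descent (more negative value) marks a more promising child.
    """
    parent_point = np.atleast_1d(np.asarray(parent_point, dtype=float))
    u = minimal_image_displacement(space, np.asarray(candidate_point, float),
                                   parent_point)
    norm = np.linalg.norm(u)
    if norm == 0.0:
        raise ValueError("candidate coincides with parent: zero direction")
    est = combined_gradient(windows, parent_point, space)
    return float(est.gradient @ (u / norm))
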