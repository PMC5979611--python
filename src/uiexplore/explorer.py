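"""Automated exploration of a free-energy landscape.

Starting from one biased window, the loop repeatedly

  (1) picks the border window with the lowest current PMF (the parent),
  (2) spawns equiangular/lattice candidate points on the parent's
      Mahalanobis ellipsoid at radius sqrt(3) (i.e. 3 * sigma_j^2),
  (3) prunes candidates closer than 2.5 Mahalanobis (in the nearest
      neighboring window's own metric) to an already-sampled window,
      clearing the parent's border flag if nothing survives,
  (4) picks the candidate with the steepest-descent umbrella-integration
      directional gradient as the child,
  (5) samples a new harmonically biased window at the child, doubling the
      force constant if the realized mean drifts too far from the request,

re-solving WHAM (warm-started) after every accepted window so step (1)
always sees current PMF values.  Termination: no border windows remain
(full coverage), every border window sits above a PMF threshold
(threshold mode), or the window budget is exhausted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np

from .gradients import directional_gradient
from .space import ReactionSpace, mahalanobis_distance, wrap_point
from .wham import PMFGrid, pmf_at, wham_solve
from .windows import (BiasPotential, WindowRecord, WindowStats,
                      estimate_window_stats)

logger = logging.getLogger("uiexplore.explorer")

#: sentinel returned by select_parent when exploration is finished
EXHAUSTED = None


@dataclass
class ExplorationConfig:
    """Tunable knobs of the exploration loop.

    Defaults follow the method's published operating point: 2.5 pruning
    radius, radius multiplier 3 on the variances (candidates at Mahalanobis
    sqrt(3)), and a 100 energy/rad^2 harmonic bias.
    """

    n_candidates_2d: int = 8
    radius_variance_multiplier: float = 3.0
    prune_threshold: float = 2.5
    default_force_constant: float | tuple = 100.0
    pmf_threshold: float | None = None
    max_iterations: int = 200
    lattice_M: int = 1
    center_deviation_tol: float = 1.0
    max_bias_retries: int = 3
    rng_seed: int = 0
    samples_per_window: int = 10_000
    wham_bins: int | tuple = 60
    wham_tol: float = 1e-7
    wham_max_iter: int = 100_000
    wham_every: int = 1
    wham_ranges: tuple | None = None   # required for non-periodic dims
    wham_min_counts: float = 5.0       # starved bins treated as unsampled

    def __post_init__(self):
        if self.n_candidates_2d < 3:
            raise ValueError("n_candidates_2d must be >= 3")
        for name in ("radius_variance_multiplier", "prune_threshold",
                     "center_deviation_tol", "wham_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lattice_M <= 0:
            raise ValueError("lattice_M must be a positive integer")


@dataclass(frozen=True)
class CandidatePoint:
    position: np.ndarray
    parent_id: int
    index: int
    meta: tuple = ()      # (axis, sign) in 1D/2D, lattice vector in nD


@dataclass
class WindowRegistry:
    """Ordered window list with the explorer's bookkeeping."""

    space: ReactionSpace
    records: list = field(default_factory=list)
    iteration: int = 0

    def add(self, rec: WindowRecord):
        if any(r.id == rec.id for r in self.records):
            raise ValueError(f"duplicate window id {rec.id}")
        if rec.parent_id is not None and not any(
                r.id == rec.parent_id for r in self.records):
            raise ValueError(f"parent id {rec.parent_id} not in registry")
        self.records.append(rec)

    def get(self, wid: int) -> WindowRecord:
        for r in self.records:
            if r.id == wid:
                return r
        raise KeyError(wid)

    def __len__(self):
        return len(self.records)

    def border_records(self):
        return [r for r in self.records if r.is_border]

    def next_id(self) -> int:
        return max((r.id for r in self.records), default=-1) + 1


@dataclass
class ExplorationResult:
    registry: WindowRegistry
    pmf: PMFGrid
    termination: str
    log: list = field(default_factory=list)


# -- step 1 ------------------------------------------------------------------

def select_parent(registry: WindowRegistry, pmf: PMFGrid,
                  config: ExplorationConfig | None = None):
    """Border window with the lowest PMF at its mean, or EXHAUSTED.

    In threshold mode (config.pmf_threshold set) EXHAUSTED is also
    returned when even the best border window lies above the threshold.
    """
    border = registry.border_records()
    if len(registry) == 1 and registry.records[0].is_border:
        # just after step (0) there is nothing to compare against
        rec = registry.records[0]
        rec.pmf_value = pmf_at(pmf, rec.stats.mean)
    if not border:
        return EXHAUSTED
    for rec in border:
        rec.pmf_value = pmf_at(pmf, rec.stats.mean)
    best = min(border, key=lambda r: (r.pmf_value, r.id))
    if (config is not None and config.pmf_threshold is not None
            and best.pmf_value > config.pmf_threshold):
        return EXHAUSTED
    return best


# -- step 2 ------------------------------------------------------------------

def generate_candidates_2d(parent: WindowRecord, config: ExplorationConfig,
                           space: ReactionSpace) -> list:
    """Equiangular points on the parent's covariance ellipse.

    Radii are sqrt(m * sigma_j^2) along the eigen-axes (m the variance
    multiplier, 3 by default), so every candidate sits at Mahalanobis
    sqrt(m) from the parent mean in the parent's own metric.
    """
    if space.dim != 2:
        raise ValueError("generate_candidates_2d requires a 2D space")
    stats = parent.stats
    r = math.sqrt(config.radius_variance_multiplier)
    sig = stats.sigmas
    e1, e2 = stats.eigenvectors[:, 0], stats.eigenvectors[:, 1]
    n = config.n_candidates_2d
    out = []
    for k in range(n):
        theta = 2.0 * math.pi * k / n
        pos = stats.mean + r * sig[0] * math.cos(theta) * e1 \
                         + r * sig[1] * math.sin(theta) * e2
        out.append(CandidatePoint(position=wrap_point(space, pos),
                                  parent_id=parent.id, index=k,
                                  meta=("theta", k)))
    return out


def admissible_lattice_vectors(f: int, M: int) -> list:
    """All nonzero integer vectors with sum|K_i| <= n + M, n = #nonzero."""
    if M <= 0:
        raise ValueError("M must be a positive integer")
    rng = range(-(M + 1), M + 2)
    out = []
    for K in product(rng, repeat=f):
        v = np.array(K, dtype=int)
        n_nonzero = int(np.count_nonzero(v))
        if n_nonzero == 0:
            continue
        if int(np.abs(v).sum()) <= n_nonzero + M:
            out.append(v)
    return out


def primitive_directions(vectors: Sequence[np.ndarray]) -> list:
    """Collapse positive collinear multiples to the primitive vector.

    Antiparallel vectors are kept distinct: candidates must surround the
    parent on both sides of each direction.
    """
    seen = {}
    for v in vectors:
        g = int(np.gcd.reduce(np.abs(v)))
        p = tuple((v // g).tolist())
        seen.setdefault(p, np.array(p, dtype=int))
    return [seen[k] for k in sorted(seen)]


def generate_candidates_nd(parent: WindowRecord, config: ExplorationConfig,
                           space: ReactionSpace) -> list:
    """Integer-lattice hypersphere directions mapped to the ellipsoid.

    Each primitive lattice vector K, read in the parent's eigen-axis
    coordinates (units of sigma_j along e_j), is Mahalanobis-normalized and
    the candidate placed at metric distance sqrt(m) from the mean.  For
    dim 2 this reproduces equiangular-like ellipse points; for dim 1 it
    degenerates to the two axis points.
    """
    stats = parent.stats
    f = space.dim
    r = math.sqrt(config.radius_variance_multiplier)
    dirs = primitive_directions(admissible_lattice_vectors(f, config.lattice_M))
    sig = stats.sigmas
    V = stats.eigenvectors
    out = []
    for idx, K in enumerate(dirs):
        norm = float(np.linalg.norm(K))          # Mahalanobis norm in sigma units
        disp = V @ (K * sig) * (r / norm)
        out.append(CandidatePoint(position=wrap_point(space,
                                                      stats.mean + disp),
                                  parent_id=parent.id, index=idx,
                                  meta=tuple(int(k) for k in K)))
    return out


def generate_candidates(parent: WindowRecord, config: ExplorationConfig,
                        space: ReactionSpace) -> list:
    if space.dim == 2:
        return generate_candidates_2d(parent, config, space)
    return generate_candidates_nd(parent, config, space)


# -- step 3 ------------------------------------------------------------------

def nearest_neighboring_window(candidate: CandidatePoint,
                               registry: WindowRegistry,
                               parent: WindowRecord,
                               space: ReactionSpace):
    """Registered window (parent excluded) with maximal biased density at
    the candidate, or None if the parent is the only window."""
    best, best_logp = None, -np.inf
    for rec in registry.records:
        if rec.id == parent.id:
            continue
        logp = rec.stats.log_density(candidate.position, space)
        if logp > best_logp:
            best, best_logp = rec, logp
    return best


def prune_candidates(candidates: Sequence[CandidatePoint],
                     registry: WindowRegistry, parent: WindowRecord,
                     config: ExplorationConfig, space: ReactionSpace):
    """Drop candidates within the prune radius of their nearest neighbor.

    A candidate is rejected iff its Mahalanobis distance to the N.N.
    window's mean, measured in the N.N. window's metric, is below
    config.prune_threshold.  The parent is excluded from the N.N. search
    (all its own candidates sit at sqrt(3) < 2.5 by construction).
    Returns (kept, parent_still_border).
    """
    kept = []
    for cand in candidates:
        nn = nearest_neighboring_window(cand, registry, parent, space)
        if nn is None:
            kept.append(cand)
            continue
        d = mahalanobis_distance(nn.stats, cand.position, space)
        if d >= config.prune_threshold:
            kept.append(cand)
    return kept, bool(kept)


# -- step 4 ------------------------------------------------------------------

def select_child(parent: WindowRecord, kept: Sequence[CandidatePoint],
                 registry: WindowRegistry | Sequence[WindowRecord],
                 space: ReactionSpace) -> CandidatePoint:
    """Candidate whose parent->candidate directional gradient is steepest
    descent (most negative); exact ties break to the smallest index."""
    if not kept:
        raise ValueError("no candidates to choose from")
    windows = registry.records if isinstance(registry, WindowRegistry) \
        else list(registry)
    best, best_g = None, np.inf
    for cand in kept:
        g = directional_gradient(windows, parent.stats.mean, cand.position,
                                 space)
        if g < best_g:
            best, best_g = cand, g
    return best


# -- step 5 ------------------------------------------------------------------

def place_window(sampler: Callable, child_position, config: ExplorationConfig,
                 space: ReactionSpace, window_id: int = 0,
                 parent_id: int | None = None) -> WindowRecord:
    """Sample a new biased window at the requested center.

    If the realized mean deviates from the request by more than
    center_deviation_tol in the window's own Mahalanobis metric, the force
    constant is doubled and the window resampled, up to max_bias_retries
    times; a still-deviating window is flagged but kept (the realized mean,
    not the request, is what becomes a future parent).
    """
    pos = wrap_point(space, np.atleast_1d(np.asarray(child_position, float)))
    K = np.broadcast_to(np.asarray(config.default_force_constant, float),
                        (space.dim,)).copy()
    returns_stats = getattr(sampler, "returns_stats", False)
    seed = config.rng_seed + window_id
    attempts = 1 + max(0, config.max_bias_retries)
    samples = None
    for attempt in range(attempts):
        bias = BiasPotential(center=pos, force_constants=K)
        try:
            out = sampler(bias, config.samples_per_window, seed)
        except Exception as e:
            raise RuntimeError(
                f"sampler failed for window {window_id} at {pos}: {e}") from e
        if returns_stats or isinstance(out, WindowStats):
            stats = out
        else:
            samples = np.asarray(out, dtype=float)
            if samples.ndim == 1:
                samples = samples[:, None]
            stats = estimate_window_stats(samples, space, bias.center)
        deviation = mahalanobis_distance(stats, pos, space)
        if deviation <= config.center_deviation_tol:
            return WindowRecord(id=window_id, bias=bias, stats=stats,
                                samples=samples, parent_id=parent_id)
        if attempt < attempts - 1:
            logger.info("window %d: center deviation %.2f > %.2f, "
                        "doubling K", window_id, deviation,
                        config.center_deviation_tol)
            K = K * 2.0
    logger.warning("window %d: center deviation %.2f still above tolerance "
                   "after %d retries", window_id, deviation,
                   config.max_bias_retries)
    return WindowRecord(id=window_id, bias=bias, stats=stats, samples=samples,
                        parent_id=parent_id, deviation_flagged=True)


# -- the loop ----------------------------------------------------------------

def _coverage_mask(registry: WindowRegistry, centers: np.ndarray,
                   config: ExplorationConfig,
                   space: ReactionSpace) -> np.ndarray:
    """Bins within the prune radius of some window mean (its own metric).

    Beyond ~2.5 Mahalanobis of every window only Gaussian-tail excursions
    land; a handful of correlated counts there would be amplified by the
    huge unbiasing factor exp(beta*omega) into a spuriously deep PMF bin,
    so those bins are treated as unexplored.
    """
    covered = np.zeros(centers.shape[0], dtype=bool)
    r2 = config.prune_threshold ** 2
    for rec in registry.records:
        todo = ~covered
        if not todo.any():
            break
        d = wrap_point(space, centers[todo] - rec.stats.mean)
        V = rec.stats.eigenvectors
        y = (d @ V) / np.sqrt(rec.stats.eigenvalues)
        covered[todo] = np.einsum("ij,ij->i", y, y) <= r2
    return covered


class _WhamAccumulator:
    """Incremental WHAM input: each window's histogram and bias-energy row
    are computed once, when the window is added, so the per-iteration
    re-solve costs only the self-consistent sweeps."""

    def __init__(self, space: ReactionSpace, config: ExplorationConfig):
        from .wham import HistogramGrid, default_edges
        if not all(space.periodic) and config.wham_ranges is None:
            raise ValueError(
                "exploration on a non-periodic space needs wham_ranges "
                "(a fixed per-dimension (lo, hi) bin range)")
        self.space, self.config = space, config
        self.edges = default_edges(space, config.wham_bins,
                                   config.wham_ranges)
        centers_1d = [0.5 * (e[1:] + e[:-1]) for e in self.edges]
        grids = np.meshgrid(*centers_1d, indexing="ij")
        self.centers = np.stack([g.ravel() for g in grids], axis=1)
        self.shape = tuple(c.size for c in centers_1d)
        self._HistogramGrid = HistogramGrid
        self.counts, self.bias_rows, self.totals = [], [], []

    def add(self, rec: WindowRecord):
        from .windows import bias_energy_grid
        if rec.samples is None:
            raise ValueError("explore requires a sampler that returns "
                             "samples")
        X = wrap_point(self.space, rec.samples)
        h, _ = np.histogramdd(X, bins=self.edges)
        self.counts.append(h)
        self.bias_rows.append(bias_energy_grid(rec.bias, self.centers,
                                               self.space))
        self.totals.append(float(X.shape[0]))

    def solve(self, registry: WindowRegistry, f_init=None) -> PMFGrid:
        cfg = self.config
        hist = self._HistogramGrid(
            bin_edges=self.edges, counts=np.asarray(self.counts),
            totals=np.asarray(self.totals), space=self.space)
        biases = [r.bias for r in registry.records]
        if f_init is not None and f_init.size == len(biases) - 1:
            f_init = np.append(f_init, f_init[-1])  # warm start: reuse last F
        elif f_init is not None and f_init.size != len(biases):
            f_init = None
        coverage = _coverage_mask(registry, self.centers, cfg,
                                  self.space).reshape(self.shape)
        return wham_solve(hist, biases, self.space, tol=cfg.wham_tol,
                          max_iter=cfg.wham_max_iter, f_init=f_init,
                          min_counts=cfg.wham_min_counts, coverage=coverage,
                          bias_energies=np.stack(self.bias_rows))


def explore(sampler: Callable, initial_center, config: ExplorationConfig,
            space: ReactionSpace) -> ExplorationResult:
    """Run steps (0)-(5) until a termination criterion fires.

    Returns the registry (every record carries its bias, realized
    statistics, border flag, parent link and cached PMF value), the final
    WHAM PMF grid, the termination reason and a per-iteration log.
    """
    registry = WindowRegistry(space=space)
    acc = _WhamAccumulator(space, config)
    rec0 = place_window(sampler, initial_center, config, space,
                        window_id=0, parent_id=None)
    registry.add(rec0)
    acc.add(rec0)
    registry.iteration = 1
    log = []
    if registry.iteration >= config.max_iterations:
        pmf = acc.solve(registry)
        rec0.pmf_value = pmf_at(pmf, rec0.stats.mean)
        return ExplorationResult(registry, pmf, "max_iterations", log)

    pmf = acc.solve(registry)
    termination = "max_iterations"
    stale = 0
    while registry.iteration < config.max_iterations:
        parent = select_parent(registry, pmf, config)
        if parent is EXHAUSTED:
            termination = ("threshold"
                           if config.pmf_threshold is not None
                           and registry.border_records() else "full_coverage")
            break
        candidates = generate_candidates(parent, config, space)
        kept, still_border = prune_candidates(candidates, registry, parent,
                                              config, space)
        if not kept:
            parent.is_border = False
            log.append({"event": "border_cleared", "parent": parent.id,
                        "n_candidates": len(candidates)})
            continue
        child = select_child(parent, kept, registry, space)
        rec = place_window(sampler, child.position, config, space,
                           window_id=registry.next_id(), parent_id=parent.id)
        registry.add(rec)
        acc.add(rec)
        registry.iteration += 1
        stale += 1
        if stale >= config.wham_every:
            pmf = acc.solve(registry, f_init=pmf.offsets)
            stale = 0
        log.append({"event": "window", "id": rec.id, "parent": parent.id,
                    "n_candidates": len(candidates), "n_kept": len(kept),
                    "child_meta": child.meta,
                    "wham_residual": pmf.residual,
                    "deviation_flagged": rec.deviation_flagged})
        logger.info("iter %d: parent %d -> window %d (%d/%d candidates "
                    "kept), WHAM residual %.2e", registry.iteration,
                    parent.id, rec.id, len(kept), len(candidates),
                    pmf.residual)
    if stale:
        pmf = acc.solve(registry, f_init=pmf.offsets)
    for rec in registry.records:
        try:
            rec.pmf_value = pmf_at(pmf, rec.stats.mean)
        except Exception:
            rec.pmf_value = None
    return ExplorationResult(registry, pmf, termination, log)
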