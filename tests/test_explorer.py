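"""The exploration loop: parent selection, candidate geometry, pruning,
child choice, window placement, and the full loop on a 1D double well."""

import numpy as np
import pytest

from uiexplore.explorer import (EXHAUSTED, CandidatePoint, ExplorationConfig,
                                WindowRegistry, admissible_lattice_vectors,
                                explore, generate_candidates_2d,
                                generate_candidates_nd, place_window,
                                primitive_directions, prune_candidates,
                                select_child, select_parent)
from uiexplore.space import ReactionSpace, mahalanobis_distance
from uiexplore.surfaces import (double_well_1d, exact_biased_stats,
                                metropolis_sampler, quadratic_surface)
from uiexplore.wham import PMFGrid
from uiexplore.windows import BiasPotential, WindowRecord, WindowStats


def record(space, wid, mean, cov=None, k=100.0, border=True, parent=None):
    cov = np.eye(space.dim) * 0.01 if cov is None else np.asarray(cov)
    return WindowRecord(
        id=wid, bias=BiasPotential(mean, [k] * space.dim),
        stats=WindowStats(1000, mean, cov, space), is_border=border,
        parent_id=parent)


def uniform_pmf_grid(space, lo=-np.pi, hi=np.pi, n=20, values=None):
    centers = np.linspace(lo, hi, n, endpoint=not space.periodic[0])
    if space.periodic[0]:
        centers = centers + (hi - lo) / (2 * n)
    vals = np.zeros((n,) * space.dim) if values is None else values
    return PMFGrid(bin_centers=[centers] * space.dim, pmf=vals,
                   mask=np.zeros_like(vals, dtype=bool),
                   offsets=np.zeros(1), space=space)


class TestSelectParent:
    def test_lowest_border_pmf_wins(self, flat2d):
        reg = WindowRegistry(space=flat2d)
        vals = {0: 2.0, 1: 1.0, 2: 3.0}
        grid = uniform_pmf_grid(flat2d, -3, 3, 30)
        for wid, v in vals.items():
            r = record(flat2d, wid, [wid * 0.5 - 0.5, 0.0])
            reg.add(r)
        # bake the PMF values into the grid at the window means
        for wid, v in vals.items():
            from uiexplore.wham import containing_bin
            grid.pmf[containing_bin(grid, reg.get(wid).stats.mean)] = v
        chosen = select_parent(reg, grid)
        assert chosen.id == 1

    def test_single_window_after_step0(self, flat2d):
        reg = WindowRegistry(space=flat2d)
        reg.add(record(flat2d, 0, [0.0, 0.0]))
        grid = uniform_pmf_grid(flat2d, -3, 3, 30)
        assert select_parent(reg, grid).id == 0

    def test_no_border_records_exhausted(self, flat2d):
        reg = WindowRegistry(space=flat2d)
        reg.add(record(flat2d, 0, [0.0, 0.0], border=False))
        grid = uniform_pmf_grid(flat2d, -3, 3, 30)
        assert select_parent(reg, grid) is EXHAUSTED

    def test_threshold_mode_stops_above_threshold(self, flat2d):
        reg = WindowRegistry(space=flat2d)
        reg.add(record(flat2d, 0, [0.0, 0.0]))
        grid = uniform_pmf_grid(flat2d, -3, 3, 30,
                                values=np.full((30, 30), 5.0))
        cfg = ExplorationConfig(pmf_threshold=4.0)
        assert select_parent(reg, grid, cfg) is EXHAUSTED
        cfg = ExplorationConfig(pmf_threshold=6.0)
        assert select_parent(reg, grid, cfg).id == 0


class TestCandidates2D:
    def test_isotropic_axis_points(self, flat2d):
        sigma2 = 0.01
        parent = record(flat2d, 0, [0.2, -0.3], cov=np.eye(2) * sigma2)
        cfg = ExplorationConfig(n_candidates_2d=4)
        cands = generate_candidates_2d(parent, cfg, flat2d)
        assert len(cands) == 4
        r = np.sqrt(3 * sigma2)
        got = sorted(tuple(np.round(c.position - parent.stats.mean, 12))
                     for c in cands)
        expect = sorted([(r, 0.0), (-r, 0.0), (0.0, r), (0.0, -r)])
        assert np.allclose(got, expect, atol=1e-12)

    def test_all_candidates_at_sqrt3(self, flat2d, rng):
        A = rng.normal(size=(2, 2))
        parent = record(flat2d, 0, [0.0, 0.0],
                        cov=0.01 * (A @ A.T + 0.5 * np.eye(2)))
        cands = generate_candidates_2d(parent, ExplorationConfig(), flat2d)
        for c in cands:
            d = mahalanobis_distance(parent.stats, c.position, flat2d)
            assert d == pytest.approx(np.sqrt(3.0), rel=1e-9)

    def test_anisotropic_matches_eigen_parameterization(self, flat2d):
        C = np.diag([0.04, 0.01])
        parent = record(flat2d, 0, [0.0, 0.0], cov=C)
        cfg = ExplorationConfig(n_candidates_2d=8)
        cands = generate_candidates_2d(parent, cfg, flat2d)
        # oracle: explicit ellipse x = sqrt(3)*sigma1 cos(t) e1 + ...
        for k, c in enumerate(cands):
            t = 2 * np.pi * k / 8
            e1 = np.array([1.0, 0.0])   # eigenvectors of a diagonal C
            e2 = np.array([0.0, 1.0])
            expect = np.sqrt(3) * 0.2 * np.cos(t) * e1 \
                + np.sqrt(3) * 0.1 * np.sin(t) * e2
            assert np.allclose(np.abs(c.position), np.abs(expect),
                               atol=1e-12)


class TestCandidatesND:
    def brute_force(self, f, M, span=6):
        from itertools import product
        out = []
        for K in product(range(-span, span + 1), repeat=f):
            v = np.array(K)
            n = np.count_nonzero(v)
            if n and np.abs(v).sum() <= n + M:
                out.append(tuple(K))
        return sorted(out)

    @pytest.mark.parametrize("f,M", [(2, 1), (2, 3), (3, 2), (4, 3)])
    def test_enumeration_matches_brute_force(self, f, M):
        got = sorted(tuple(v) for v in admissible_lattice_vectors(f, M))
        assert got == self.brute_force(f, M)

    def test_constraint_arithmetic_example(self):
        # (3, 0): sum|K| = 3 > n + M = 1 + 1 = 2 -> excluded
        vecs = {tuple(v) for v in admissible_lattice_vectors(2, 1)}
        assert (3, 0) not in vecs
        assert (2, 0) in vecs        # sum = 2 <= 2
        assert (1, 1) in vecs        # sum = 2 <= n + M = 3

    def test_primitive_dedup_keeps_antiparallel(self):
        dirs = primitive_directions([np.array([2, 0]), np.array([1, 0]),
                                     np.array([-1, 0]), np.array([2, 2])])
        asset = sorted(tuple(d) for d in dirs)
        assert asset == [(-1, 0), (1, 0), (1, 1)]

    def test_all_nd_candidates_at_sqrt3(self, rng):
        space = ReactionSpace(dim=3, periodic=(False,) * 3, beta=1.0)
        A = rng.normal(size=(3, 3))
        parent = record(space, 0, [0.0, 0.0, 0.0],
                        cov=0.01 * (A @ A.T + 0.5 * np.eye(3)))
        cands = generate_candidates_nd(parent, ExplorationConfig(lattice_M=2),
                                       space)
        assert len(cands) > 6
        for c in cands:
            d = mahalanobis_distance(parent.stats, c.position, space)
            assert d == pytest.approx(np.sqrt(3.0), rel=1e-9)

    def test_invalid_M(self):
        with pytest.raises(ValueError):
            admissible_lattice_vectors(2, 0)


class TestPruneCandidates:
    def _setup(self, space, nn_mean, nn_sigma2=0.01):
        reg = WindowRegistry(space=space)
        parent = record(space, 0, [0.0, 0.0])
        nn = record(space, 1, nn_mean, cov=np.eye(2) * nn_sigma2)
        reg.add(parent)
        reg.add(nn)
        return reg, parent, nn

    def test_reject_below_and_keep_above_threshold(self, flat2d):
        sigma = 0.1
        reg, parent, nn = self._setup(flat2d, [1.0, 0.0], sigma ** 2)
        cfg = ExplorationConfig()
        at = lambda d: CandidatePoint(
            position=np.array([1.0 - d * sigma, 0.0]), parent_id=0, index=0)
        kept, border = prune_candidates([at(2.4)], reg, parent, cfg, flat2d)
        assert kept == [] and border is False
        kept, border = prune_candidates([at(2.6)], reg, parent, cfg, flat2d)
        assert len(kept) == 1 and border is True

    def test_only_parent_registered_vacuous(self, flat2d):
        reg = WindowRegistry(space=flat2d)
        parent = record(flat2d, 0, [0.0, 0.0])
        reg.add(parent)
        cands = generate_candidates_2d(parent, ExplorationConfig(), flat2d)
        kept, border = prune_candidates(cands, reg, parent,
                                        ExplorationConfig(), flat2d)
        assert len(kept) == len(cands) and border is True

    def test_nn_is_max_density_not_min_distance(self, flat2d):
        # a broad window can be the N.N. even when a narrow one is closer
        reg = WindowRegistry(space=flat2d)
        parent = record(flat2d, 0, [0.0, 0.0])
        narrow = record(flat2d, 1, [1.0, 0.0], cov=np.eye(2) * 1e-4)
        broad = record(flat2d, 2, [1.5, 0.0], cov=np.eye(2) * 0.25)
        for r in (parent, narrow, broad):
            reg.add(r)
        c = CandidatePoint(position=np.array([0.8, 0.0]), parent_id=0,
                           index=0)
        from uiexplore.explorer import nearest_neighboring_window
        nn = nearest_neighboring_window(c, reg, parent, flat2d)
        assert nn.id == 2


class TestSelectChild:
    def test_steepest_descent_and_ties(self, flat2d):
        # quadratic PMF centered at origin, parent window at (1, 0)
        space = flat2d
        surf = quadratic_surface(np.diag([2.0, 1.0]), [0.0, 0.0],
                                 space=space)
        bias = BiasPotential([1.0, 0.0], [100.0, 100.0])
        stats = exact_biased_stats(surf, bias)
        parent = WindowRecord(0, bias, stats)
        reg = WindowRegistry(space=space)
        reg.add(parent)
        mk = lambda i, pos: CandidatePoint(position=np.array(pos),
                                           parent_id=0, index=i)
        # gradient at parent mean ~ H(p - 0) points along +x
        c_down = mk(0, parent.stats.mean + [-0.1, 0.0])
        c_up = mk(1, parent.stats.mean + [0.1, 0.0])
        c_side = mk(2, parent.stats.mean + [0.0, 0.1])
        assert select_child(parent, [c_up, c_side, c_down], reg,
                            space) is c_down
        assert select_child(parent, [c_up], reg, space) is c_up
        # exact tie: two perpendicular candidates -> lower index wins
        c_side2 = mk(3, parent.stats.mean + [0.0, -0.1])
        chosen = select_child(parent, [c_side, c_side2], reg, space)
        assert chosen is c_side


class TestPlaceWindow:
    def test_flat_pmf_no_retry(self):
        space = ReactionSpace(dim=1, periodic=(False,), beta=0.4)
        surf = quadratic_surface([[1e-9]], [0.0], space=space)

        calls = []

        def sampler(bias, n, seed):
            calls.append(bias.force_constants.copy())
            rng = np.random.default_rng(seed)
            sigma = 1 / np.sqrt(space.beta * bias.force_constants[0])
            return bias.center + sigma * rng.standard_normal((n, 1))

        cfg = ExplorationConfig(samples_per_window=4000, rng_seed=1)
        rec = place_window(sampler, [0.5], cfg, space, window_id=3)
        assert len(calls) == 1                     # no retry
        assert not rec.deviation_flagged
        se = 1 / np.sqrt(space.beta * 100.0) / np.sqrt(4000)
        assert abs(rec.stats.mean[0] - 0.5) < 3 * se * 3  # 3 SE headroom

    def test_linear_slope_triggers_retry(self):
        """Strong linear PMF: mean shift -g/K per the completed square;
        doubling K halves the shift until within tolerance."""
        space = ReactionSpace(dim=1, periodic=(False,), beta=0.4)
        g = 40.0      # slope, energy/unit

        def sampler(bias, n, seed):
            K = bias.force_constants[0]
            mean = bias.center[0] - g / K
            sigma = 1 / np.sqrt(space.beta * K)
            rng = np.random.default_rng(seed)
            return (mean + sigma * rng.standard_normal((n, 1)))

        # shift in own-metric units: (g/K) * sqrt(beta K) = g sqrt(beta/K)
        dev0 = g * np.sqrt(space.beta / 100.0)
        assert dev0 > 1.0          # must trigger at K = 100
        cfg = ExplorationConfig(samples_per_window=50_000, rng_seed=5)
        rec = place_window(sampler, [0.0], cfg, space)
        assert rec.bias.force_constants[0] > 100.0
        dev_final = g * np.sqrt(space.beta / rec.bias.force_constants[0])
        assert dev_final < 1.1     # tolerance met (with sampling slack)
        assert not rec.deviation_flagged

    def test_sampler_failure_propagates_with_context(self, flat2d):
        def sampler(bias, n, seed):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="window 7"):
            place_window(sampler, [0.0, 0.0], ExplorationConfig(), flat2d,
                         window_id=7)


@pytest.fixture(scope="module")
def double_well_run():
    """Full loop on the asymmetric double well with the threshold above the
    barrier (both wells reachable).  Force constant 200 keeps the window
    spacing guideline sqrt(3/(beta K)) ahead of the surface's steepest
    drift, so the frontier can climb the barrier."""
    surf = double_well_1d(5.0, 2.0)
    lower = min(surf.minima(), key=lambda s: s.pmf)
    cfg = ExplorationConfig(samples_per_window=4000, rng_seed=12,
                            max_iterations=120, default_force_constant=200.0,
                            wham_bins=48, wham_ranges=((-1.9, 1.9),),
                            pmf_threshold=8.0)
    res = explore(metropolis_sampler(surf), lower.position, cfg, surf.space)
    return surf, res


class TestExploreLoop:
    def test_both_minima_found_lower_first(self, double_well_run):
        surf, res = double_well_run
        means = np.array([r.stats.mean[0] for r in res.registry.records])
        mins = sorted(surf.minima(), key=lambda s: s.pmf)
        near_lower = np.abs(means - mins[0].position[0]) < 0.2
        near_upper = np.abs(means - mins[1].position[0]) < 0.2
        assert near_lower.any() and near_upper.any()
        assert np.argmax(near_lower) < np.argmax(near_upper)

    def test_registry_is_tree_rooted_at_initial(self, double_well_run):
        _, res = double_well_run
        recs = res.registry.records
        assert recs[0].parent_id is None
        ids = {r.id for r in recs}
        for r in recs[1:]:
            assert r.parent_id in ids and r.parent_id != r.id

    def test_accepted_candidates_respect_prune_radius(self, double_well_run):
        """Every accepted candidate position was >= 2.5 Mahalanobis from
        its nearest-neighboring window (max biased density, parent
        excluded) among the windows existing at acceptance time."""
        _, res = double_well_run
        recs = res.registry.records
        space = res.registry.space
        for i, r in enumerate(recs[1:], 1):
            prior = [w for w in recs[:i] if w.id != r.parent_id]
            if not prior:
                continue
            nn = max(prior,
                     key=lambda w: w.stats.log_density(r.bias.center, space))
            assert mahalanobis_distance(nn.stats, r.bias.center,
                                        space) >= 2.5

    def test_max_iterations_one_gives_single_window(self):
        surf = double_well_1d(5.0, 2.0)
        cfg = ExplorationConfig(samples_per_window=2000, rng_seed=3,
                                max_iterations=1, wham_bins=32,
                                wham_ranges=((-1.9, 1.9),))
        res = explore(metropolis_sampler(surf), [1.0], cfg, surf.space)
        assert len(res.registry) == 1
        assert res.termination == "max_iterations"

    def test_threshold_below_barrier_confines(self):
        surf = double_well_1d(5.0, 2.0)
        saddle_x = surf.saddles()[0].position[0]
        lower = min(surf.minima(), key=lambda s: s.pmf)
        cfg = ExplorationConfig(samples_per_window=4000, rng_seed=12,
                                max_iterations=120,
                                default_force_constant=200.0, wham_bins=48,
                                wham_ranges=((-1.9, 1.9),),
                                pmf_threshold=2.5)
        res = explore(metropolis_sampler(surf), lower.position, cfg,
                      surf.space)
        assert res.termination == "threshold"
        side = np.sign(lower.position[0] - saddle_x)
        for r in res.registry.records:
            assert np.sign(r.stats.mean[0] - saddle_x) == side
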