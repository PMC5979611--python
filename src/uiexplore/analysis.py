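"""Stationary-point analysis of a binned PMF.

Equilibrium states (EQ) are strict local minima of the PMF grid;
transition states (TS) are first-order saddles located as the lowest
crossing point on the watershed ridge between two adjacent basins.  Both
are refined by a local quadratic fit, which is robust to histogram-level
noise (unlike Hessian eigenanalysis of raw bins).  Energies are reported
relative to the global minimum, matching the usual convention for
free-energy landscape tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .space import ReactionSpace, minimal_image_displacement, wrap_point
from .wham import PMFGrid


@dataclass(frozen=True)
class StationaryPoint:
    position: np.ndarray
    kind: str                 # "minimum" | "saddle"
    pmf: float                # relative to the global minimum
    basin: tuple = ()         # basin label (minima) or connected pair (saddles)


def _neighbor_offsets(dim: int):
    return [off for off in product((-1, 0, 1), repeat=dim)
            if any(o != 0 for o in off)]


def _shift_index(idx, off, shape, periodic):
    out = []
    for i, o, n, per in zip(idx, off, shape, periodic):
        j = i + o
        if per:
            j %= n
        elif j < 0 or j >= n:
            return None
        out.append(j)
    return tuple(out)


def _bin_widths(grid: PMFGrid) -> np.ndarray:
    return np.array([c[1] - c[0] if c.size > 1 else 1.0
                     for c in grid.bin_centers])


def _bin_position(grid: PMFGrid, idx) -> np.ndarray:
    return np.array([c[i] for c, i in zip(grid.bin_centers, idx)])


def _patch(grid: PMFGrid, idx, radius: int = 1):
    """(offsets, values) over the (2r+1)^dim patch, or None if any bin of
    the patch is masked/out of range (refinement then falls back)."""
    offs, vals = [], []
    span = tuple(range(-radius, radius + 1))
    for off in product(span, repeat=grid.dim):
        j = _shift_index(idx, off, grid.shape, grid.space.periodic)
        if j is None or grid.mask[j]:
            return None
        offs.append(off)
        vals.append(grid.pmf[j])
    return np.array(offs, float), np.array(vals, float)


def _quadratic_fit(offs: np.ndarray, vals: np.ndarray, dim: int):
    """Least-squares A ~ c + g.d + 1/2 d'Hd on the patch; returns (c, g, H)."""
    cols = [np.ones(len(offs))]
    for j in range(dim):
        cols.append(offs[:, j])
    for j in range(dim):
        for k in range(j, dim):
            f = 0.5 if j == k else 1.0
            cols.append(f * offs[:, j] * offs[:, k])
    X = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(X, vals, rcond=None)
    c = coef[0]
    g = coef[1:1 + dim]
    H = np.zeros((dim, dim))
    pos = 1 + dim
    for j in range(dim):
        for k in range(j, dim):
            H[j, k] = H[k, j] = coef[pos]
            pos += 1
    return c, g, H


def _refine(grid: PMFGrid, idx):
    """Stationary point of a local quadratic fit, clipped near the bin.

    A 5x5 patch is preferred when fully sampled: on a noisy histogram PMF
    the minimum bin is biased low by order one noise standard deviation
    (it won the min over its neighborhood), and the wider least-squares
    fit averages that away.  Near the mask frontier the fit falls back to
    the 3x3 patch, then to the raw bin.
    """
    pos = _bin_position(grid, idx)
    val = float(grid.pmf[idx])
    for radius, clip in ((2, 1.5), (1, 1.0)):
        patch = _patch(grid, idx, radius)
        if patch is None:
            continue
        c, g, H = _quadratic_fit(*patch, grid.dim)
        try:
            d = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            continue
        if np.any(np.abs(d) > clip):
            continue
        widths = _bin_widths(grid)
        refined_pos = wrap_point(grid.space, pos + d * widths)
        refined_val = float(c + g @ d + 0.5 * d @ H @ d)
        return refined_pos, refined_val
    return pos, val


def label_basins(grid: PMFGrid) -> np.ndarray:
    """Watershed basin labels by ascending-PMF flooding.

    Bins are visited from low to high PMF; a bin with no labeled lower
    neighbor seeds a new basin (it is a local minimum), otherwise it joins
    the basin of its lowest labeled neighbor.  Masked bins get label -1.
    """
    labels = np.full(grid.shape, -1, dtype=int)
    order = np.argsort(grid.pmf, axis=None, kind="stable")
    offsets = _neighbor_offsets(grid.dim)
    next_label = 0
    for flat in order:
        idx = np.unravel_index(flat, grid.shape)
        if grid.mask[idx]:
            continue
        best_label, best_val = -1, np.inf
        for off in offsets:
            j = _shift_index(idx, off, grid.shape, grid.space.periodic)
            if j is None or labels[j] < 0:
                continue
            if grid.pmf[j] < best_val:
                best_val, best_label = grid.pmf[j], labels[j]
        if best_label < 0:
            labels[idx] = next_label
            next_label += 1
        else:
            labels[idx] = best_label
    return labels


def _basin_persistence(grid: PMFGrid, labels: np.ndarray) -> dict:
    """Topological persistence of each watershed basin.

    Basins are merged in order of increasing ridge height (Kruskal over
    the boundary graph); when two components join, the one whose minimum
    is higher dies with persistence = ridge - its minimum.  Surviving
    components (the global minimum of each connected piece) get +inf.
    """
    n_basins = labels.max() + 1
    basin_min = np.full(n_basins, np.inf)
    for idx in np.ndindex(*grid.shape):
        la = labels[idx]
        if la >= 0:
            basin_min[la] = min(basin_min[la], grid.pmf[idx])
    ridges = {}
    offsets = _neighbor_offsets(grid.dim)
    for idx in np.ndindex(*grid.shape):
        la = labels[idx]
        if la < 0:
            continue
        for off in offsets:
            j = _shift_index(idx, off, grid.shape, grid.space.periodic)
            if j is None or labels[j] < 0 or labels[j] == la:
                continue
            pair = (min(la, labels[j]), max(la, labels[j]))
            ridge = max(grid.pmf[idx], grid.pmf[j])
            if pair not in ridges or ridge < ridges[pair]:
                ridges[pair] = ridge
    parent = list(range(n_basins))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comp_min = basin_min.copy()      # per-component lowest minimum
    persistence = {b: np.inf for b in range(n_basins)}
    for pair, ridge in sorted(ridges.items(), key=lambda kv: kv[1]):
        ra, rb = find(pair[0]), find(pair[1])
        if ra == rb:
            continue
        lo, hi = (ra, rb) if comp_min[ra] <= comp_min[rb] else (rb, ra)
        # the higher-minimum component dies at this ridge
        for b in range(n_basins):
            if find(b) == hi and persistence[b] == np.inf:
                persistence[b] = min(persistence[b],
                                     ridge - basin_min[b])
        parent[hi] = lo
        comp_min[lo] = min(comp_min[lo], comp_min[hi])
    return persistence


def find_minima(grid: PMFGrid, space: ReactionSpace | None = None,
                merge_bins: float = 1.0,
                min_prominence: float = 0.0) -> list:
    """Strict local minima of the PMF grid, quadratically refined.

    A bin qualifies if it is strictly lower than every unmasked Moore
    neighbor.  Minima closer than `merge_bins` bin widths after refinement
    are merged, keeping the lower one (suppresses histogram-noise
    duplicates).  With `min_prominence` > 0 (energy units), minima whose
    topological persistence — the barrier separating them from a deeper
    basin — is smaller are discarded as well: histogram noise produces
    shallow dimples of persistence comparable to the per-bin statistical
    error, far below any physical barrier of interest.
    """
    space = space or grid.space
    if grid.mask.all():
        raise ValueError("fully masked PMF grid")
    offsets = _neighbor_offsets(grid.dim)
    raw = []
    for idx in np.ndindex(*grid.shape):
        if grid.mask[idx]:
            continue
        v = grid.pmf[idx]
        strict = True
        for off in offsets:
            j = _shift_index(idx, off, grid.shape, space.periodic)
            if j is None or grid.mask[j]:
                continue
            if grid.pmf[j] <= v:
                strict = False
                break
        if strict:
            raw.append(idx)
    if min_prominence > 0.0 and raw:
        labels = label_basins(grid)
        persistence = _basin_persistence(grid, labels)
        raw = [idx for idx in raw
               if persistence.get(labels[idx], np.inf) >= min_prominence]
    widths = _bin_widths(grid)
    refined = [_refine(grid, idx) for idx in raw]
    refined.sort(key=lambda t: t[1])
    merged = []
    for pos, val in refined:
        dup = False
        for mpos, _ in merged:
            d = minimal_image_displacement(space, pos, mpos)
            if np.all(np.abs(d) <= merge_bins * widths):
                dup = True
                break
        if not dup:
            merged.append((pos, val))
    if not merged:
        return []
    base = min(v for _, v in merged)
    return [StationaryPoint(position=pos, kind="minimum", pmf=v - base,
                            basin=(i,))
            for i, (pos, v) in enumerate(merged)]


def merge_shallow_basins(grid: PMFGrid, labels: np.ndarray,
                         min_prominence: float) -> np.ndarray:
    """Absorb basins of persistence < min_prominence into their neighbors.

    Each shallow basin is merged across its lowest ridge into the adjacent
    basin, iterating until every surviving basin's persistence reaches the
    threshold; this collapses histogram-noise dimples so the watershed
    reflects only physically meaningful basins.
    """
    n = labels.max() + 1
    basin_min = np.full(n, np.inf)
    for idx in np.ndindex(*grid.shape):
        la = labels[idx]
        if la >= 0:
            basin_min[la] = min(basin_min[la], grid.pmf[idx])
    ridges = {}
    offsets = _neighbor_offsets(grid.dim)
    for idx in np.ndindex(*grid.shape):
        la = labels[idx]
        if la < 0:
            continue
        for off in offsets:
            j = _shift_index(idx, off, grid.shape, grid.space.periodic)
            if j is None or labels[j] < 0 or labels[j] == la:
                continue
            pair = (min(la, labels[j]), max(la, labels[j]))
            ridge = max(grid.pmf[idx], grid.pmf[j])
            if pair not in ridges or ridge < ridges[pair]:
                ridges[pair] = ridge

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comp_min = basin_min.copy()
    while True:
        best = None
        for (a, b), ridge in ridges.items():
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            die = ra if comp_min[ra] > comp_min[rb] else rb
            prom = ridge - comp_min[die]
            if prom < min_prominence and (best is None or prom < best[0]):
                best = (prom, ra, rb)
        if best is None:
            break
        _, ra, rb = best
        keep, die = (ra, rb) if comp_min[ra] <= comp_min[rb] else (rb, ra)
        parent[die] = keep
        comp_min[keep] = min(comp_min[keep], comp_min[die])
    reps = sorted({find(b) for b in range(n)})
    remap = {r: i for i, r in enumerate(reps)}
    out = labels.copy()
    it = np.nditer(labels, flags=["multi_index"])
    for v in it:
        if v >= 0:
            out[it.multi_index] = remap[find(int(v))]
    return out


def find_saddles(grid: PMFGrid, space: ReactionSpace | None = None,
                 min_prominence: float = 0.0) -> list:
    """First-order saddles between adjacent watershed basins (2D grids).

    For each pair of basins sharing a sampled boundary, the saddle is the
    lowest ridge crossing: min over adjacent opposite-label bin pairs of
    max(A_a, A_b), refined by a local quadratic fit.  Basin pairs with no
    sampled connection are skipped (a truncated landscape reports no TS
    there rather than extrapolating).  `min_prominence` > 0 first merges
    shallow (noise) basins so only barriers of at least that height are
    reported.
    """
    space = space or grid.space
    if grid.dim != 2:
        raise ValueError("saddle search implemented for 2D grids")
    labels = label_basins(grid)
    if min_prominence > 0.0:
        labels = merge_shallow_basins(grid, labels, min_prominence)
    offsets = _neighbor_offsets(2)
    best = {}
    for idx in np.ndindex(*grid.shape):
        la = labels[idx]
        if la < 0:
            continue
        for off in offsets:
            j = _shift_index(idx, off, grid.shape, space.periodic)
            if j is None:
                continue
            lb = labels[j]
            if lb < 0 or lb == la:
                continue
            pair = (min(la, lb), max(la, lb))
            ridge = max(grid.pmf[idx], grid.pmf[j])
            high = idx if grid.pmf[idx] >= grid.pmf[j] else j
            if pair not in best or ridge < best[pair][0]:
                best[pair] = (ridge, high)
    out = []
    global_min = float(np.nanmin(np.where(grid.mask, np.nan, grid.pmf)))
    for pair, (ridge, idx) in sorted(best.items()):
        pos, val = _refine_saddle(grid, idx, ridge)
        out.append(StationaryPoint(position=pos, kind="saddle",
                                   pmf=val - global_min, basin=pair))
    out.sort(key=lambda s: s.pmf)
    return out


def _refine_saddle(grid: PMFGrid, idx, fallback_val):
    pos = _bin_position(grid, idx)
    patch = _patch(grid, idx)
    if patch is None:
        return pos, float(fallback_val)
    c, g, H = _quadratic_fit(*patch, grid.dim)
    ev = np.linalg.eigvalsh(H)
    if not (ev[0] < 0 < ev[-1]):       # not saddle-shaped locally: keep bin
        return pos, float(fallback_val)
    d = np.linalg.solve(H, -g)
    if np.any(np.abs(d) > 1.0):
        return pos, float(fallback_val)
    widths = _bin_widths(grid)
    return (wrap_point(grid.space, pos + d * widths),
            float(c + g @ d + 0.5 * d @ H @ d))


def summarize(points, coord_names=None, energy_unit="kJ/mol",
              kcal: bool = False) -> pd.DataFrame:
    """Report table: minima then saddles, sorted by PMF within each group.

    Coordinates are rounded to 0.1 rad and energies to 0.1 in the output
    unit; energies are relative to the global minimum.  Set kcal=True to
    convert kJ/mol input to kcal/mol.
    """
    points = list(points)
    if not points:
        raise ValueError("no stationary points to summarize")
    dim = points[0].position.size
    if coord_names is None:
        coord_names = [f"xi{j + 1} (rad)" for j in range(dim)]
    scale = 1.0 / 4.184 if kcal else 1.0
    unit = "kcal/mol" if kcal else energy_unit
    minima = sorted((p for p in points if p.kind == "minimum"),
                    key=lambda p: p.pmf)
    saddles = sorted((p for p in points if p.kind == "saddle"),
                     key=lambda p: p.pmf)
    rows = []
    for i, p in enumerate(minima, 1):
        rows.append([f"EQ{i}", *np.round(p.position, 1),
                     round(p.pmf * scale, 1)])
    for i, p in enumerate(saddles, 1):
        rows.append([f"TS{i}", *np.round(p.position, 1),
                     round(p.pmf * scale, 1)])
    return pd.DataFrame(rows, columns=["state", *coord_names,
                                       f"A ({unit})"])
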