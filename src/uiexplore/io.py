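"""Text file formats: time series, WHAM metadata, registries, PMF grids.

All formats are whitespace-delimited text with '#' comments and floats
written at 17 significant digits, so every file round-trips bit-exactly.
The time-series format is COLVAR-like: first column time, remaining
columns the reaction-coordinate components.
"""

from __future__ import annotations

import os

import numpy as np

from .space import ReactionSpace
from .wham import PMFGrid
from .windows import BiasPotential, WindowRecord, WindowStats

FLOAT_FMT = "%.17g"


def _fmt(x) -> str:
    return FLOAT_FMT % float(x)


# -- time series -------------------------------------------------------------

def read_timeseries(path, dim: int | None = None) -> np.ndarray:
    """Read a COLVAR-like file; returns (n, dim) samples (time dropped).

    Malformed lines are reported with their line number.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if ncols is None:
                ncols = len(parts)
                if ncols < 2:
                    raise ValueError(
                        f"{path}:{lineno}: need a time column plus at least "
                        f"one coordinate, got {ncols} columns")
                if dim is not None and ncols != dim + 1:
                    raise ValueError(
                        f"{path}:{lineno}: expected {dim + 1} columns "
                        f"(time + {dim} coords), got {ncols}")
            if len(parts) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncols} columns, "
                    f"got {len(parts)}")
            try:
                rows.append([float(p) for p in parts[1:]])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from e
    if not rows:
        raise ValueError(f"{path}: no data lines")
    return np.asarray(rows, dtype=float)


def write_timeseries(path, samples, dt: float = 1.0):
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    with open(path, "w") as fh:
        fh.write("# time " + " ".join(f"xi{j + 1}"
                                      for j in range(X.shape[1])) + "\n")
        for i, row in enumerate(X):
            fh.write(" ".join([_fmt(i * dt)] + [_fmt(v) for v in row]) + "\n")


# -- WHAM metadata (Grossfield dialect) --------------------------------------

def write_wham_metadata(records, paths, out_path, convention: str = "half-k"):
    """One line per window: timeseries-path, center(s), spring constant(s).

    convention="half-k" lists k such that the bias is (1/2) k d^2 (the
    internal convention); "full-k" lists constants for a bias k d^2, i.e.
    half the internal values.  The convention is recorded in the header.
    """
    if convention not in ("half-k", "full-k"):
        raise ValueError(f"unknown harmonic convention {convention!r}")
    records = list(records)
    paths = list(paths)
    if len(paths) != len(records):
        raise ValueError("need one time-series path per window")
    if any(p is None for p in paths):
        raise ValueError("every window needs a time-series path")
    factor = 1.0 if convention == "half-k" else 0.5
    with open(out_path, "w") as fh:
        fh.write(f"# harmonic convention: {convention} "
                 f"(bias = {'0.5*k*d^2' if convention == 'half-k' else 'k*d^2'})\n")
        fh.write("# path center... spring...\n")
        for rec, p in zip(records, paths):
            bias = rec.bias if isinstance(rec, WindowRecord) else rec
            fields = [str(p)] + [_fmt(c) for c in bias.center] + \
                     [_fmt(k * factor) for k in bias.force_constants]
            fh.write(" ".join(fields) + "\n")


def read_wham_metadata(path, dim: int):
    """Returns (paths, BiasPotential list); honors the header convention."""
    convention = "half-k"
    paths, biases = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if s.startswith("#"):
                if "harmonic convention:" in s:
                    convention = s.split("harmonic convention:")[1].split()[0]
                continue
            if not s:
                continue
            parts = s.split()
            if len(parts) != 1 + 2 * dim:
                raise ValueError(
                    f"{path}:{lineno}: expected path + {dim} centers + "
                    f"{dim} springs, got {len(parts)} fields")
            center = [float(x) for x in parts[1:1 + dim]]
            springs = np.array([float(x) for x in parts[1 + dim:]])
            if convention == "full-k":
                springs = springs * 2.0
            paths.append(parts[0])
            biases.append(BiasPotential(center=center,
                                        force_constants=springs))
    return paths, biases


# -- window registry ---------------------------------------------------------

def save_registry(records, path, space: ReactionSpace):
    """One window per line: id parent center K N mean covariance border pmf."""
    dim = space.dim
    with open(path, "w") as fh:
        fh.write(f"# uiexplore registry dim={dim}\n")
        fh.write("# id parent center*dim K*dim N mean*dim cov*dim^2 "
                 "border pmf flagged\n")
        for r in records:
            fields = [str(r.id), str(-1 if r.parent_id is None
                                     else r.parent_id)]
            fields += [_fmt(c) for c in r.bias.center]
            fields += [_fmt(k) for k in r.bias.force_constants]
            fields += [str(r.stats.n_samples)]
            fields += [_fmt(m) for m in r.stats.mean]
            fields += [_fmt(c) for c in r.stats.covariance.ravel()]
            fields += ["1" if r.is_border else "0"]
            fields += ["nan" if r.pmf_value is None else _fmt(r.pmf_value)]
            fields += ["1" if r.deviation_flagged else "0"]
            fh.write(" ".join(fields) + "\n")


def load_registry(path, space: ReactionSpace) -> list:
    dim = space.dim
    n_fields = 2 + dim + dim + 1 + dim + dim * dim + 3
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != n_fields:
                raise ValueError(f"{path}:{lineno}: expected {n_fields} "
                                 f"fields, got {len(parts)}")
            it = iter(parts)
            wid = int(next(it))
            parent = int(next(it))
            center = [float(next(it)) for _ in range(dim)]
            K = [float(next(it)) for _ in range(dim)]
            n = int(next(it))
            mean = [float(next(it)) for _ in range(dim)]
            cov = np.array([float(next(it))
                            for _ in range(dim * dim)]).reshape(dim, dim)
            border = next(it) == "1"
            pmf_s = next(it)
            flagged = next(it) == "1"
            stats = WindowStats(n_samples=n, mean=mean, covariance=cov,
                                space=space)
            records.append(WindowRecord(
                id=wid, parent_id=None if parent < 0 else parent,
                bias=BiasPotential(center=center, force_constants=K),
                stats=stats, is_border=border,
                pmf_value=None if pmf_s == "nan" else float(pmf_s),
                deviation_flagged=flagged))
    return records


# -- PMF grids ---------------------------------------------------------------

def save_pmf_grid(grid: PMFGrid, path):
    """Header with geometry and bin centers, then row-major PMF values
    (nan marks masked bins)."""
    sp = grid.space
    with open(path, "w") as fh:
        fh.write(f"# uiexplore pmf dim={grid.dim} "
                 f"shape={','.join(str(s) for s in grid.shape)} "
                 f"beta={_fmt(sp.beta)} "
                 f"periodic={','.join('1' if p else '0' for p in sp.periodic)} "
                 f"period={','.join(_fmt(L) for L in sp.period)}\n")
        for j, c in enumerate(grid.bin_centers):
            fh.write(f"# centers{j} " + " ".join(_fmt(x) for x in c) + "\n")
        fh.write("# offsets " + " ".join(_fmt(f) for f in grid.offsets) + "\n")
        fh.write(f"# iterations={grid.iterations} "
                 f"residual={_fmt(grid.residual) if np.isfinite(grid.residual) else 'nan'}\n")
        for v in grid.pmf.ravel():
            fh.write((_fmt(v) if np.isfinite(v) else "nan") + "\n")


def load_pmf_grid(path) -> PMFGrid:
    centers = {}
    meta = {}
    offsets = np.array([0.0])
    values = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                parts = s[1:].split()
                if parts and parts[0] == "uiexplore":
                    for kv in parts[2:]:
                        k, v = kv.split("=")
                        meta[k] = v
                elif parts and parts[0].startswith("centers"):
                    centers[int(parts[0][len("centers"):])] = \
                        np.array([float(x) for x in parts[1:]])
                elif parts and parts[0] == "offsets":
                    offsets = np.array([float(x) for x in parts[1:]])
                continue
            values.append(float(s))
    dim = int(meta["dim"])
    shape = tuple(int(s) for s in meta["shape"].split(","))
    periodic = tuple(p == "1" for p in meta["periodic"].split(","))
    period = tuple(float(x) for x in meta["period"].split(","))
    space = ReactionSpace(dim=dim, periodic=periodic, period=period,
                          beta=float(meta["beta"]))
    pmf = np.array(values).reshape(shape)
    return PMFGrid(bin_centers=[centers[j] for j in range(dim)], pmf=pmf,
                   mask=~np.isfinite(pmf), offsets=offsets, space=space)


def save_pmf_long(grid: PMFGrid, path):
    """Long format (xi1 ... xiD A) triples for plotting; masked bins skipped."""
    grids = np.meshgrid(*grid.bin_centers, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    flat = grid.pmf.ravel()
    with open(path, "w") as fh:
        fh.write("# " + " ".join(f"xi{j + 1}" for j in range(grid.dim)) +
                 " A\n")
        for row, v in zip(pts, flat):
            if np.isfinite(v):
                fh.write(" ".join(_fmt(x) for x in row) + " " + _fmt(v) +
                         "\n")
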