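"""Moving-window barrier detection: how much would restoring a circular
window of the landscape to minimum resistance shorten least-cost linkages?

For a patch pair (a, b) with least-cost cost C and a circular window W, the
improvement score is ``C - C_restored`` where ``C_restored`` is the
least-cost distance after every cell of W is set to the landscape's minimum
resistance.  Restoration only lowers edge costs, so the restored
cost-distance fields are computed by a decrease-only Dijkstra restart
seeded from the window with the original fields as tentative distances --
exactly equivalent to a full re-solve on the modified surface (and tested
as such), at a fraction of the cost.  Scores are attributed to the window
center, maximized over detection radii and over linkages.  Barrier points
are the geometric centers of top-Jenks-class score regions above a minimum
area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from numba import njit
from scipy import ndimage

from .corridors import CostDistanceField, LeastCostPath, corridor_raster
from .geoio import RasterGrid, jenks_breaks
from .resistance import ResistanceSurface

__all__ = [
    "ImprovementField",
    "BarrierPointSet",
    "improvement_score",
    "scan_barriers",
    "extract_barrier_points",
    "DEFAULT_RADII_M",
]

#: Detection radii from minimum 100 m / maximum 500 m / step 200 m.
DEFAULT_RADII_M = (100.0, 300.0, 500.0)

_SQRT2 = math.sqrt(2.0)
_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class ImprovementField:
    """Per-cell connectivity-improvement score (CWD units), max over radii
    and linkages; 0 outside the scanned corridor extents."""

    score: RasterGrid
    radii_m: tuple[float, ...] = DEFAULT_RADII_M


@dataclass
class BarrierPointSet:
    """Barrier points: (center point, area_km2, max_score) per top region."""

    points: list[tuple[shapely.Geometry, float, float]]
    k_classes: int = 5
    min_area_km2: float = 0.05

    def __len__(self) -> int:
        return len(self.points)


def _window_offsets(radius_m: float, cell_size: float) -> np.ndarray:
    r = radius_m / cell_size
    n = int(math.floor(r))
    offs = [(dr, dc) for dr in range(-n, n + 1) for dc in range(-n, n + 1)
            if dr * dr + dc * dc <= r * r]
    return np.asarray(offs, dtype=np.int64)


# ---------------------------------------------------------------------------
# Numba core: decrease-only Dijkstra restart over the restored window
# ---------------------------------------------------------------------------

@njit(cache=True)
def _heap_push(hd, hi, size, d, i):  # pragma: no cover - numba
    hd[size] = d
    hi[size] = i
    k = size
    while k > 0:
        p = (k - 1) >> 1
        if hd[p] > hd[k]:
            hd[p], hd[k] = hd[k], hd[p]
            hi[p], hi[k] = hi[k], hi[p]
            k = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(hd, hi, size):  # pragma: no cover - numba
    d, i = hd[0], hi[0]
    size -= 1
    hd[0], hi[0] = hd[size], hi[size]
    k = 0
    while True:
        l, r = 2 * k + 1, 2 * k + 2
        m = k
        if l < size and hd[l] < hd[m]:
            m = l
        if r < size and hd[r] < hd[m]:
            m = r
        if m == k:
            break
        hd[m], hd[k] = hd[k], hd[m]
        hi[m], hi[k] = hi[k], hi[m]
        k = m
    return d, i, size


@njit(cache=True)
def _seeded_update(new, res, valid, win, rmin, s, nrows, ncols,
                   changed_idx):  # pragma: no cover - numba
    """Decrease-only shortest-path update after window cells drop to rmin.

    ``new`` is the original field (inf where unreachable) updated in place;
    returns the number of improved cells, their flat ids in changed_idx."""
    cap = 16 * (nrows * ncols) + 64
    hd = np.empty(cap, dtype=np.float64)
    hi = np.empty(cap, dtype=np.int64)
    size = 0
    nwin = 0
    # seed every node incident to a modified edge: window cells + neighbors
    seeded = np.zeros(nrows * ncols, dtype=np.uint8)
    for idx in range(win.size):
        if not win[idx]:
            continue
        r0, c0 = idx // ncols, idx % ncols
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                rr, cc = r0 + dr, c0 + dc
                if rr < 0 or rr >= nrows or cc < 0 or cc >= ncols:
                    continue
                j = rr * ncols + cc
                if valid[j] and not seeded[j] and np.isfinite(new[j]):
                    seeded[j] = 1
                    size = _heap_push(hd, hi, size, new[j], j)
    nch = 0
    while size > 0:
        d, i, size = _heap_pop(hd, hi, size)
        if d > new[i] + 1e-12:
            continue
        r0, c0 = i // ncols, i % ncols
        ri = rmin if win[i] else res[i]
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r0 + dr, c0 + dc
                if rr < 0 or rr >= nrows or cc < 0 or cc >= ncols:
                    continue
                j = rr * ncols + cc
                if not valid[j]:
                    continue
                rj = rmin if win[j] else res[j]
                f = _SQRT2 if (dr != 0 and dc != 0) else 1.0
                nd = d + 0.5 * (ri + rj) * s * f
                if nd < new[j] - 1e-12:
                    if seeded[j] != 2:  # record each improved cell once
                        changed_idx[nch] = j
                        nch += 1
                        seeded[j] = 2
                    new[j] = nd
                    size = _heap_push(hd, hi, size, nd, j)
    return nch


@njit(cache=True)
def _improvement_core(res, valid, base_a, base_b, win, rmin, s,
                      nrows, ncols, cost):  # pragma: no cover - numba
    n = nrows * ncols
    new_a = base_a.copy()
    new_b = base_b.copy()
    ch_a = np.empty(n, dtype=np.int64)
    ch_b = np.empty(n, dtype=np.int64)
    na = _seeded_update(new_a, res, valid, win, rmin, s, nrows, ncols, ch_a)
    nb = _seeded_update(new_b, res, valid, win, rmin, s, nrows, ncols, ch_b)
    best = cost
    for k in range(na):
        j = ch_a[k]
        t = new_a[j] + new_b[j]
        if t < best:
            best = t
    for k in range(nb):
        j = ch_b[k]
        t = new_a[j] + new_b[j]
        if t < best:
            best = t
    imp = cost - best
    return imp if imp > 0.0 else 0.0


def _improvement(grid: RasterGrid, field_a: CostDistanceField,
                 field_b: CostDistanceField, cost: float,
                 win: np.ndarray, rmin: float) -> float:
    """Improvement for one window given flat boolean window mask."""
    res = grid.values.astype(np.float64).ravel()
    valid = grid.valid_mask().ravel()
    win = win & valid & (res > rmin + 1e-12)
    if not win.any():
        return 0.0
    base_a = np.where(field_a.cwd.valid_mask(), field_a.cwd.values, np.inf).ravel()
    base_b = np.where(field_b.cwd.valid_mask(), field_b.cwd.values, np.inf).ravel()
    return float(_improvement_core(res, valid, base_a, base_b, win, rmin,
                                   grid.cell_size, grid.nrows, grid.ncols,
                                   cost))


def improvement_score(R: RasterGrid | ResistanceSurface,
                      field_a: CostDistanceField,
                      field_b: CostDistanceField,
                      cost: float,
                      center: tuple[int, int],
                      radius_m: float,
                      rmin: float | None = None) -> float:
    """Improvement (CWD units) from restoring the circular window at
    ``center`` (row, col) with the given radius to minimum resistance.

    Equals ``cost - cost_restored`` for the linkage whose CWD fields are
    given; never negative.  The window must lie fully on the grid and the
    radius must be at least one cell."""
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    if radius_m < grid.cell_size:
        raise ValueError("detection radius must be >= cell_size")
    if not np.isfinite(cost):
        raise ValueError("linkage has no finite least-cost distance")
    offs = _window_offsets(radius_m, grid.cell_size)
    rows = center[0] + offs[:, 0]
    cols = center[1] + offs[:, 1]
    if (rows.min() < 0 or rows.max() >= grid.nrows
            or cols.min() < 0 or cols.max() >= grid.ncols):
        raise ValueError("window extends beyond the grid")
    if rmin is None:
        rmin = float(grid.values[grid.valid_mask()].min())
    win = np.zeros(grid.values.size, dtype=bool)
    win[rows * grid.ncols + cols] = True
    return _improvement(grid, field_a, field_b, cost, win, rmin)


def scan_barriers(R: RasterGrid | ResistanceSurface,
                  paths: list[LeastCostPath],
                  fields: dict[int, CostDistanceField],
                  radii_m: tuple[float, ...] = DEFAULT_RADII_M,
                  corridor_extent_cwd: float | None = None,
                  stride: int = 1) -> ImprovementField:
    """Per-cell improvement score, maximized over radii and linkages.

    Window centers are scanned over each linkage's corridor search extent:
    by default every cell within one maximum detection radius of the
    least-cost path (a symmetric band, so a window anywhere in it can reach
    the path), or -- when ``corridor_extent_cwd`` is given -- the cells whose
    normalized corridor value stays within that CWD budget.  ``stride``
    subsamples centers on large landscapes; unscanned cells inside the
    extent inherit the nearest scanned score so region extraction stays
    contiguous.  Cells outside every extent score 0."""
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    if not paths:
        raise ValueError("no least-cost paths to scan")
    valid = grid.valid_mask()
    rmin = float(grid.values[valid].min())
    reach = int(math.ceil(max(radii_m) / grid.cell_size))

    nrows, ncols = grid.shape
    score = np.zeros(grid.shape, dtype=np.float64)
    scanned_any = np.zeros(grid.shape, dtype=bool)
    extent_any = np.zeros(grid.shape, dtype=bool)
    offsets = {rad: _window_offsets(rad, grid.cell_size) for rad in radii_m}
    for p in paths:
        fa, fb = fields[p.pair[0]], fields[p.pair[1]]
        if corridor_extent_cwd is not None:
            nlcc = corridor_raster(p.pair, fa, fb, p.cost).nlcc
            extent = nlcc.valid_mask() & (nlcc.values <= corridor_extent_cwd)
        else:
            pmask = np.zeros(grid.shape, dtype=bool)
            for rc in p.cells:
                pmask[rc] = True
            extent = ndimage.binary_dilation(pmask, structure=_EIGHT,
                                             iterations=reach) & valid
        extent_any |= extent
        centers = np.argwhere(extent)
        if stride > 1:
            centers = centers[(centers[:, 0] % stride == 0)
                              & (centers[:, 1] % stride == 0)]
        base_a = np.where(fa.cwd.valid_mask(), fa.cwd.values, np.inf).ravel()
        base_b = np.where(fb.cwd.valid_mask(), fb.cwd.values, np.inf).ravel()
        res = grid.values.astype(np.float64).ravel()
        vflat = valid.ravel()
        for r0, c0 in centers:
            for rad in radii_m:
                offs = offsets[rad]
                rows = r0 + offs[:, 0]
                cols = c0 + offs[:, 1]
                # windows are cropped at the grid boundary so edge barriers
                # stay detectable
                keep = ((rows >= 0) & (rows < nrows)
                        & (cols >= 0) & (cols < ncols))
                if not keep.any():
                    continue
                win = np.zeros(grid.values.size, dtype=bool)
                win[rows[keep] * ncols + cols[keep]] = True
                win &= vflat & (res > rmin + 1e-12)
                if not win.any():
                    scanned_any[r0, c0] = True
                    continue
                imp = float(_improvement_core(
                    res, vflat, base_a, base_b, win, rmin, grid.cell_size,
                    nrows, ncols, p.cost))
                scanned_any[r0, c0] = True
                if imp > score[r0, c0]:
                    score[r0, c0] = imp
    if stride > 1 and scanned_any.any():
        # nearest-scanned fill inside the extents keeps regions contiguous
        idx = ndimage.distance_transform_edt(~scanned_any,
                                             return_distances=False,
                                             return_indices=True)
        filled = score[tuple(idx)]
        score = np.where(extent_any & ~scanned_any, filled, score)
    return ImprovementField(score=grid.like(score), radii_m=tuple(radii_m))


def extract_barrier_points(field: ImprovementField, k_classes: int = 5,
                           min_area_km2: float = 0.05) -> BarrierPointSet:
    """Geometric centers of top-Jenks-class improvement regions >= the
    minimum area.  An all-zero field yields an empty set."""
    grid = field.score
    valid = grid.valid_mask()
    pos = grid.values[valid & (grid.values > 0)]
    if pos.size == 0:
        return BarrierPointSet(points=[], k_classes=k_classes,
                               min_area_km2=min_area_km2)
    if np.unique(pos).size < k_classes:
        warnings.warn("too few distinct positive scores for k-class breaks; "
                      "treating every positive-score region as top class")
        top = valid & (grid.values > 0)
    else:
        cb = jenks_breaks(pos, k=k_classes)
        top = valid & (grid.values > cb.breaks[-1])
    lab, nlab = ndimage.label(top, structure=_EIGHT)
    cell_km2 = grid.cell_area_km2()
    pts = []
    for rid in range(1, nlab + 1):
        m = lab == rid
        area = float(m.sum()) * cell_km2
        if area < min_area_km2:
            continue
        rr, cc = np.nonzero(m)
        x = grid.origin_x + (cc.mean() + 0.5) * grid.cell_size
        y = grid.origin_y - (rr.mean() + 0.5) * grid.cell_size
        pts.append((shapely.Point(x, y), area, float(grid.values[m].max())))
    return BarrierPointSet(points=pts, k_classes=k_classes,
                           min_area_km2=min_area_km2)
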