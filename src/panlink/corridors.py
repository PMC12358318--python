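"""Least-cost connectivity between protected-area patches: patch labeling,
cost-weighted distance (CWD) fields, least-cost paths (LCPs) and normalized
least-cost corridor rasters.

The landscape is an 8-connected grid graph.  The cost of stepping between
adjacent cells i, j is ``(R_i + R_j)/2 * cell_size`` for orthogonal moves and
``sqrt(2)`` times that for diagonal moves -- the standard cost-distance
convention, so CWD carries units of resistance x meters.  A patch acts as a
multi-cell source: CWD is 0 on every patch cell.  For a patch pair (a, b)
the normalized corridor value of a cell x is ``cwd_a(x) + cwd_b(x) -
cost(a, b)``: zero exactly on the least-cost path and growing outward, so
thresholding it yields a corridor of finite width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

from .geoio import RasterGrid, VectorLayer, jenks_breaks, rasterize
from .resistance import ResistanceSurface

__all__ = [
    "PatchInfo",
    "PatchSet",
    "CostDistanceField",
    "LeastCostPath",
    "CorridorRaster",
    "build_grid_graph",
    "label_patches",
    "cost_distance",
    "least_cost_paths",
    "corridor_raster",
    "threshold_corridor",
    "classify_ratios",
]

_SQRT2 = math.sqrt(2.0)
# 8-neighborhood as (dr, dc, diagonal?) for the forward half (symmetrized later)
_FORWARD_STEPS = ((0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True))
_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class PatchInfo:
    id: int
    category: str
    area_km2: float
    centroid: tuple[float, float]  # projected (x, y) of the cell-center mean
    n_cells: int


@dataclass
class PatchSet:
    """Labeled source patches: ``labels`` holds dense ids 1..P (0 = background)."""

    labels: RasterGrid
    patches: list[PatchInfo]

    def __len__(self) -> int:
        return len(self.patches)

    def mask(self, patch_id: int | None = None) -> np.ndarray:
        lab = self.labels.values
        return lab > 0 if patch_id is None else lab == patch_id

    def by_id(self, patch_id: int) -> PatchInfo:
        return self.patches[patch_id - 1]


@dataclass
class CostDistanceField:
    """Multi-source shortest-path field from one patch (or cell set)."""

    source_patch: int | None
    cwd: RasterGrid
    backlink: np.ndarray  # flat predecessor ids, -9999 where none/unreachable


@dataclass
class LeastCostPath:
    pair: tuple[int, int]
    cells: list[tuple[int, int]]  # ordered (row, col) from patch a to patch b
    cost: float                   # CWD units (resistance * meters)
    length_m: float               # per-step 1 / sqrt(2) cell increments
    ratio: float                  # cost / length_m, the relative resistance

    ratio_class: int | None = None      # 1=low .. 3=high, set by classify_ratios
    centrality: float | None = None
    centrality_class: int | None = None


@dataclass
class CorridorRaster:
    """Normalized least-cost corridor: nlcc = cwd_a + cwd_b - cost(a,b)."""

    pair: tuple[int, int]
    nlcc: RasterGrid


# ---------------------------------------------------------------------------
# Grid graph
# ---------------------------------------------------------------------------

def build_grid_graph(R: RasterGrid | ResistanceSurface) -> csr_matrix:
    """Sparse symmetric 8-connected cost graph over the resistance grid.

    Node ids are flat cell indices ``row * ncols + col``; nodata cells get no
    edges (impassable).  Edge weight = mean cell resistance x step length."""
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    vals = grid.values.astype(np.float64)
    valid = grid.valid_mask()
    nrows, ncols = grid.shape
    n = nrows * ncols
    ids = np.arange(n).reshape(nrows, ncols)
    s = grid.cell_size

    rows, cols, data = [], [], []
    for dr, dc, diag in _FORWARD_STEPS:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows + min(0, dr) or nrows)
        c1 = slice(max(0, dc), ncols + min(0, dc) or ncols)
        a, b = ids[r0, c0], ids[r1, c1]
        ok = valid[r0, c0] & valid[r1, c1]
        w = 0.5 * (vals[r0, c0] + vals[r1, c1]) * s * (_SQRT2 if diag else 1.0)
        rows.append(a[ok])
        cols.append(b[ok])
        data.append(w[ok])
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    w = np.concatenate(data)
    m = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    return m.tocsr()


# ---------------------------------------------------------------------------
# Patch labeling
# ---------------------------------------------------------------------------

def label_patches(pa: VectorLayer, template: RasterGrid,
                  valid_mask: np.ndarray | None = None) -> PatchSet:
    """Rasterize PA polygons and label 8-connected components.

    Polygons sharing (or diagonally touching) cells merge into one patch.
    Each patch inherits the category attribute of the first polygon touching
    it.  ``valid_mask`` (e.g. the terrestrial resistance mask) clips patches
    to analyzable cells."""
    if len(pa) == 0:
        raise ValueError("protected-area layer is empty")
    mask = rasterize(pa, template)
    if valid_mask is not None:
        mask &= valid_mask
    if not mask.any():
        raise ValueError("protected-area polygons rasterized to zero valid cells")
    lab, nlab = ndimage.label(mask, structure=_EIGHT)
    cell_km2 = template.cell_area_km2()
    x, y = template.cell_centers()

    # patch category: first polygon (by layer order) whose cells hit the patch
    cat = {}
    for g, attrs in pa.features:
        pmask = rasterize([g], template)
        if valid_mask is not None:
            pmask &= valid_mask
        for pid in np.unique(lab[pmask]):
            if pid > 0 and pid not in cat:
                cat[int(pid)] = str(attrs.get("category", "protected area"))

    patches = []
    for pid in range(1, nlab + 1):
        m = lab == pid
        ncells = int(m.sum())
        patches.append(PatchInfo(
            id=pid,
            category=cat.get(pid, "protected area"),
            area_km2=ncells * cell_km2,
            centroid=(float(x[m].mean()), float(y[m].mean())),
            n_cells=ncells,
        ))
    return PatchSet(labels=template.like(lab.astype(np.int32), nodata=-1), patches=patches)


# ---------------------------------------------------------------------------
# Cost distance
# ---------------------------------------------------------------------------

def cost_distance(R: RasterGrid | ResistanceSurface,
                  sources: np.ndarray,
                  graph: csr_matrix | None = None,
                  source_patch: int | None = None) -> CostDistanceField:
    """Multi-source Dijkstra CWD field from the boolean source mask."""
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    src = np.asarray(sources, dtype=bool)
    if src.shape != grid.shape:
        raise ValueError("source mask shape does not match the grid")
    src = src & grid.valid_mask()
    if not src.any():
        raise ValueError("no valid source cells")
    if graph is None:
        graph = build_grid_graph(grid)
    idx = np.flatnonzero(src.ravel())
    dist, pred, _src = dijkstra(graph, indices=idx, min_only=True,
                                return_predecessors=True)
    cwd = dist.reshape(grid.shape)
    out = np.where(np.isfinite(cwd), cwd, grid.nodata)
    return CostDistanceField(source_patch=source_patch,
                             cwd=grid.like(out), backlink=pred)


def _allocation(grid: RasterGrid, patchset: PatchSet,
                graph: csr_matrix) -> np.ndarray:
    """Per-cell id of the nearest patch by CWD (0 where unreachable)."""
    lab = patchset.labels.values
    idx = np.flatnonzero((lab > 0).ravel())
    dist, _pred, src = dijkstra(graph, indices=idx, min_only=True,
                                return_predecessors=True)
    alloc = np.zeros(lab.size, dtype=np.int32)
    ok = np.isfinite(dist) & (src >= 0)
    alloc[ok] = lab.ravel()[src[ok]]
    return alloc.reshape(lab.shape)


def _adjacent_pairs(alloc: np.ndarray) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for dr, dc, _ in _FORWARD_STEPS:
        a = alloc[max(0, -dr): alloc.shape[0] - max(0, dr),
                  max(0, -dc): alloc.shape[1] - max(0, dc)]
        b = alloc[max(0, dr): alloc.shape[0] + min(0, dr) or alloc.shape[0],
                  max(0, dc): alloc.shape[1] + min(0, dc) or alloc.shape[1]]
        diff = (a != b) & (a > 0) & (b > 0)
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            pairs.add((int(min(u, v)), int(max(u, v))))
    return pairs


def _backtrack(pred: np.ndarray, start_flat: int, ncols: int) -> list[tuple[int, int]]:
    cells = []
    node = start_flat
    while node >= 0:
        cells.append((node // ncols, node % ncols))
        node = int(pred[node])
    return cells


def _path_metrics(cells: list[tuple[int, int]], cell_size: float) -> float:
    length = 0.0
    for (r0, c0), (r1, c1) in zip(cells, cells[1:]):
        length += cell_size * (_SQRT2 if (r0 != r1 and c0 != c1) else 1.0)
    return length


def least_cost_paths(patchset: PatchSet,
                     R: RasterGrid | ResistanceSurface,
                     pairing: str = "adjacent_allocation",
                     max_neighbors: int = 4,
                     ) -> tuple[list[LeastCostPath], dict[int, CostDistanceField]]:
    """Least-cost paths between selected patch pairs.

    pairing='adjacent_allocation' (default, the Linkage-Pathways convention)
    links a pair iff their minimum-CWD allocation regions share a boundary;
    'all_pairs' links every pair; 'max_neighbors' keeps each patch's
    ``max_neighbors`` cheapest partners.  Returns the paths plus the
    per-patch CWD fields for corridor building.  Unreachable pairs are
    excluded with a warning.
    """
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    if len(patchset) < 2:
        raise ValueError("need at least two patches")
    graph = build_grid_graph(grid)
    fields = {
        p.id: cost_distance(grid, patchset.mask(p.id), graph=graph, source_patch=p.id)
        for p in patchset.patches
    }

    ids = [p.id for p in patchset.patches]
    if pairing == "adjacent_allocation":
        alloc = _allocation(grid, patchset, graph)
        candidate = sorted(_adjacent_pairs(alloc))
    elif pairing in ("all_pairs", "max_neighbors"):
        candidate = list(combinations(ids, 2))
    else:
        raise ValueError(f"unknown pairing rule: {pairing}")

    nrows, ncols = grid.shape
    valid = grid.valid_mask()
    paths: list[LeastCostPath] = []
    costs: dict[tuple[int, int], float] = {}
    for a, b in candidate:
        fa, fb = fields[a], fields[b]
        va, vb = fa.cwd.valid_mask(), fb.cwd.valid_mask()
        both = va & vb & valid
        if not both.any():
            warnings.warn(f"patch pair ({a},{b}) is unreachable; skipped")
            continue
        total = np.where(both, fa.cwd.values + fb.cwd.values, np.inf)
        meet_flat = int(np.argmin(total.ravel()))  # deterministic (row, col) order
        cost = float(total.ravel()[meet_flat])
        if not np.isfinite(cost):
            warnings.warn(f"patch pair ({a},{b}) is unreachable; skipped")
            continue
        costs[(a, b)] = cost
        half_a = _backtrack(fa.backlink, meet_flat, ncols)[::-1]  # a .. meet
        half_b = _backtrack(fb.backlink, meet_flat, ncols)        # meet .. b
        cells = half_a + half_b[1:]
        length = _path_metrics(cells, grid.cell_size)
        if length <= 0:  # adjacent patches meeting in a single shared cell
            length = grid.cell_size
        paths.append(LeastCostPath(pair=(a, b), cells=cells, cost=cost,
                                   length_m=length, ratio=cost / length))

    if pairing == "max_neighbors":
        keep: set[tuple[int, int]] = set()
        for pid in ids:
            partners = sorted(
                ((c, pr) for pr, c in costs.items() if pid in pr),
                key=lambda t: t[0],
            )[:max_neighbors]
            keep.update(pr for _c, pr in partners)
        paths = [p for p in paths if p.pair in keep]
    return paths, fields


# ---------------------------------------------------------------------------
# Corridors
# ---------------------------------------------------------------------------

def corridor_raster(pair: tuple[int, int], cwd_a: CostDistanceField,
                    cwd_b: CostDistanceField, cost: float) -> CorridorRaster:
    """nlcc(x) = cwd_a(x) + cwd_b(x) - cost(pair); >= 0, 0 on the LCP."""
    ga, gb = cwd_a.cwd, cwd_b.cwd
    ga.require_aligned(gb, "cwd field")
    both = ga.valid_mask() & gb.valid_mask()
    nlcc = np.where(both, np.maximum(ga.values + gb.values - cost, 0.0), ga.nodata)
    return CorridorRaster(pair=pair, nlcc=ga.like(nlcc))


def threshold_corridor(corridor: CorridorRaster, t: float) -> np.ndarray:
    """Boolean corridor mask: cells with nlcc <= t (t in CWD units)."""
    if t < 0:
        raise ValueError("corridor threshold must be non-negative")
    g = corridor.nlcc
    return g.valid_mask() & (g.values <= t)


def classify_ratios(paths: list[LeastCostPath]) -> list[LeastCostPath]:
    """Three-level Jenks classing of CWD:length relative-resistance ratios.

    Sets ``ratio_class`` in place (1=low, 2=medium, 3=high resistance) and
    returns the list.  Fewer than 3 distinct ratios collapse to one class."""
    ratios = np.array([p.ratio for p in paths], dtype=np.float64)
    if np.unique(ratios).size < 3:
        warnings.warn("fewer than 3 distinct ratios; all paths in one class")
        for p in paths:
            p.ratio_class = 1
        return paths
    cb = jenks_breaks(ratios, k=3)
    for p, cls in zip(paths, cb.classify(ratios)):
        p.ratio_class = int(cls)
    return paths
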