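"""Circuit-theory connectivity: the resistance grid as an electrical
network, cumulative current density between patches, and pinch points.

Each valid cell is a node; 8-neighbor edges carry conductance equal to the
reciprocal of the cost-distance edge cost (mean cell resistance x step
length), so the circuit and least-cost worlds share one geometry.  Patches
are short-circuited into supernodes.  Injecting current and grounding a
patch solves the graph Laplacian for node voltages; the per-cell current
density is half the sum of absolute currents on incident edges.  In
"all-to-one" mode each patch in turn is grounded while every other patch
injects 1 A, and densities accumulate over iterations.  Pinch points are
top-Jenks-class current regions above a minimum area: corridor cells where
flow has no alternative route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix, diags
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .corridors import PatchSet, build_grid_graph
from .geoio import RasterGrid, jenks_breaks
from .resistance import ResistanceSurface

__all__ = [
    "CurrentMap",
    "PinchPointSet",
    "conductance_graph",
    "solve_current",
    "cumulative_current",
    "effective_resistance",
    "extract_pinch_points",
    "regions_to_polygons",
]

_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class CurrentMap:
    """Cumulative current density per cell (A per unit injection)."""

    current: RasterGrid
    mode: str = "pairwise"
    corridor_mask: np.ndarray | None = None

    def in_mask_values(self) -> np.ndarray:
        g = self.current
        m = g.valid_mask()
        if self.corridor_mask is not None:
            m &= self.corridor_mask
        return g.values[m]


@dataclass
class PinchPointSet:
    """Top-current regions: (polygon, area_km2, peak_current) triples."""

    points: list[tuple[shapely.Geometry, float, float]]
    k_classes: int = 5
    min_area_km2: float = 0.1

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def conductance_graph(R: RasterGrid | ResistanceSurface) -> csr_matrix:
    """Per-edge conductance g = 1 / cost-distance edge cost."""
    cost = build_grid_graph(R)
    g = cost.copy()
    g.data = 1.0 / g.data
    return g


def _contract(grid: RasterGrid, g: csr_matrix,
              groups: np.ndarray) -> tuple[csr_matrix, np.ndarray, int]:
    """Contract cells into supernodes.

    ``groups``: int grid, >0 = supernode id (dense 1..P), 0 = own node,
    anything on invalid cells ignored.  Returns (contracted adjacency,
    flat cell -> node id map (-1 for invalid cells), node count); supernode
    p occupies node id p-1."""
    valid = grid.valid_mask().ravel()
    grp = groups.ravel()
    n_super = int(grp.max()) if grp.size else 0
    node_of = np.full(grid.values.size, -1, dtype=np.int64)
    node_of[valid & (grp > 0)] = grp[valid & (grp > 0)] - 1
    free = valid & (grp <= 0)
    node_of[free] = n_super + np.arange(int(free.sum()))
    n_nodes = n_super + int(free.sum())

    cells = np.flatnonzero(valid)
    m = coo_matrix(
        (np.ones(cells.size), (cells, node_of[cells])),
        shape=(grid.values.size, n_nodes),
    ).tocsr()
    a = (m.T @ g @ m).tocoo()
    keep = a.row != a.col  # drop intra-supernode self loops
    a = coo_matrix((a.data[keep], (a.row[keep], a.col[keep])),
                   shape=(n_nodes, n_nodes)).tocsr()
    return a, node_of, n_nodes


def _solve_voltages(adj: csr_matrix, injections: np.ndarray,
                    ground: np.ndarray) -> np.ndarray:
    """Node voltages with the given per-node injections (A) and grounded
    nodes fixed at 0 V.  Raises on a component disconnected from ground."""
    n = adj.shape[0]
    lap = diags(np.asarray(adj.sum(axis=1)).ravel()) - adj
    gidx = np.flatnonzero(ground)
    if gidx.size == 0:
        raise ValueError("no ground nodes")
    ncomp, comp = connected_components(adj, directed=False)
    grounded_comps = set(comp[gidx].tolist())
    inj_comps = set(comp[np.flatnonzero(injections != 0)].tolist())
    stranded = sorted(inj_comps - grounded_comps)
    if stranded:
        raise ValueError(
            f"singular system: graph component(s) {stranded} carry injection "
            "but contain no ground node"
        )
    keep = np.flatnonzero(~ground)
    v = np.zeros(n)
    if keep.size:
        lred = lap.tocsr()[keep][:, keep].tocsc()
        b = injections[keep]
        v[keep] = spsolve(lred, b)
    # stranded un-grounded, un-injected components solve to 0; fine
    return v


def _cell_current_density(grid: RasterGrid, g: csr_matrix,
                          v_cells: np.ndarray) -> np.ndarray:
    """Per-cell density = 0.5 * sum over incident edges |(v_i - v_j) g_ij|."""
    gc = g.tocoo()
    half = gc.row < gc.col
    i, j, w = gc.row[half], gc.col[half], gc.data[half]
    edge_cur = np.abs((v_cells[i] - v_cells[j]) * w)
    dens = np.zeros(grid.values.size)
    np.add.at(dens, i, 0.5 * edge_cur)
    np.add.at(dens, j, 0.5 * edge_cur)
    return dens.reshape(grid.shape)


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def solve_current(R: RasterGrid | ResistanceSurface,
                  source_cells: np.ndarray,
                  ground_cells: np.ndarray,
                  injection: float = 1.0,
                  merge_sources: bool = True) -> tuple[CurrentMap, np.ndarray]:
    """One pairwise solve: inject ``injection`` amps at the source cell set
    (short-circuited into one supernode when ``merge_sources``), ground cells
    fixed at 0 V.  Returns the current map and the per-cell voltages."""
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    src = np.asarray(source_cells, dtype=bool) & grid.valid_mask()
    gnd = np.asarray(ground_cells, dtype=bool) & grid.valid_mask()
    if not src.any() or not gnd.any():
        raise ValueError("source and ground cell sets must both be non-empty")
    if (src & gnd).any():
        raise ValueError("source and ground cells must be disjoint")

    g = conductance_graph(grid)
    groups = np.zeros(grid.shape, dtype=np.int64)
    if merge_sources:
        groups[src] = 1
        groups[gnd] = 2
    else:
        groups[gnd] = 1
    adj, node_of, n_nodes = _contract(grid, g, groups)

    inj = np.zeros(n_nodes)
    ground = np.zeros(n_nodes, dtype=bool)
    if merge_sources:
        inj[0] = injection
        ground[1] = True
    else:
        src_nodes = np.unique(node_of[src.ravel()])
        inj[src_nodes] = injection
        ground[0] = True
    v_nodes = _solve_voltages(adj, inj, ground)
    v_cells = np.zeros(grid.values.size)
    ok = node_of >= 0
    v_cells[ok] = v_nodes[node_of[ok]]

    dens = _cell_current_density(grid, g, v_cells)
    dens[~grid.valid_mask()] = grid.nodata
    return CurrentMap(current=grid.like(dens), mode="pairwise"), v_cells


def effective_resistance(R: RasterGrid | ResistanceSurface,
                         a_cells: np.ndarray, b_cells: np.ndarray) -> float:
    """Two-point effective resistance between two short-circuited cell sets."""
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    _cm, v = solve_current(grid, a_cells, b_cells, injection=1.0)
    src = (np.asarray(a_cells, dtype=bool) & grid.valid_mask()).ravel()
    return float(v[src][0])


def cumulative_current(R: RasterGrid | ResistanceSurface,
                       patchset: PatchSet,
                       mode: str = "all_to_one",
                       corridor_mask: np.ndarray | None = None) -> CurrentMap:
    """All-to-one cumulative current density over the patch network.

    Iterates each patch as ground while every other patch injects 1 A
    through its supernode; per-cell densities sum over iterations.  When a
    ``corridor_mask`` is given (e.g. min-over-pairs normalized corridor
    within the configured CWD width) the analysis is restricted to masked
    cells plus all patch cells."""
    if mode != "all_to_one":
        raise ValueError("only 'all_to_one' mode is implemented")
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    if len(patchset) < 2:
        raise ValueError("all-to-one needs at least two patches")

    work = grid
    if corridor_mask is not None:
        keep = np.asarray(corridor_mask, dtype=bool) | patchset.mask()
        vals = np.where(keep, grid.values, grid.nodata)
        work = grid.like(vals)

    g = conductance_graph(work)
    groups = patchset.labels.values.astype(np.int64).copy()
    groups[~work.valid_mask()] = 0
    adj, node_of, n_nodes = _contract(work, g, groups)
    n_p = len(patchset)

    total = np.zeros(work.shape, dtype=np.float64)
    for ground_patch in range(n_p):
        inj = np.zeros(n_nodes)
        inj[:n_p] = 1.0
        inj[ground_patch] = 0.0
        ground = np.zeros(n_nodes, dtype=bool)
        ground[ground_patch] = True
        v_nodes = _solve_voltages(adj, inj, ground)
        v_cells = np.zeros(work.values.size)
        ok = node_of >= 0
        v_cells[ok] = v_nodes[node_of[ok]]
        total += _cell_current_density(work, g, v_cells)

    out = np.where(work.valid_mask(), total, grid.nodata)
    return CurrentMap(current=grid.like(out), mode="all_to_one",
                      corridor_mask=corridor_mask)


# ---------------------------------------------------------------------------
# Pinch points
# ---------------------------------------------------------------------------

def regions_to_polygons(mask: np.ndarray, grid: RasterGrid,
                        min_area_km2: float,
                        score: np.ndarray) -> list[tuple[shapely.Geometry, float, float]]:
    """8-connected regions of the mask above the area floor, as cell-square
    union polygons with (polygon, area_km2, peak score)."""
    lab, nlab = ndimage.label(mask, structure=_EIGHT)
    cell_km2 = grid.cell_area_km2()
    s = grid.cell_size
    out = []
    for rid in range(1, nlab + 1):
        m = lab == rid
        area = float(m.sum()) * cell_km2
        if area < min_area_km2:
            continue
        rr, cc = np.nonzero(m)
        boxes = [
            shapely.box(grid.origin_x + c * s, grid.origin_y - (r + 1) * s,
                        grid.origin_x + (c + 1) * s, grid.origin_y - r * s)
            for r, c in zip(rr.tolist(), cc.tolist())
        ]
        poly = shapely.union_all(boxes)
        out.append((poly, area, float(score[m].max())))
    return out


def extract_pinch_points(cm: CurrentMap, k_classes: int = 5,
                         min_area_km2: float = 0.1) -> PinchPointSet:
    """Top-Jenks-class current regions with area >= ``min_area_km2``.

    A degenerate (near-constant) current map yields an empty set with a
    warning rather than an error."""
    grid = cm.current
    vals = cm.in_mask_values()
    if np.unique(vals).size < k_classes:
        warnings.warn("current map has too few distinct values; no pinch points")
        return PinchPointSet(points=[], k_classes=k_classes,
                             min_area_km2=min_area_km2)
    cb = jenks_breaks(vals, k=k_classes)
    top_floor = cb.breaks[-1]
    m = grid.valid_mask()
    if cm.corridor_mask is not None:
        m &= cm.corridor_mask
    top = m & (grid.values > top_floor)
    pts = regions_to_polygons(top, grid, min_area_km2, grid.values)
    return PinchPointSet(points=pts, k_classes=k_classes,
                         min_area_km2=min_area_km2)
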