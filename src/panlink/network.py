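"""Patch-corridor graph analytics and conservation prioritization.

The protected-area network is abstracted as a graph whose nodes are PA
patches and whose edges are least-cost linkages weighted by their CWD cost
(the Centrality Mapper convention).  Current-flow centrality grounds each
node in turn, injects 1 A at every other node of its component, solves the
edge-resistance circuit and accumulates the absolute current carried by
every node and edge.  Patches and corridors are then classed into three
Jenks levels (III = highest), corridors additionally cross-classed with
their relative-resistance class into a 3 x 3 bivariate ensemble of nine
construction-priority categories.  Pinch/barrier co-occurrence regions and
OECM (other effective area-based conservation measure) candidate screening
complete the optimization stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from scipy import ndimage

from .barriers import BarrierPointSet
from .circuit import PinchPointSet, regions_to_polygons
from .corridors import LeastCostPath, PatchSet
from .geoio import RasterGrid, VectorLayer, distance_to, jenks_breaks, rasterize
from .resistance import ResistanceSurface

__all__ = [
    "build_link_graph",
    "centrality",
    "classify_centrality",
    "bivariate_ensemble",
    "ensemble_priority",
    "cooccurrence_regions",
    "OecmCandidate",
    "OecmCandidateSet",
    "screen_oecm",
]

_EIGHT = ndimage.generate_binary_structure(2, 2)


def build_link_graph(patchset: PatchSet, paths: list[LeastCostPath]) -> nx.Graph:
    """Patch graph with edge attribute ``resistance`` = LCP cost (CWD)."""
    g = nx.Graph()
    for p in patchset.patches:
        g.add_node(p.id, category=p.category, area_km2=p.area_km2)
    for lcp in paths:
        g.add_edge(*lcp.pair, resistance=lcp.cost, length_m=lcp.length_m,
                   ratio=lcp.ratio)
    return g


def centrality(graph: nx.Graph) -> nx.Graph:
    """Current-flow centrality of every node and edge, in place.

    Per connected component: each node serves once as ground while every
    other node injects 1 A; the Laplacian of edge conductances
    (1/resistance) is solved for voltages and the absolute currents are
    accumulated into node attribute ``centrality`` and edge attribute
    ``centrality``.  A node's per-iteration current counts half its incident
    edge currents plus half its own net injection.  Isolated nodes get
    centrality 0 with a warning."""
    nx.set_node_attributes(graph, 0.0, "centrality")
    nx.set_edge_attributes(graph, 0.0, "centrality")
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            warnings.warn(f"isolated patch {nodes[0]}: centrality 0")
            continue
        idx = {u: i for i, u in enumerate(nodes)}
        n = len(nodes)
        lap = np.zeros((n, n))
        edges = [(u, v, 1.0 / graph.edges[u, v]["resistance"])
                 for u, v in graph.subgraph(comp).edges]
        for u, v, g in edges:
            i, j = idx[u], idx[v]
            lap[i, i] += g
            lap[j, j] += g
            lap[i, j] -= g
            lap[j, i] -= g
        for ground in range(n):
            b = np.ones(n)
            b[ground] = -(n - 1)
            keep = [i for i in range(n) if i != ground]
            v = np.zeros(n)
            v[keep] = np.linalg.solve(lap[np.ix_(keep, keep)], b[keep])
            node_cur = np.abs(b) * 0.5
            for u, w, g in edges:
                i, j = idx[u], idx[w]
                cur = abs((v[i] - v[j]) * g)
                graph.edges[u, w]["centrality"] += cur
                node_cur[i] += 0.5 * cur
                node_cur[j] += 0.5 * cur
            for u in nodes:
                graph.nodes[u]["centrality"] += float(node_cur[idx[u]])
    return graph


def classify_centrality(values: np.ndarray, k: int = 3) -> np.ndarray:
    """Jenks k-class labels of centrality values; class k (=III) highest.

    Fewer than k distinct values collapse to a single class with a warning."""
    v = np.asarray(values, dtype=np.float64)
    if np.unique(v).size < k:
        warnings.warn("fewer distinct centrality values than classes; "
                      "single class assigned")
        return np.ones(v.size, dtype=int)
    return jenks_breaks(v, k=k).classify(v)


def bivariate_ensemble(ratio_class: int, centrality_class: int) -> tuple[int, int]:
    """The 3 x 3 ensemble category of a corridor: the ordered pair
    (relative-resistance class, centrality class).  Nine categories total."""
    if ratio_class not in (1, 2, 3) or centrality_class not in (1, 2, 3):
        raise ValueError("classes must be in 1..3")
    return (ratio_class, centrality_class)


def ensemble_priority(category: tuple[int, int]) -> int:
    """Construction-priority rank 1 (best) .. 9 of an ensemble category:
    high centrality first, low resistance breaking ties -- (1, 3) is rank 1."""
    rc, cc = category
    return (3 - cc) * 3 + rc


def cooccurrence_regions(pinch: PinchPointSet, barrier: BarrierPointSet,
                         radius_m: float = 1000.0) -> list[shapely.Geometry]:
    """Regions where a pinch polygon and a barrier point lie within
    ``radius_m`` of each other; overlapping pair regions merge by union."""
    if len(pinch) == 0 or len(barrier) == 0:
        return []
    pair_regions = []
    for poly, _a, _p in pinch.points:
        for pt, _ab, _sb in barrier.points:
            if poly.distance(pt) <= radius_m:
                pair_regions.append(
                    shapely.convex_hull(shapely.union(poly, pt.buffer(1.0))))
    if not pair_regions:
        return []
    merged = shapely.union_all(pair_regions)
    if merged.geom_type == "Polygon":
        return [merged]
    return list(merged.geoms)


@dataclass
class OecmCandidate:
    polygon: shapely.Geometry
    area_km2: float
    mean_resistance: float
    distance_to_pa_m: float
    on_corridor: bool
    near_settlement: bool


@dataclass
class OecmCandidateSet:
    candidates: list[OecmCandidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def total_area_km2(self) -> float:
        return sum(c.area_km2 for c in self.candidates)


def screen_oecm(pinch: PinchPointSet,
                R: ResistanceSurface | RasterGrid,
                pa: VectorLayer,
                settlements: VectorLayer,
                min_area_km2: float = 0.1,
                resistance_pct: float = 20.0,
                settlement_dist_m: float = 2000.0,
                require_outside_pa: bool = True,
                require_focal: bool = True,
                require_low_resistance: bool = True,
                require_near_settlement: bool = True) -> OecmCandidateSet:
    """Screen corridor focal (pinch) areas for OECM candidates.

    A candidate is an 8-connected region satisfying every enabled predicate:
    outside PA boundaries, intersecting pinch focal areas, area at least
    ``min_area_km2``, mean resistance below the landscape's
    ``resistance_pct``-th percentile, and within ``settlement_dist_m`` of a
    settlement.  Predicates are individually toggleable and jointly
    conjunctive, so disabling one can only enlarge the candidate set."""
    grid = R.grid if isinstance(R, ResistanceSurface) else R
    valid = grid.valid_mask()
    base = valid.copy()

    if require_focal:
        if len(pinch) == 0:
            return OecmCandidateSet()
        focal = np.zeros(grid.shape, dtype=bool)
        for poly, _a, _p in pinch.points:
            focal |= rasterize([poly], grid)
        base &= focal
    pa_mask = rasterize(pa, grid) if len(pa) else np.zeros(grid.shape, dtype=bool)
    if require_outside_pa:
        base &= ~pa_mask
    near = None
    if require_near_settlement:
        near = distance_to(settlements, grid).values <= settlement_dist_m
        base &= near
    r_floor = float(np.percentile(grid.values[valid], resistance_pct))

    lab, nlab = ndimage.label(base, structure=_EIGHT)
    cell_km2 = grid.cell_area_km2()
    pa_dist = distance_to(pa, grid).values if len(pa) else np.full(grid.shape, np.inf)
    out = []
    for rid in range(1, nlab + 1):
        m = lab == rid
        area = float(m.sum()) * cell_km2
        if area < min_area_km2:
            continue
        mean_r = float(grid.values[m].mean())
        if require_low_resistance and mean_r >= r_floor:
            continue
        polys = regions_to_polygons(m, grid, 0.0, grid.values)
        out.append(OecmCandidate(
            polygon=polys[0][0],
            area_km2=area,
            mean_resistance=mean_r,
            distance_to_pa_m=float(pa_dist[m].min()),
            on_corridor=True,
            near_settlement=bool(near[m].all()) if near is not None else True,
        ))
    return OecmCandidateSet(out)
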