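"""Link-graph centrality, bivariate prioritization, co-occurrence and OECM
screening."""

import networkx as nx
import numpy as np
import pytest
import shapely

import panlink as pl
from panlink.barriers import BarrierPointSet
from panlink.circuit import PinchPointSet
from panlink.geoio import RasterGrid, VectorLayer
from panlink.network import (bivariate_ensemble, centrality,
                             classify_centrality, cooccurrence_regions,
                             ensemble_priority, screen_oecm)
from test_geoio import brute_jenks


def graph_from_edges(edges):
    g = nx.Graph()
    for u, v, r in edges:
        g.add_edge(u, v, resistance=r)
    return g


def pinv_oracle(g):
    """Independent route: Laplacian pseudoinverse instead of reduced solves."""
    nodes = sorted(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    lap = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = 1.0 / d["resistance"]
        i, j = idx[u], idx[v]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
    lplus = np.linalg.pinv(lap)
    node_cur = {u: 0.0 for u in nodes}
    edge_cur = {tuple(sorted(e)): 0.0 for e in g.edges}
    for ground in nodes:
        b = np.ones(n)
        b[idx[ground]] = -(n - 1)
        v = lplus @ b
        for u in nodes:
            node_cur[u] += 0.5 * abs(b[idx[u]])
        for x, y, d in g.edges(data=True):
            cur = abs((v[idx[x]] - v[idx[y]]) / d["resistance"])
            edge_cur[tuple(sorted((x, y)))] += cur
            node_cur[x] += 0.5 * cur
            node_cur[y] += 0.5 * cur
    return node_cur, edge_cur


def test_path_graph_middle_node_dominates():
    g = centrality(graph_from_edges([("a", "b", 1.0), ("b", "c", 1.0)]))
    assert g.nodes["b"]["centrality"] > g.nodes["a"]["centrality"]
    assert g.nodes["b"]["centrality"] > g.nodes["c"]["centrality"]


def test_star_graph_hub_dominates():
    g = centrality(graph_from_edges([("hub", f"s{i}", 2.0) for i in range(5)]))
    hub = g.nodes["hub"]["centrality"]
    assert all(hub > g.nodes[f"s{i}"]["centrality"] for i in range(5))


def test_random_graph_matches_pseudoinverse_oracle(rng):
    g = nx.gnm_random_graph(8, 14, seed=7)
    for u, v in g.edges:
        g.edges[u, v]["resistance"] = float(rng.uniform(0.5, 5))
    node_cur, edge_cur = pinv_oracle(g)
    centrality(g)
    for u in g.nodes:
        assert g.nodes[u]["centrality"] == pytest.approx(node_cur[u], abs=1e-8)
    for e in g.edges:
        assert g.edges[e]["centrality"] == pytest.approx(
            edge_cur[tuple(sorted(e))], abs=1e-8)


def test_centrality_conservation_per_ground_iteration():
    """Each ground iteration injects 1 A per non-ground node; the ground's
    incident edge currents must absorb exactly that total."""
    g = graph_from_edges([("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 3.0),
                          ("c", "d", 1.0)])
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    lap = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = 1.0 / d["resistance"]
        lap[idx[u], idx[u]] += w
        lap[idx[v], idx[v]] += w
        lap[idx[u], idx[v]] -= w
        lap[idx[v], idx[u]] -= w
    for ground in nodes:
        b = np.ones(n)
        b[idx[ground]] = 0.0
        keep = [i for i in range(n) if i != idx[ground]]
        v = np.zeros(n)
        v[keep] = np.linalg.solve(lap[np.ix_(keep, keep)], b[keep])
        absorbed = sum(abs(v[idx[u]] - v[idx[ground]]) / g.edges[u, ground]["resistance"]
                       for u in g.neighbors(ground))
        assert absorbed == pytest.approx(n - 1, abs=1e-8)


def test_isolated_node_gets_zero_centrality():
    g = graph_from_edges([("a", "b", 1.0)])
    g.add_node("loner")
    with pytest.warns(UserWarning, match="isolated"):
        centrality(g)
    assert g.nodes["loner"]["centrality"] == 0.0


def test_classify_centrality_matches_bruteforce_split(rng):
    vals = np.array([1.0, 2.0, 100.0, 50.0, 51.0, 2.5])
    cls = classify_centrality(vals, k=3)
    _, breaks = brute_jenks(vals, 3)
    oracle = np.searchsorted(breaks, vals, side="left") + 1
    np.testing.assert_array_equal(cls, oracle)
    assert cls[np.argmax(vals)] == 3  # class III is the highest


def test_classify_centrality_order_invariant(rng):
    vals = rng.uniform(0, 10, size=12)
    perm = rng.permutation(12)
    np.testing.assert_array_equal(classify_centrality(vals)[perm],
                                  classify_centrality(vals[perm]))


def test_classify_centrality_degenerate():
    with pytest.warns(UserWarning):
        cls = classify_centrality(np.array([3.0, 3.0, 3.0]))
    assert set(cls) == {1}


def test_bivariate_ensemble_partitions_and_priority(rng):
    cats = set()
    for _ in range(30):
        rc = int(rng.integers(1, 4))
        cc = int(rng.integers(1, 4))
        cats.add(bivariate_ensemble(rc, cc))
    assert cats <= {(r, c) for r in (1, 2, 3) for c in (1, 2, 3)}
    assert ensemble_priority((1, 3)) == 1      # low resistance, high centrality
    assert ensemble_priority((3, 1)) == 9
    ranks = sorted(ensemble_priority((r, c)) for r in (1, 2, 3) for c in (1, 2, 3))
    assert ranks == list(range(1, 10))
    with pytest.raises(ValueError):
        bivariate_ensemble(0, 1)


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------

def _pinch_at(x, y, size=100.0):
    poly = shapely.box(x - size, y - size, x + size, y + size)
    return PinchPointSet(points=[(poly, 0.2, 1.0)])


def _barrier_at(x, y):
    return BarrierPointSet(points=[(shapely.Point(x, y), 0.06, 10.0)])


def test_cooccurrence_colocated_and_distant():
    assert len(cooccurrence_regions(_pinch_at(0, 0), _barrier_at(50, 50))) == 1
    assert len(cooccurrence_regions(_pinch_at(0, 0), _barrier_at(5000, 0),
                                    radius_m=1000)) == 0
    assert cooccurrence_regions(PinchPointSet(points=[]), _barrier_at(0, 0)) == []


def test_cooccurrence_two_separate_composites():
    pinch = PinchPointSet(points=_pinch_at(0, 0).points
                          + _pinch_at(50_000, 0).points)
    barrier = BarrierPointSet(points=_barrier_at(300, 0).points
                              + _barrier_at(50_300, 0).points)
    regions = cooccurrence_regions(pinch, barrier, radius_m=1000)
    assert len(regions) == 2


# ---------------------------------------------------------------------------
# OECM screening
# ---------------------------------------------------------------------------

def _oecm_fixture():
    """30x30 landscape engineered with 3 qualifying regions plus decoys."""
    vals = np.full((30, 30), 50.0)
    grid = RasterGrid(vals, cell_size=30.0)
    s = grid.cell_size

    def box(r0, c0, r1, c1):
        return shapely.box(grid.origin_x + c0 * s, grid.origin_y - r1 * s,
                           grid.origin_x + c1 * s, grid.origin_y - r0 * s)

    # low-resistance pockets; small enough (28% of cells) that the
    # landscape's 30th-percentile floor stays at the background value
    pockets = [(2, 2, 10, 10), (2, 18, 10, 26), (18, 2, 26, 10)]
    for r0, c0, r1, c1 in pockets:
        vals[r0:r1, c0:c1] = 1.0
    # decoy pocket inside the PA
    vals[19:27, 19:27] = 1.0
    pa = VectorLayer([(box(18, 18, 28, 28), {})])
    # pinch focal areas over all four pockets
    pinch = PinchPointSet(points=[(box(*p), 1.0, 1.0) for p in pockets]
                          + [(box(19, 19, 27, 27), 1.0, 1.0)])
    settlements = VectorLayer([(shapely.Point(grid.origin_x + 15 * s,
                                              grid.origin_y - 15 * s), {})])
    return grid, pinch, pa, settlements


def test_screen_oecm_finds_engineered_regions():
    grid, pinch, pa, settlements = _oecm_fixture()
    out = screen_oecm(pinch, grid, pa, settlements, min_area_km2=0.05,
                      resistance_pct=30.0, settlement_dist_m=2000.0)
    assert len(out) == 3  # the in-PA pocket is excluded
    assert all(c.mean_resistance < 50.0 for c in out.candidates)
    assert all(c.area_km2 >= 0.05 for c in out.candidates)


def test_screen_oecm_rejects_small_area():
    grid, pinch, pa, settlements = _oecm_fixture()
    out = screen_oecm(pinch, grid, pa, settlements, min_area_km2=1e9)
    assert len(out) == 0


def test_screen_oecm_predicates_are_conjunctive():
    grid, pinch, pa, settlements = _oecm_fixture()
    strict = screen_oecm(pinch, grid, pa, settlements, min_area_km2=0.05,
                         resistance_pct=30.0)
    relaxed = screen_oecm(pinch, grid, pa, settlements, min_area_km2=0.05,
                          resistance_pct=30.0, require_outside_pa=False)
    assert len(relaxed) >= len(strict)
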