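"""Cost distance, least-cost paths and normalized corridors, checked against
an independent graph-shortest-path oracle."""

import math

import networkx as nx
import numpy as np
import pytest
import shapely

import panlink as pl
from panlink.corridors import (_allocation, build_grid_graph, classify_ratios,
                               corridor_raster, cost_distance, label_patches,
                               least_cost_paths, threshold_corridor)
from panlink.geoio import RasterGrid, VectorLayer

SQRT2 = math.sqrt(2.0)


def oracle_graph(grid):
    """Independent edge-list construction + networkx Dijkstra."""
    g = nx.Graph()
    nrows, ncols = grid.shape
    valid = grid.valid_mask()
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and valid[rr, cc]:
                    f = SQRT2 if dr and dc else 1.0
                    w = 0.5 * (grid.values[r, c] + grid.values[rr, cc]) \
                        * grid.cell_size * f
                    g.add_edge((r, c), (rr, cc), weight=w)
    return g


def oracle_cwd(grid, sources):
    g = oracle_graph(grid)
    g.add_node("SRC")
    for rc in sources:
        g.add_edge("SRC", tuple(rc), weight=0.0)
    dist = nx.single_source_dijkstra_path_length(g, "SRC")
    out = np.full(grid.shape, np.inf)
    for node, d in dist.items():
        if node != "SRC":
            out[node] = d
    return out


def square_polygon(grid, r0, c0, r1, c1):
    s = grid.cell_size
    return shapely.box(grid.origin_x + c0 * s, grid.origin_y - r1 * s,
                       grid.origin_x + c1 * s, grid.origin_y - r0 * s)


# ---------------------------------------------------------------------------
# Patch labeling
# ---------------------------------------------------------------------------

def test_single_square_polygon_is_one_patch():
    g = RasterGrid(np.ones((12, 12)), cell_size=30.0)
    pa = VectorLayer([(square_polygon(g, 2, 2, 5, 5), {"category": "forest park"})])
    ps = label_patches(pa, g)
    assert len(ps) == 1
    assert ps.patches[0].area_km2 == pytest.approx(9 * 0.0009)
    assert ps.patches[0].category == "forest park"


def test_diagonally_touching_polygons_merge_under_8_connectivity():
    g = RasterGrid(np.ones((12, 12)), cell_size=30.0)
    pa = VectorLayer([(square_polygon(g, 1, 1, 3, 3), {}),
                      (square_polygon(g, 3, 3, 5, 5), {})])
    assert len(label_patches(pa, g)) == 1


def test_generator_patch_count_matches_config(small_bundle, small_patches):
    assert len(small_patches) == small_bundle.config.n_pa


def test_empty_pa_layer_rejected():
    g = RasterGrid(np.ones((5, 5)))
    with pytest.raises(ValueError):
        label_patches(VectorLayer([]), g)


# ---------------------------------------------------------------------------
# Cost distance
# ---------------------------------------------------------------------------

def test_uniform_surface_closed_forms():
    g = RasterGrid(np.ones((9, 9)), cell_size=30.0)
    src = np.zeros((9, 9), dtype=bool)
    src[4, 4] = True
    f = cost_distance(g, src)
    assert f.cwd.values[4, 4] == 0.0
    assert f.cwd.values[4, 5] == pytest.approx(30.0)
    assert f.cwd.values[5, 5] == pytest.approx(30.0 * SQRT2)
    assert f.cwd.values[4, 6] == pytest.approx(60.0)


def test_cwd_field_matches_oracle_on_random_grid(rng):
    g = RasterGrid(rng.uniform(1, 100, size=(15, 15)), cell_size=30.0)
    src = np.zeros((15, 15), dtype=bool)
    src[0, 0] = True
    mine = cost_distance(g, src).cwd.values
    expect = oracle_cwd(g, [(0, 0)])
    np.testing.assert_allclose(mine, expect, rtol=1e-12, atol=1e-9)


def test_cwd_nonnegative_and_zero_on_sources(rng):
    g = RasterGrid(rng.uniform(1, 50, size=(10, 10)))
    src = np.zeros((10, 10), dtype=bool)
    src[[2, 7], [3, 8]] = True
    f = cost_distance(g, src)
    assert np.all(f.cwd.values[src] == 0)
    assert np.all(f.cwd.values >= 0)


def test_nodata_cells_are_impassable():
    vals = np.ones((5, 5))
    vals[:, 2] = -9999.0  # wall of nodata splits the grid
    g = RasterGrid(vals, nodata=-9999.0)
    src = np.zeros((5, 5), dtype=bool)
    src[2, 0] = True
    f = cost_distance(g, src)
    assert not f.cwd.valid_mask()[2, 4]  # unreachable right half


# ---------------------------------------------------------------------------
# Least-cost paths
# ---------------------------------------------------------------------------

def two_patch_setup(vals, cell_size=30.0):
    g = RasterGrid(np.asarray(vals, dtype=float), cell_size=cell_size)
    pa = VectorLayer([(square_polygon(g, 1, 1, 2, 2), {}),
                      (square_polygon(g, g.nrows - 2, g.ncols - 2,
                                      g.nrows - 1, g.ncols - 1), {})])
    ps = label_patches(pa, g)
    return g, ps


def test_two_patches_uniform_surface_geodesic_cost():
    g, ps = two_patch_setup(np.ones((10, 10)))
    paths, fields = least_cost_paths(ps, g, pairing="all_pairs")
    assert len(paths) == 1
    p = paths[0]
    # grid geodesic between cells (1,1) and (8,8): 7 diagonal steps
    assert p.cost == pytest.approx(7 * 30.0 * SQRT2, rel=1e-9)
    assert p.ratio == pytest.approx(1.0, rel=1e-9)


def test_path_cost_symmetric_and_matches_oracle(rng):
    g = RasterGrid(rng.uniform(1, 80, size=(14, 14)), cell_size=30.0)
    pa = VectorLayer([(square_polygon(g, 0, 0, 2, 2), {}),
                      (square_polygon(g, 11, 11, 13, 13), {})])
    ps = label_patches(pa, g)
    paths, fields = least_cost_paths(ps, g, pairing="all_pairs")
    p = paths[0]
    # oracle: multi-source to multi-target shortest path
    a_cells = [tuple(rc) for rc in np.argwhere(ps.mask(1))]
    d = oracle_cwd(g, a_cells)
    expect = min(d[tuple(rc)] for rc in np.argwhere(ps.mask(2)))
    assert p.cost == pytest.approx(expect, rel=1e-12)
    # symmetry: recompute with roles swapped
    d2 = oracle_cwd(g, [tuple(rc) for rc in np.argwhere(ps.mask(2))])
    expect2 = min(d2[tuple(rc)] for rc in np.argwhere(ps.mask(1)))
    assert expect == pytest.approx(expect2, rel=1e-12)


def test_scaling_invariance(rng):
    vals = rng.uniform(1, 40, size=(12, 12))
    g1, ps1 = two_patch_setup(vals)
    g2, ps2 = two_patch_setup(vals * 7.0)
    p1, _ = least_cost_paths(ps1, g1, pairing="all_pairs")
    p2, _ = least_cost_paths(ps2, g2, pairing="all_pairs")
    assert p2[0].cost == pytest.approx(7.0 * p1[0].cost, rel=1e-9)
    assert p2[0].cells == p1[0].cells
    assert p2[0].ratio == pytest.approx(7.0 * p1[0].ratio, rel=1e-9)


def test_triangle_inequality_nlcc_nonnegative(rng):
    g = RasterGrid(rng.uniform(1, 60, size=(12, 12)), cell_size=30.0)
    pa = VectorLayer([(square_polygon(g, 0, 0, 2, 2), {}),
                      (square_polygon(g, 9, 9, 11, 11), {})])
    ps = label_patches(pa, g)
    paths, fields = least_cost_paths(ps, g, pairing="all_pairs")
    cr = corridor_raster(paths[0].pair, fields[1], fields[2], paths[0].cost)
    v = cr.nlcc.values[cr.nlcc.valid_mask()]
    assert np.all(v >= -1e-9)
    # zero exactly on the least-cost path cells
    for rc in paths[0].cells:
        assert cr.nlcc.values[rc] == pytest.approx(0.0, abs=1e-6)


def test_threshold_corridor_limits():
    g, ps = two_patch_setup(np.ones((10, 10)))
    paths, fields = least_cost_paths(ps, g, pairing="all_pairs")
    cr = corridor_raster(paths[0].pair, fields[1], fields[2], paths[0].cost)
    m0 = threshold_corridor(cr, 0.0)
    path_cells = set(paths[0].cells)
    assert {tuple(rc) for rc in np.argwhere(m0)} >= path_cells
    m_inf = threshold_corridor(cr, np.inf)
    assert m_inf.sum() == cr.nlcc.valid_mask().sum()
    with pytest.raises(ValueError):
        threshold_corridor(cr, -1.0)


def test_adjacent_allocation_is_sparser_than_all_pairs(small_patches,
                                                       small_surface):
    adj, _ = least_cost_paths(small_patches, small_surface,
                              pairing="adjacent_allocation")
    allp, _ = least_cost_paths(small_patches, small_surface,
                               pairing="all_pairs")
    n = len(small_patches)
    assert len(allp) <= n * (n - 1) // 2
    assert len(adj) <= len(allp)
    assert len(adj) >= n - 1  # allocation neighbors span the landscape


def test_allocation_covers_reachable_cells(small_patches, small_surface):
    graph = build_grid_graph(small_surface.grid)
    alloc = _allocation(small_surface.grid, small_patches, graph)
    valid = small_surface.grid.valid_mask()
    assert np.all(alloc[valid] > 0)


def test_planted_corridor_recovered(small_bundle, small_patches, small_paths):
    """The least-cost route between the planted pair hugs the forest strip."""
    paths, _ = small_paths
    lmap = pl.patch_label_map(small_patches, small_bundle)
    want = tuple(sorted((lmap[1], lmap[2])))
    match = [p for p in paths if tuple(sorted(p.pair)) == want]
    assert match, "planted pair not linked"
    frac = pl.path_in_corridor_fraction(match[0].cells, small_bundle, (1, 2))
    assert frac >= 0.9


def test_classify_ratios_three_groups():
    paths = [pl.LeastCostPath(pair=(1, i + 2), cells=[], cost=r, length_m=1.0,
                              ratio=r) for i, r in enumerate([1, 1.1, 5, 5.2, 20])]
    classify_ratios(paths)
    cls = [p.ratio_class for p in paths]
    assert cls == [1, 1, 2, 2, 3]


def test_classify_ratios_degenerate_single_class():
    paths = [pl.LeastCostPath(pair=(1, 2), cells=[], cost=5, length_m=1, ratio=5.0),
             pl.LeastCostPath(pair=(1, 3), cells=[], cost=5, length_m=1, ratio=5.0)]
    with pytest.warns(UserWarning):
        classify_ratios(paths)
    assert all(p.ratio_class == 1 for p in paths)
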