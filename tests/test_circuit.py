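"""Circuit solver: closed-form toy circuits, Kirchhoff conservation against
a dense linear-algebra oracle, and pinch-point extraction on a bowtie."""

import numpy as np
import pytest
import shapely

import panlink as pl
from panlink.circuit import (conductance_graph, cumulative_current,
                             effective_resistance, extract_pinch_points,
                             solve_current)
from panlink.corridors import label_patches
from panlink.geoio import RasterGrid, VectorLayer


def mask_at(shape, cells):
    m = np.zeros(shape, dtype=bool)
    for rc in cells:
        m[rc] = True
    return m


def strip_grid(n, R=1.0, cell_size=30.0):
    return RasterGrid(np.full((1, n), float(R)), cell_size=cell_size)


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def test_series_chain_current_and_effective_resistance():
    # 1x3 chain, uniform R: edge cost 30R, conductance g = 1/(30R);
    # 1 A end to end -> middle node carries the full ampere, R_eff = 2/g.
    g = strip_grid(3, R=2.0)
    cm, v = solve_current(g, mask_at(g.shape, [(0, 0)]),
                          mask_at(g.shape, [(0, 2)]), injection=1.0)
    edge_cost = 2.0 * 30.0
    assert cm.current.values[0, 1] == pytest.approx(1.0, abs=1e-10)
    assert effective_resistance(g, mask_at(g.shape, [(0, 0)]),
                                mask_at(g.shape, [(0, 2)])) \
        == pytest.approx(2.0 * edge_cost, rel=1e-10)


def test_parallel_branches_split_current_and_halve_resistance():
    # two mirror-image branches between a shared source and ground column:
    # each branch carries 0.5 A; R_eff is half the single-branch value.
    vals = np.full((3, 5), np.nan)
    vals[0, :] = 1.0   # top branch
    vals[2, :] = 1.0   # bottom branch
    vals[1, 0] = 1.0   # shared source cell
    vals[1, 4] = 1.0   # shared ground cell
    g = RasterGrid(np.where(np.isnan(vals), -9999.0, vals), nodata=-9999.0)
    src = mask_at(g.shape, [(1, 0)])
    gnd = mask_at(g.shape, [(1, 4)])
    cm, _ = solve_current(g, src, gnd, injection=1.0)
    assert cm.current.values[0, 2] == pytest.approx(0.5, abs=1e-9)
    assert cm.current.values[2, 2] == pytest.approx(0.5, abs=1e-9)
    r_both = effective_resistance(g, src, gnd)
    top_only = np.where(np.isnan(vals), -9999.0, vals)
    top_only[2, :] = -9999.0
    g_top = RasterGrid(top_only, nodata=-9999.0)
    r_single = effective_resistance(g_top, src, gnd)
    assert r_both == pytest.approx(r_single / 2.0, rel=1e-9)


# ---------------------------------------------------------------------------
# Dense oracle and conservation
# ---------------------------------------------------------------------------

def dense_voltages(grid, src, gnd, injection=1.0):
    """Independent oracle: assemble the full cell Laplacian densely and
    solve with numpy, sources merged into one supernode."""
    g = conductance_graph(grid).toarray()
    valid = grid.valid_mask().ravel()
    idx = np.flatnonzero(valid)
    sub = g[np.ix_(idx, idx)]
    # merge source cells: add their rows/cols together
    pos = {int(i): k for k, i in enumerate(idx)}
    src_k = [pos[int(i)] for i in np.flatnonzero(src.ravel())]
    gnd_k = [pos[int(i)] for i in np.flatnonzero(gnd.ravel())]
    keep = [k for k in range(len(idx)) if k not in src_k[1:]]
    merged = sub.copy()
    for k in src_k[1:]:
        merged[src_k[0], :] += merged[k, :]
        merged[:, src_k[0]] += merged[:, k]
    merged = merged[np.ix_(keep, keep)]
    np.fill_diagonal(merged, 0.0)
    lap = np.diag(merged.sum(axis=1)) - merged
    remap = {k: i for i, k in enumerate(keep)}
    b = np.zeros(len(keep))
    b[remap[src_k[0]]] = injection
    gset = [remap[k] for k in gnd_k if k in remap]
    free = [i for i in range(len(keep)) if i not in gset]
    v = np.zeros(len(keep))
    v[free] = np.linalg.solve(lap[np.ix_(free, free)], b[free])
    out = np.zeros(grid.values.size)
    for k, i in remap.items():
        out[idx[k]] = v[i]
    for k in src_k[1:]:
        out[idx[k]] = v[remap[src_k[0]]]
    return out


def test_random_grid_matches_dense_solve_and_kirchhoff(rng):
    g = RasterGrid(rng.uniform(1, 50, size=(12, 12)), cell_size=30.0)
    src = mask_at(g.shape, [(0, 0)])
    gnd = mask_at(g.shape, [(11, 11)])
    cm, v = solve_current(g, src, gnd, injection=1.0)
    expect = dense_voltages(g, src, gnd)
    np.testing.assert_allclose(v, expect, atol=1e-8)
    # Kirchhoff: net current at every interior (non-source, non-ground) node
    cond = conductance_graph(g).tocoo()
    net = np.zeros(g.values.size)
    for i, j, w in zip(cond.row, cond.col, cond.data):
        net[i] += (v[j] - v[i]) * w
    interior = ~(src | gnd).ravel()
    assert np.max(np.abs(net[interior])) < 1e-8
    # conservation: current absorbed at ground equals the injection
    assert net[np.flatnonzero(gnd.ravel())[0]] == pytest.approx(1.0, abs=1e-8)


def test_effective_resistance_reciprocity(rng):
    g = RasterGrid(rng.uniform(1, 30, size=(8, 8)))
    a = mask_at(g.shape, [(0, 0), (0, 1)])
    b = mask_at(g.shape, [(7, 7)])
    assert effective_resistance(g, a, b) == pytest.approx(
        effective_resistance(g, b, a), rel=1e-10)


def test_lowering_resistance_never_raises_effective_resistance(rng):
    vals = rng.uniform(5, 50, size=(7, 7))
    g = RasterGrid(vals.copy())
    a = mask_at(g.shape, [(0, 0)])
    b = mask_at(g.shape, [(6, 6)])
    r0 = effective_resistance(g, a, b)
    for _ in range(5):
        r, c = rng.integers(0, 7, size=2)
        vals2 = vals.copy()
        vals2[r, c] = vals2[r, c] * 0.3
        r1 = effective_resistance(RasterGrid(vals2), a, b)
        assert r1 <= r0 + 1e-9


def test_disconnected_ground_raises():
    vals = np.ones((3, 5))
    vals[:, 2] = -9999.0
    g = RasterGrid(vals, nodata=-9999.0)
    with pytest.raises(ValueError, match="component"):
        solve_current(g, mask_at(g.shape, [(0, 0)]),
                      mask_at(g.shape, [(0, 4)]))


# ---------------------------------------------------------------------------
# Cumulative (all-to-one) current
# ---------------------------------------------------------------------------

def _two_patch_landscape(rng=None, nrows=10, ncols=16):
    vals = np.ones((nrows, ncols)) if rng is None else \
        rng.uniform(1, 20, size=(nrows, ncols))
    g = RasterGrid(vals, cell_size=30.0)
    s = g.cell_size
    # patches straddle the horizontal midline so a vertical flip is a symmetry
    r0, r1 = nrows // 2 - 1, nrows // 2 + 1
    pa = VectorLayer([
        (shapely.box(g.origin_x + 1 * s, g.origin_y - r1 * s,
                     g.origin_x + 3 * s, g.origin_y - r0 * s), {}),
        (shapely.box(g.origin_x + (ncols - 3) * s, g.origin_y - r1 * s,
                     g.origin_x + (ncols - 1) * s, g.origin_y - r0 * s), {}),
    ])
    return g, label_patches(pa, g)


def test_all_to_one_two_patches_equals_twice_pairwise(rng):
    g, ps = _two_patch_landscape(rng)
    cm = cumulative_current(g, ps)
    single, _ = solve_current(g, ps.mask(1), ps.mask(2), injection=1.0)
    np.testing.assert_allclose(cm.current.values, 2.0 * single.current.values,
                               atol=1e-8)


def test_mirror_symmetric_landscape_gives_symmetric_current():
    g, ps = _two_patch_landscape(None)
    cm = cumulative_current(g, ps)
    np.testing.assert_allclose(cm.current.values,
                               cm.current.values[::-1, :], atol=1e-8)


def bowtie_grid(lobe=30, neck_len=115, neck_width=1, cell=30.0):
    """Two broad lobes joined by a thin neck; patches at the far lobe edges."""
    nrows = lobe
    ncols = lobe * 2 + neck_len
    vals = np.full((nrows, ncols), -9999.0)
    vals[:, :lobe] = 1.0
    vals[:, lobe + neck_len:] = 1.0
    mid = nrows // 2
    half = neck_width // 2
    vals[mid - half: mid - half + neck_width, lobe:lobe + neck_len] = 1.0
    g = RasterGrid(vals, nodata=-9999.0, cell_size=cell)
    s = cell
    pa = VectorLayer([
        (shapely.box(g.origin_x, g.origin_y - nrows * s,
                     g.origin_x + 2 * s, g.origin_y), {}),
        (shapely.box(g.origin_x + (ncols - 2) * s, g.origin_y - nrows * s,
                     g.origin_x + ncols * s, g.origin_y), {}),
    ])
    return g, label_patches(pa, g), (mid - half, mid - half + neck_width,
                                     lobe, lobe + neck_len)


def test_bowtie_maximum_current_in_neck():
    g, ps, (r0, r1, c0, c1) = bowtie_grid()
    cm = cumulative_current(g, ps)
    cur = np.where(cm.current.valid_mask(), cm.current.values, -np.inf)
    rmax, cmax = np.unravel_index(np.argmax(cur), cur.shape)
    assert r0 <= rmax < r1 and c0 <= cmax < c1


def test_bowtie_pinch_extraction_returns_exactly_the_neck():
    g, ps, (r0, r1, c0, c1) = bowtie_grid()
    cm = cumulative_current(g, ps)
    pp = extract_pinch_points(cm, k_classes=5, min_area_km2=0.1)
    assert len(pp) == 1
    poly, area, peak = pp.points[0]
    assert area >= 0.1
    # the region lies within the neck rows (plus the funnel mouths)
    minx, miny, maxx, maxy = poly.bounds
    rows = (g.origin_y - np.array([maxy, miny])) / g.cell_size
    assert rows[0] >= r0 - 2 and rows[1] <= r1 + 2


def test_uniform_current_yields_no_pinch_points():
    g, ps = _two_patch_landscape(None, nrows=6, ncols=9)
    cm = cumulative_current(g, ps)
    vals = np.round(cm.current.values, 12)
    cm2 = pl.CurrentMap(current=g.like(np.full(g.shape, 0.5)), mode="all_to_one")
    with pytest.warns(UserWarning):
        pp = extract_pinch_points(cm2)
    assert len(pp) == 0


def test_min_area_filter_dominates():
    g, ps, _ = bowtie_grid()
    cm = cumulative_current(g, ps)
    pp = extract_pinch_points(cm, k_classes=5, min_area_km2=1e9)
    assert len(pp) == 0


def test_single_patch_rejected():
    g, ps = _two_patch_landscape(None)
    ps.patches = ps.patches[:1]
    with pytest.raises(ValueError):
        cumulative_current(g, ps)
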