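"""Seeded generator of synthetic coastal landscapes with planted
connectivity structure.

The generator emulates the structure of a densely settled coastal province:
a low coastal strip against open sea, urban cores and a road network of
high disturbance on the lowland, a mountainous forested interior of low
resistance, fragmented protected-area (PA) patches of several categories,
and biodiversity-conservation-priority-area (BCPA) polygons partially
overlapping the PAs.  Connectivity structure can be *planted*: low-
resistance forest strips between chosen PA pairs (corridors a least-cost
analysis should recover) and high-resistance urban walls stamped across
them (barriers a moving-window scan should recover).  The planted truth is
recorded cell-by-cell so detector output can be scored against it.

All randomness flows through one integer-seeded NumPy generator in a fixed
order, so a given (config, seed) pair reproduces bit-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from scipy import ndimage

from . import codes
from .geoio import RasterGrid, VectorLayer

__all__ = [
    "PA_CATEGORIES",
    "PlantedBarrier",
    "LandscapeConfig",
    "LandscapeBundle",
    "generate",
    "patch_label_map",
    "truth_report",
    "score_barrier_recovery",
    "path_in_corridor_fraction",
]

PA_CATEGORIES = ("nature reserve", "scenic spot", "forest park",
                 "geological park", "wetland park", "marine park")

ROAD_CLASSES = ("expressway", "primary", "secondary")


@dataclass
class PlantedBarrier:
    """A high-resistance wall stamped across a planted corridor.

    ``corridor`` names the (pa_id, pa_id) pair whose strip the wall crosses;
    the wall is centered ``frac`` of the way along the strip unless an
    explicit (row, col) ``center`` is given.  The wall runs perpendicular to
    the corridor, ``radius_m`` long on each side of the center and
    ``thickness_cells`` cells thick, so a moving window that restores a cut
    through it reopens the linkage.  Without a corridor the footprint is a
    disk of ``radius_m``."""

    corridor: tuple[int, int] | None = None
    center: tuple[int, int] | None = None
    radius_m: float = 300.0
    frac: float = 0.5
    thickness_cells: int = 2


@dataclass
class LandscapeConfig:
    nrows: int = 150
    ncols: int = 150
    cell_size: float = 30.0
    seed: int = 0
    n_pa: int = 8
    pa_categories: tuple[str, ...] = PA_CATEGORIES
    urban_fraction: float = 0.10
    forest_fraction: float = 0.28
    cropland_fraction: float = 0.35
    water_fraction: float = 0.02
    sea_fraction: float = 0.10
    wetland_fraction: float = 0.04
    bare_fraction: float = 0.02
    n_roads: int = 6
    n_settlements: int = 5
    n_bcpa: int = 3
    coast_side: str = "E"
    pa_radius_cells: tuple[int, int] = (3, 7)
    corridor_halfwidth_cells: int = 1
    planted_corridors: list[tuple[int, int]] = dc_field(default_factory=list)
    planted_barriers: list[PlantedBarrier] = dc_field(default_factory=list)
    origin_x: float = 500_000.0
    origin_y: float = 4_000_000.0
    crs_id: str = "EPSG:32650"

    def __post_init__(self) -> None:
        fr = (self.urban_fraction + self.forest_fraction + self.cropland_fraction
              + self.water_fraction + self.sea_fraction + self.wetland_fraction
              + self.bare_fraction)
        if fr > 1.0 + 1e-9:
            raise ValueError(f"landcover fractions sum to {fr:.3f} > 1")
        if self.coast_side not in "NSEW":
            raise ValueError("coast_side must be one of N, S, E, W")
        if self.n_roads < 3:
            raise ValueError("need n_roads >= 3 (one per road class)")
        for a, b in self.planted_corridors:
            if not (1 <= a <= self.n_pa and 1 <= b <= self.n_pa):
                raise ValueError(f"planted corridor ({a},{b}) references a "
                                 f"nonexistent patch (n_pa={self.n_pa})")
        ncorr = len(self.planted_corridors)
        for pb in self.planted_barriers:
            if pb.corridor is not None and pb.corridor not in self.planted_corridors:
                raise ValueError(f"planted barrier references unplanted corridor {pb.corridor}")
            if pb.corridor is None and pb.center is None:
                raise ValueError("planted barrier needs a corridor or a center")


@dataclass
class LandscapeBundle:
    config: LandscapeConfig
    dem: RasterGrid
    ndvi: RasterGrid
    landcover: RasterGrid
    degraded: RasterGrid          # 0/1 degraded-land mask
    roads: VectorLayer
    settlements: VectorLayer
    water: VectorLayer
    pa_polygons: VectorLayer
    bcpa_polygons: VectorLayer
    truth: dict

    def sea_mask(self) -> np.ndarray:
        return self.landcover.values == codes.SEA

    def land_mask(self) -> np.ndarray:
        return ~self.sea_mask()


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo + 1e-12)


def _coast_depth(grid_shape, coast_side: str) -> np.ndarray:
    """Per-cell distance (in cells) inland from the coast side."""
    nrows, ncols = grid_shape
    r = np.arange(nrows)[:, None] * np.ones((1, ncols))
    c = np.ones((nrows, 1)) * np.arange(ncols)[None, :]
    return {"N": r, "S": nrows - 1 - r, "W": c, "E": ncols - 1 - c}[coast_side]


def _strip_cells(a: tuple[int, int], b: tuple[int, int], halfwidth: int,
                 shape) -> list[tuple[int, int]]:
    """Cells of a straight strip between two cell centers (supercover line
    dilated by ``halfwidth`` using the 8-neighborhood)."""
    n = int(max(abs(b[0] - a[0]), abs(b[1] - a[1]))) + 1
    rr = np.rint(np.linspace(a[0], b[0], n)).astype(int)
    cc = np.rint(np.linspace(a[1], b[1], n)).astype(int)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    if halfwidth > 0:
        m = ndimage.binary_dilation(
            m, structure=ndimage.generate_binary_structure(2, 2),
            iterations=halfwidth)
    cells = np.argwhere(m)
    # order along the a->b axis so "fraction of the way along" is meaningful
    axis = np.array([b[0] - a[0], b[1] - a[1]], dtype=float)
    axis /= max(np.linalg.norm(axis), 1e-9)
    order = np.argsort((cells - np.asarray(a, dtype=float)) @ axis,
                       kind="stable")
    return [(int(r), int(c)) for r, c in cells[order]]


def generate(config: LandscapeConfig) -> LandscapeBundle:
    """Build a full landscape bundle from the config (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    nrows, ncols, s = config.nrows, config.ncols, config.cell_size
    n_cells = nrows * ncols
    shape = (nrows, ncols)

    def xy(r, c):
        return (config.origin_x + (c + 0.5) * s, config.origin_y - (r + 0.5) * s)

    # 1. sea: wavy strip along the coast side ------------------------------
    depth = _coast_depth(shape, config.coast_side)
    axis_len = ncols if config.coast_side in "NS" else nrows
    wave = 0.5 + _smooth_noise(rng, (axis_len,), sigma=axis_len / 12)
    sea_cells_target = config.sea_fraction * n_cells
    profile = wave * (sea_cells_target / wave.sum()) if sea_cells_target > 0 else wave * 0
    if config.coast_side in "NS":
        sea = depth < profile[None, :]
    else:
        sea = depth < profile[:, None]

    # 2. DEM: smoothed field, mountainous interior, low coastal strip ------
    rough = _smooth_noise(rng, shape, sigma=min(nrows, ncols) / 10)
    inland = depth / depth.max()
    dem_vals = 600.0 * (0.35 * rough + 0.65 * rough * inland) + 5.0
    dem_vals = np.where(sea, 0.0, dem_vals)

    # 3. settlements on coastal lowland ------------------------------------
    land_idx = np.argwhere(~sea)
    lowland_score = dem_vals + 3.0 * depth * (s / 100.0)
    order = np.argsort(lowland_score[~sea] + rng.normal(0, 30.0, size=land_idx.shape[0]))
    sites: list[tuple[int, int]] = []
    min_sep = max(6, min(nrows, ncols) // (config.n_settlements + 1))
    for k in order:
        r, c = map(int, land_idx[k])
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_sep ** 2 for r2, c2 in sites):
            sites.append((r, c))
        if len(sites) == config.n_settlements:
            break
    settlements = VectorLayer(
        [(shapely.Point(*xy(r, c)), {"name": f"settlement {i+1}"})
         for i, (r, c) in enumerate(sites)], config.crs_id)

    # 4. roads between settlements (classes round-robin) -------------------
    road_feats = []
    pairs = []
    for i in range(config.n_roads):
        a = sites[i % len(sites)]
        b = sites[(i + 1 + i // len(sites)) % len(sites)]
        if a == b or (a, b) in pairs or (b, a) in pairs:
            b = sites[(i + 2) % len(sites)]
            if a == b:
                continue
        pairs.append((a, b))
        road_feats.append((shapely.LineString([xy(*a), xy(*b)]),
                           {"road_class": ROAD_CLASSES[i % 3]}))
    # the roads layer is assembled after planted barriers, which may add
    # expressway segments along their walls

    # 5. urban growth around settlements to the target share ----------------
    seed_mask = np.zeros(shape, dtype=bool)
    for r, c in sites:
        seed_mask[r, c] = True
    d_set = ndimage.distance_transform_edt(~seed_mask)
    urban_cost = d_set + 8.0 * _smooth_noise(rng, shape, sigma=3)
    urban_cost[sea] = np.inf
    n_urban = int(round(config.urban_fraction * n_cells))
    urban = np.zeros(shape, dtype=bool)
    if n_urban:
        flat = np.argsort(urban_cost.ravel(), kind="stable")[:n_urban]
        urban.ravel()[flat] = True

    # 6. rivers from interior to coast --------------------------------------
    river_feats = []
    n_rivers = max(1, int(round(config.water_fraction * n_cells
                                / (0.9 * max(nrows, ncols)))))
    interior = np.argwhere((~sea) & (inland > 0.6))
    for _ in range(n_rivers):
        if interior.shape[0] == 0:
            break
        r0, c0 = map(int, interior[rng.integers(interior.shape[0])])
        # walk toward the coast with lateral meander
        pts = [(r0, c0)]
        r, c = float(r0), float(c0)
        step = {"N": (-1, 0), "S": (1, 0), "W": (0, -1), "E": (0, 1)}[config.coast_side]
        while 0 <= r < nrows and 0 <= c < ncols and not sea[int(r), int(c)]:
            r += step[0] + (rng.normal(0, 0.7) if step[0] == 0 else 0)
            c += step[1] + (rng.normal(0, 0.7) if step[1] == 0 else 0)
            if not (0 <= r < nrows and 0 <= c < ncols):
                break
            pts.append((int(r), int(c)))
        if len(pts) > 1:
            river_feats.append(
                (shapely.LineString([xy(r, c) for r, c in pts]).simplify(s),
                 {"water_type": "river"}))

    # sea polygon (cell-accurate enough for distance factors: bounding strip)
    sea_poly = shapely.union_all([
        shapely.box(config.origin_x + c * s, config.origin_y - (r + 1) * s,
                    config.origin_x + (c + 1) * s, config.origin_y - r * s)
        for r, c in np.argwhere(sea)]) if sea.any() else shapely.Polygon()
    water_feats = list(river_feats)
    if not sea_poly.is_empty:
        water_feats.append((sea_poly, {"water_type": "sea"}))
    water = VectorLayer(water_feats, config.crs_id)

    river_mask = np.zeros(shape, dtype=bool)
    for geom, _ in river_feats:
        # rasterize the polyline onto cells it passes through
        n_samp = max(2, int(geom.length / (0.5 * s)))
        for t in np.linspace(0, 1, n_samp):
            p = geom.interpolate(t, normalized=True)
            rr = int((config.origin_y - p.y) / s)
            cc = int((p.x - config.origin_x) / s)
            if 0 <= rr < nrows and 0 <= cc < ncols and not sea[rr, cc]:
                river_mask[rr, cc] = True

    # 7. land cover assembly -------------------------------------------------
    lc = np.full(shape, codes.CROPLAND, dtype=np.int32)
    land = ~sea
    free = land & ~urban & ~river_mask
    n_forest = int(round(config.forest_fraction * n_cells))
    n_wet = int(round(config.wetland_fraction * n_cells))
    n_bare = int(round(config.bare_fraction * n_cells))
    dem_key = np.where(free, dem_vals, -np.inf).ravel()
    forest_flat = np.argsort(dem_key, kind="stable")[::-1][:n_forest]
    forest = np.zeros(shape, dtype=bool)
    forest.ravel()[forest_flat] = True
    forest &= free
    # grassland: a fringe around forest
    grass = ndimage.binary_dilation(forest, iterations=2) & free & ~forest
    # wetland: lowest land near the coast
    wet_key = np.where(free & ~forest & ~grass, dem_vals + depth * 0.5, np.inf).ravel()
    wet_flat = np.argsort(wet_key, kind="stable")[:n_wet]
    wet = np.zeros(shape, dtype=bool)
    wet.ravel()[wet_flat] = True
    wet &= free & ~forest & ~grass
    # bare: scattered patches
    bare_seeds = _smooth_noise(rng, shape, sigma=2)
    bare_key = np.where(free & ~forest & ~grass & ~wet, -bare_seeds, np.inf).ravel()
    bare_flat = np.argsort(bare_key, kind="stable")[:n_bare]
    bare = np.zeros(shape, dtype=bool)
    bare.ravel()[bare_flat] = True
    bare &= free & ~forest & ~grass & ~wet

    lc[forest] = codes.FOREST
    lc[grass] = codes.GRASSLAND
    lc[wet] = codes.WETLAND
    lc[bare] = codes.BARE
    lc[river_mask] = codes.WATER
    lc[urban] = codes.URBAN
    lc[sea] = codes.SEA

    # 8. protected-area patches on forest/wetland ----------------------------
    pa_feats = []
    pa_centers: dict[int, tuple[int, int]] = {}
    candidates = np.argwhere((lc == codes.FOREST) | (lc == codes.WETLAND))
    if candidates.shape[0] == 0:
        raise ValueError("no forest/wetland cells to host PA patches")
    rmin_c, rmax_c = config.pa_radius_cells
    placed: list[tuple[int, int, int]] = []  # (r, c, radius)
    tries = 0
    order = rng.permutation(candidates.shape[0])
    oi = 0
    while len(placed) < config.n_pa:
        if oi >= order.size:
            raise ValueError(
                f"cannot place {config.n_pa} non-overlapping PA patches "
                f"(placed {len(placed)}); lower n_pa or raise forest_fraction")
        r, c = map(int, candidates[order[oi]])
        oi += 1
        rad = int(rng.integers(rmin_c, rmax_c + 1))
        if r - rad < 1 or r + rad >= nrows - 1 or c - rad < 1 or c + rad >= ncols - 1:
            continue
        if sea[max(0, r - rad):r + rad + 1, max(0, c - rad):c + rad + 1].any():
            continue
        if any((r - r2) ** 2 + (c - c2) ** 2 < (rad + rad2 + 3) ** 2
               for r2, c2, rad2 in placed):
            continue
        placed.append((r, c, rad))
    for i, (r, c, rad) in enumerate(placed):
        pid = i + 1
        pa_centers[pid] = (r, c)
        cat = config.pa_categories[i % len(config.pa_categories)]
        center = shapely.Point(*xy(r, c))
        blob = center.buffer(rad * s, quad_segs=8)
        pa_feats.append((blob, {"pa_id": pid, "category": cat}))
        # PAs sit on protected natural cover
        rr, cc = np.ogrid[:nrows, :ncols]
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2
        lc[disk & land] = codes.FOREST
    pa_polygons = VectorLayer(pa_feats, config.crs_id)

    # 9. planted corridors: forest strips between patch centers -------------
    truth_corridors = []
    strip_cells_by_pair: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for (a, b) in config.planted_corridors:
        cells = _strip_cells(pa_centers[a], pa_centers[b],
                             config.corridor_halfwidth_cells, shape)
        cells = [rc for rc in cells if land[rc]]
        for rc in cells:
            if lc[rc] != codes.SEA:
                lc[rc] = codes.FOREST
        strip_cells_by_pair[(a, b)] = cells
        truth_corridors.append({"pair": [a, b], "cells": [list(rc) for rc in cells]})

    # 10. planted barriers: urban walls across corridors ---------------------
    truth_barriers = []
    for pb in config.planted_barriers:
        if pb.corridor is not None:
            cells = strip_cells_by_pair[pb.corridor]
            if pb.center is not None:
                r0, c0 = pb.center
            else:
                r0, c0 = cells[int(pb.frac * (len(cells) - 1))]
            a_ctr, b_ctr = pa_centers[pb.corridor[0]], pa_centers[pb.corridor[1]]
            dvec = np.array([b_ctr[0] - a_ctr[0], b_ctr[1] - a_ctr[1]], float)
            dvec /= max(np.linalg.norm(dvec), 1e-9)
            perp = np.array([-dvec[1], dvec[0]])
            rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
            rel_r, rel_c = rr - r0, cc - c0
            along = rel_r * perp[0] + rel_c * perp[1]       # along the wall
            across = rel_r * dvec[0] + rel_c * dvec[1]      # across the corridor
            disk = ((np.abs(along) <= pb.radius_m / s)
                    & (np.abs(across) <= pb.thickness_cells / 2.0) & land)
            # the wall behaves like transport infrastructure: an expressway
            # segment along its axis so the road-distance factor spikes too
            half = pb.radius_m / s
            p0 = (r0 - perp[0] * half, c0 - perp[1] * half)
            p1 = (r0 + perp[0] * half, c0 + perp[1] * half)
            road_feats.append((shapely.LineString([xy(*p0), xy(*p1)]),
                               {"road_class": "expressway",
                                "planted_barrier": True}))
        else:
            r0, c0 = pb.center
            rad_c = pb.radius_m / s
            rr, cc = np.ogrid[:nrows, :ncols]
            disk = ((rr - r0) ** 2 + (cc - c0) ** 2 <= rad_c ** 2) & land
        lc[disk] = codes.URBAN
        truth_barriers.append({
            "center": [int(r0), int(c0)],
            "radius_m": float(pb.radius_m),
            "cells": [list(map(int, rc)) for rc in np.argwhere(disk)],
        })

    roads = VectorLayer(road_feats, config.crs_id)

    # 11. NDVI: cover-driven with noise, anticorrelated with urban ----------
    ndvi_base = np.select(
        [lc == codes.FOREST, lc == codes.GRASSLAND, lc == codes.WETLAND,
         lc == codes.CROPLAND, lc == codes.BARE, lc == codes.URBAN,
         lc == codes.WATER],
        [0.82, 0.62, 0.55, 0.45, 0.18, 0.10, 0.05], default=0.0)
    ndvi_vals = np.clip(ndvi_base + 0.04 * (rng.standard_normal(shape)), -0.1, 1.0)
    ndvi_vals[sea] = 0.0

    # 12. BCPA polygons partially overlapping PAs ----------------------------
    bcpa_feats = []
    for i in range(config.n_bcpa):
        pid = (i % config.n_pa) + 1
        r, c = pa_centers[pid]
        rad = placed[pid - 1][2]
        # rectangle shifted off the PA center so the overlap is partial
        dx = (rad * 1.0) * s * (1 if i % 2 == 0 else -1)
        dy = (rad * 0.6) * s * (1 if i % 3 == 0 else -1)
        cx, cy = xy(r, c)
        half = rad * 1.4 * s
        bcpa_feats.append((shapely.box(cx + dx - half, cy + dy - half,
                                       cx + dx + half, cy + dy + half),
                           {"bcpa_id": i + 1}))
    bcpa_polygons = VectorLayer(bcpa_feats, config.crs_id)

    # 13. degraded-land mask: bare plus a band around urban ------------------
    degraded = (lc == codes.BARE) | (ndimage.binary_dilation(urban) & ~urban
                                     & land & (lc == codes.CROPLAND))

    geo = dict(origin_x=config.origin_x, origin_y=config.origin_y,
               cell_size=s, crs_id=config.crs_id)
    truth = {
        "seed": config.seed,
        "pa_centers": {str(k): list(v) for k, v in pa_centers.items()},
        "corridors": truth_corridors,
        "barriers": truth_barriers,
    }
    return LandscapeBundle(
        config=config,
        dem=RasterGrid(dem_vals.astype(np.float64), nodata=-9999.0, **geo),
        ndvi=RasterGrid(ndvi_vals.astype(np.float64), nodata=-9999.0, **geo),
        landcover=RasterGrid(lc, nodata=-1, **geo),
        degraded=RasterGrid(degraded.astype(np.int32), nodata=-1, **geo),
        roads=roads,
        settlements=settlements,
        water=water,
        pa_polygons=pa_polygons,
        bcpa_polygons=bcpa_polygons,
        truth=truth,
    )


def patch_label_map(patchset, bundle: LandscapeBundle) -> dict[int, int]:
    """Map generator pa_id -> downstream patch label (component id), via the
    patch center cell.  Labeling order is raster-scan order, not placement
    order, so truth scoring must translate through this map."""
    lab = patchset.labels.values
    return {int(k): int(lab[tuple(v)])
            for k, v in bundle.truth["pa_centers"].items()}


def truth_report(bundle: LandscapeBundle) -> dict:
    """Machine-readable planted structure: corridor cell-paths and barrier
    footprints, for recovery scoring of downstream detectors."""
    return {
        "seed": bundle.truth["seed"],
        "corridors": [
            {"pair": t["pair"], "n_cells": len(t["cells"]), "cells": t["cells"]}
            for t in bundle.truth["corridors"]
        ],
        "barriers": [
            {"center": t["center"], "radius_m": t["radius_m"],
             "n_cells": len(t["cells"]), "cells": t["cells"]}
            for t in bundle.truth["barriers"]
        ],
    }


def score_barrier_recovery(detected_cells: list[tuple[int, int]],
                           bundle: LandscapeBundle,
                           tolerance_cells: int = 2) -> float:
    """Recall of planted barriers: fraction whose footprint (dilated by
    ``tolerance_cells``) contains at least one detected point."""
    barriers = bundle.truth["barriers"]
    if not barriers:
        return 1.0 if not detected_cells else 0.0
    hit = 0
    for t in barriers:
        foot = {tuple(rc) for rc in t["cells"]}
        ok = False
        for (r, c) in detected_cells:
            if any((r - fr) ** 2 + (c - fc) ** 2 <= tolerance_cells ** 2
                   for fr, fc in foot):
                ok = True
                break
        hit += ok
    return hit / len(barriers)


def path_in_corridor_fraction(path_cells: list[tuple[int, int]],
                              bundle: LandscapeBundle,
                              pair: tuple[int, int],
                              dilate: int = 1) -> float:
    """Fraction of a recovered path's cells lying inside the planted strip
    for ``pair`` (strip dilated by ``dilate`` cells; patch-interior cells of
    the pair are counted as in-strip since the strip spans center to center)."""
    for t in bundle.truth["corridors"]:
        if tuple(t["pair"]) == pair or tuple(t["pair"]) == pair[::-1]:
            m = np.zeros(bundle.landcover.shape, dtype=bool)
            for r, c in t["cells"]:
                m[r, c] = True
            if dilate:
                m = ndimage.binary_dilation(
                    m, structure=ndimage.generate_binary_structure(2, 2),
                    iterations=dilate)
            inside = sum(1 for rc in path_cells if m[rc])
            return inside / max(len(path_cells), 1)
    raise KeyError(f"no planted corridor for pair {pair}")
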