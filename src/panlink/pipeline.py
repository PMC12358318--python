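"""End-to-end orchestration: simulate -> resistance -> corridors -> circuit
-> barriers -> network -> assess, with a reproducible run manifest.

Each stage writes its artifacts (GeoTIFF / GeoJSON / CSV / JSON) under the
output directory and records their SHA-256 checksums; re-running with the
same config and seed reproduces identical checksums.  A stage whose outputs
already exist is skipped unless an upstream stage re-executed, so deleting
one intermediate re-runs only it and its downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import codes
from .ahp import PairwiseMatrix, WeightVector, compute_weights, DEFAULT_LABELS
from .assess import (composition, mean_lcp_cost, overlap_pct, pan_footprint,
                     sdg_indicators, spearman_matrix)
from .barriers import (DEFAULT_RADII_M, extract_barrier_points, scan_barriers)
from .circuit import cumulative_current, extract_pinch_points
from .corridors import (classify_ratios, corridor_raster, label_patches,
                        least_cost_paths, threshold_corridor)
from .geoio import (RasterGrid, VectorLayer, distance_to, rasterize, terrain,
                    write_raster, write_vector)
from .network import (build_link_graph, centrality, classify_centrality,
                      cooccurrence_regions, ensemble_priority, screen_oecm)
from .resistance import (DEFAULT_LANDCOVER_TABLE, FactorLayer,
                         ResistanceSurface, composite_surface,
                         reclassify_factor)
from .synthetic import LandscapeBundle, LandscapeConfig, generate

__all__ = [
    "STAGES",
    "PipelineConfig",
    "RunManifest",
    "default_matrix",
    "build_factor_layers",
    "compute_resistance",
    "run_pipeline",
]

#: The workflow stages, in dependency order.
STAGES = ("simulate", "resistance", "corridors", "circuit", "barriers",
          "network", "assess")

#: Default relative-importance scores behind the built-in comparison matrix:
#: anthropogenic disturbance factors dominate coastal connectivity.
DEFAULT_FACTOR_SCORES = {
    "E1": 1.0, "E2": 1.05, "E3": 0.97, "E4": 1.02, "E5": 0.95,
    "A1": 2.5, "A2.1": 2.2, "A2.2": 2.25, "A2.3": 2.3, "A3": 2.35,
}


def default_matrix() -> PairwiseMatrix:
    """Perfectly consistent pairwise matrix from the default factor scores
    (a_ij = s_i / s_j), used when no expert matrix is supplied."""
    labels = tuple(DEFAULT_FACTOR_SCORES)
    s = np.array([DEFAULT_FACTOR_SCORES[k] for k in labels])
    return PairwiseMatrix(labels=labels, a=np.outer(s, 1.0 / s))


@dataclass
class PipelineConfig:
    """Every tunable threshold of the workflow, each appearing exactly once."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    corridor_threshold_cwd: float = 10_000.0   # corridor width threshold (CWD)
    circuit_width_cwd: float = 10_000.0        # current-map corridor clip (CWD)
    radii_m: tuple[float, ...] = DEFAULT_RADII_M
    pinch_k: int = 5
    pinch_min_area_km2: float = 0.1
    barrier_k: int = 5
    barrier_min_area_km2: float = 0.05
    barrier_stride: int = 2
    centrality_k: int = 3
    coverage_target_pct: float = 30.0
    pairing: str = "adjacent_allocation"
    cooccur_radius_m: float = 1000.0
    oecm_min_area_km2: float = 0.1
    oecm_resistance_pct: float = 20.0
    oecm_settlement_dist_m: float = 2000.0
    mountain_elev_m: float = 300.0
    subzone_tiles: int = 3                      # sub-zone grid for correlations
    sea_passable: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def checksums(self) -> dict[str, dict[str, str]]:
        return {s["name"]: s["checksums"] for s in self.stages}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "parameters": self.parameters, "stages": self.stages}, indent=2))


# ---------------------------------------------------------------------------
# Factor stack and resistance
# ---------------------------------------------------------------------------

def build_factor_layers(bundle: LandscapeBundle,
                        sea_passable: bool = False) -> dict[str, FactorLayer]:
    """The ten resistance factors from a landscape bundle.

    E1 elevation, E2 slope, E3 relief (ascending: higher terrain resists),
    E4 NDVI and A2.x road / A3 settlement distances (descending: greener and
    farther from disturbance is cheaper), E5 distance to water (ascending),
    A1 land cover via the category table.  Sea cells are nodata (impassable)
    unless ``sea_passable``."""
    dem, ndvi, lc = bundle.dem, bundle.ndvi, bundle.landcover
    sea = bundle.sea_mask()
    slope, relief = terrain(dem)

    def masked(grid: RasterGrid) -> RasterGrid:
        if sea_passable:
            return grid
        vals = np.where(sea, grid.nodata, grid.values)
        return grid.like(vals)

    def road_layer(cls: str) -> VectorLayer:
        sub = bundle.roads.filter(lambda g, a: a.get("road_class") == cls)
        if len(sub) == 0:
            raise ValueError(f"no roads of class '{cls}' in the bundle")
        return sub

    factors = {
        "E1": FactorLayer("E1", masked(dem), "ascending"),
        "E2": FactorLayer("E2", masked(slope), "ascending"),
        "E3": FactorLayer("E3", masked(relief), "ascending"),
        "E4": FactorLayer("E4", masked(ndvi), "descending"),
        "E5": FactorLayer("E5", masked(distance_to(bundle.water, dem)), "ascending"),
        "A1": FactorLayer("A1", masked(lc), category_table=DEFAULT_LANDCOVER_TABLE),
        "A2.1": FactorLayer("A2.1", masked(distance_to(road_layer("expressway"), dem)), "descending"),
        "A2.2": FactorLayer("A2.2", masked(distance_to(road_layer("primary"), dem)), "descending"),
        "A2.3": FactorLayer("A2.3", masked(distance_to(road_layer("secondary"), dem)), "descending"),
        "A3": FactorLayer("A3", masked(distance_to(bundle.settlements, dem)), "descending"),
    }
    return factors


def compute_resistance(bundle: LandscapeBundle, weights: WeightVector,
                       sea_passable: bool = False) -> ResistanceSurface:
    """Reclassify all ten factors and overlay them with the given weights."""
    factors = build_factor_layers(bundle, sea_passable=sea_passable)
    reclass = {fid: reclassify_factor(f) for fid, f in factors.items()}
    return composite_surface(reclass, weights)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 matrix: PairwiseMatrix | None = None,
                 force: bool = False) -> RunManifest:
    """Execute the full workflow, writing artifacts and a manifest JSON.

    A stage is skipped when all its output files already exist and no
    upstream stage executed in this run (``force`` re-runs everything); a
    skipped stage re-derives its in-memory state deterministically but
    leaves its files untouched.  Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = matrix if matrix is not None else default_matrix()
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.landscape.seed,
        parameters={"corridor_threshold_cwd": config.corridor_threshold_cwd,
                    "circuit_width_cwd": config.circuit_width_cwd,
                    "radii_m": list(config.radii_m),
                    "coverage_target_pct": config.coverage_target_pct})

    state: dict = {}
    upstream_ran = force

    def stage(name: str, outputs: list[str], compute_state, write_outputs):
        nonlocal upstream_ran
        paths = [out / p for p in outputs]
        skip = (not upstream_ran) and all(p.exists() for p in paths)
        t0 = time.perf_counter()
        compute_state()
        if not skip:
            write_outputs()
            upstream_ran = True
        manifest.stages.append({
            "name": name,
            "executed": not skip,
            "outputs": outputs,
            "checksums": {p.name: _sha256(p) for p in paths},
            "wall_clock_s": round(time.perf_counter() - t0, 3),
        })

    # -- simulate ----------------------------------------------------------
    def simulate_state():
        state["bundle"] = generate(config.landscape)

    def simulate_write():
        bundle = state["bundle"]
        write_raster(bundle.dem, out / "dem.tif")
        write_raster(bundle.ndvi, out / "ndvi.tif")
        write_raster(bundle.landcover, out / "landcover.tif")
        write_raster(bundle.degraded, out / "degraded.tif")
        write_vector(bundle.roads, out / "roads.geojson")
        write_vector(bundle.settlements, out / "settlements.geojson")
        write_vector(bundle.water, out / "water.geojson")
        write_vector(bundle.pa_polygons, out / "pa.geojson")
        write_vector(bundle.bcpa_polygons, out / "bcpa.geojson")
        (out / "truth.json").write_text(json.dumps(bundle.truth))

    stage("simulate",
          ["dem.tif", "ndvi.tif", "landcover.tif", "degraded.tif",
           "roads.geojson", "settlements.geojson", "water.geojson",
           "pa.geojson", "bcpa.geojson", "truth.json"],
          simulate_state, simulate_write)

    # -- resistance (AHP weights derived inside the stage) -----------------
    def resistance_state():
        wv = compute_weights(matrix)
        state["weights"] = wv
        state["R"] = compute_resistance(state["bundle"], wv,
                                        sea_passable=config.sea_passable)

    def resistance_write():
        wv = state["weights"]
        write_raster(state["R"].grid, out / "resistance.tif")
        (out / "weights.json").write_text(json.dumps(
            {"weights": wv.as_dict(), "lambda_max": wv.lambda_max,
             "ci": wv.ci, "cr": wv.cr}, indent=2))

    stage("resistance", ["resistance.tif", "weights.json"],
          resistance_state, resistance_write)

    # -- corridors ---------------------------------------------------------
    def corridors_state():
        bundle, R = state["bundle"], state["R"]
        patchset = label_patches(bundle.pa_polygons, R.grid,
                                 valid_mask=R.grid.valid_mask())
        paths, fields = least_cost_paths(patchset, R, pairing=config.pairing)
        classify_ratios(paths)
        nlccs = [corridor_raster(p.pair, fields[p.pair[0]], fields[p.pair[1]],
                                 p.cost) for p in paths]
        nlcc_min = np.full(R.grid.shape, np.inf)
        for cr in nlccs:
            v = np.where(cr.nlcc.valid_mask(), cr.nlcc.values, np.inf)
            nlcc_min = np.minimum(nlcc_min, v)
        state.update(patchset=patchset, paths=paths, fields=fields, nlccs=nlccs)
        state["nlcc_min"] = R.grid.like(
            np.where(np.isfinite(nlcc_min), nlcc_min, R.grid.nodata))

    def corridors_write():
        write_raster(state["nlcc_min"], out / "nlcc_min.tif")
        rows = ["pair_a,pair_b,cost,length_m,ratio,ratio_class"]
        for p in state["paths"]:
            rows.append(f"{p.pair[0]},{p.pair[1]},{p.cost:.6f},"
                        f"{p.length_m:.3f},{p.ratio:.6f},{p.ratio_class}")
        (out / "paths.csv").write_text("\n".join(rows) + "\n")

    stage("corridors", ["nlcc_min.tif", "paths.csv"],
          corridors_state, corridors_write)

    # -- circuit -----------------------------------------------------------
    def circuit_state():
        R, patchset = state["R"], state["patchset"]
        mask = state["nlcc_min"].valid_mask() & (
            state["nlcc_min"].values <= config.circuit_width_cwd)
        cm = cumulative_current(R, patchset, corridor_mask=mask)
        state["current"] = cm
        state["pinch"] = extract_pinch_points(
            cm, k_classes=config.pinch_k,
            min_area_km2=config.pinch_min_area_km2)

    def circuit_write():
        write_raster(state["current"].current, out / "current.tif")
        feats = [(poly, {"area_km2": a, "peak_current": pc})
                 for poly, a, pc in state["pinch"].points]
        write_vector(VectorLayer(feats, state["R"].grid.crs_id),
                     out / "pinch.geojson")

    stage("circuit", ["current.tif", "pinch.geojson"],
          circuit_state, circuit_write)

    # -- barriers ----------------------------------------------------------
    def barriers_state():
        R, paths, fields = state["R"], state["paths"], state["fields"]
        fld = scan_barriers(R, paths, fields, radii_m=config.radii_m,
                            stride=config.barrier_stride)
        state["improvement"] = fld
        state["barriers"] = extract_barrier_points(
            fld, k_classes=config.barrier_k,
            min_area_km2=config.barrier_min_area_km2)

    def barriers_write():
        write_raster(state["improvement"].score, out / "improvement.tif")
        feats = [(pt, {"area_km2": a, "max_score": sc})
                 for pt, a, sc in state["barriers"].points]
        write_vector(VectorLayer(feats, state["R"].grid.crs_id),
                     out / "barriers.geojson")

    stage("barriers", ["improvement.tif", "barriers.geojson"],
          barriers_state, barriers_write)

    # -- network -----------------------------------------------------------
    def network_state():
        bundle, R = state["bundle"], state["R"]
        patchset, paths = state["patchset"], state["paths"]
        g = centrality(build_link_graph(patchset, paths))
        node_vals = np.array([g.nodes[p.id]["centrality"]
                              for p in patchset.patches])
        node_cls = classify_centrality(node_vals, k=config.centrality_k)
        edge_vals = np.array([g.edges[p.pair]["centrality"] for p in paths])
        edge_cls = classify_centrality(edge_vals, k=config.centrality_k)
        for p, ev, ec in zip(paths, edge_vals, edge_cls):
            p.centrality, p.centrality_class = float(ev), int(ec)
        state["graph"], state["node_classes"] = g, node_cls
        state["cooccur"] = cooccurrence_regions(
            state["pinch"], state["barriers"],
            radius_m=config.cooccur_radius_m)
        state["oecm"] = screen_oecm(
            state["pinch"], R, bundle.pa_polygons, bundle.settlements,
            min_area_km2=config.oecm_min_area_km2,
            resistance_pct=config.oecm_resistance_pct,
            settlement_dist_m=config.oecm_settlement_dist_m)

    def network_write():
        patchset, paths = state["patchset"], state["paths"]
        g = state["graph"]
        rows = ["pair_a,pair_b,ratio_class,centrality,centrality_class,"
                "ensemble,priority"]
        for p in paths:
            cat = (p.ratio_class, p.centrality_class)
            rows.append(f"{p.pair[0]},{p.pair[1]},{p.ratio_class},"
                        f"{p.centrality:.6f},{p.centrality_class},"
                        f"R{cat[0]}C{cat[1]},{ensemble_priority(cat)}")
        (out / "links.csv").write_text("\n".join(rows) + "\n")
        nrows_csv = ["patch_id,category,area_km2,centrality,centrality_class"]
        for p, cls in zip(patchset.patches, state["node_classes"]):
            nrows_csv.append(f"{p.id},{p.category},{p.area_km2:.4f},"
                             f"{g.nodes[p.id]['centrality']:.6f},{int(cls)}")
        (out / "patches.csv").write_text("\n".join(nrows_csv) + "\n")
        crs = state["R"].grid.crs_id
        feats = [(c.polygon, {"area_km2": c.area_km2,
                              "mean_resistance": c.mean_resistance})
                 for c in state["oecm"].candidates]
        write_vector(VectorLayer(feats, crs), out / "oecm.geojson")
        write_vector(VectorLayer([(r, {}) for r in state["cooccur"]], crs),
                     out / "cooccurrence.geojson")

    stage("network", ["links.csv", "patches.csv", "oecm.geojson",
                      "cooccurrence.geojson"], network_state, network_write)

    # -- assess ------------------------------------------------------------
    def assess_state():
        bundle, R = state["bundle"], state["R"]
        patchset, paths = state["patchset"], state["paths"]
        t = mean_lcp_cost(paths)
        land = bundle.land_mask() & R.grid.valid_mask()
        foot = pan_footprint(patchset.mask(), state["nlccs"], R.grid, t,
                             study_mask=land,
                             target_pct=config.coverage_target_pct)
        pa_only = pan_footprint(patchset.mask(), [], R.grid, 0.0,
                                study_mask=land,
                                target_pct=config.coverage_target_pct)
        bcpa_mask = rasterize(bundle.bcpa_polygons, R.grid)
        zones = {"PA": patchset.mask(), "PAN": foot.mask, "region": land}
        table = sdg_indicators(zones, bundle.landcover, bundle.dem, bcpa_mask,
                               bundle.degraded.values > 0,
                               mountain_elev_m=config.mountain_elev_m)
        nt = config.subzone_tiles
        sub = {}
        nr, nc = R.grid.shape
        for i in range(nt):
            for j in range(nt):
                m = np.zeros(R.grid.shape, dtype=bool)
                m[i * nr // nt:(i + 1) * nr // nt,
                  j * nc // nt:(j + 1) * nc // nt] = True
                m &= land
                if m.any():
                    sub[f"tile_{i}_{j}"] = m
        subtable = sdg_indicators(sub, bundle.landcover, bundle.dem,
                                  bcpa_mask, bundle.degraded.values > 0,
                                  mountain_elev_m=config.mountain_elev_m)
        state["footprint"], state["pa_only"] = foot, pa_only
        state["indicators"] = table
        state["spearman"] = spearman_matrix(subtable)

    def assess_write():
        bundle, R = state["bundle"], state["R"]
        foot, pa_only = state["footprint"], state["pa_only"]
        write_raster(R.grid.like(foot.mask.astype(np.int32), nodata=-1),
                     out / "footprint.tif")
        state["indicators"].to_csv(out / "sdg_indicators.csv")
        state["spearman"].to_csv(out / "sdg_spearman.csv")
        report = {
            "threshold_cwd": foot.threshold_used,
            "pa_coverage_pct": pa_only.coverage_pct,
            "pan_coverage_pct": foot.coverage_pct,
            "meets_target": bool(foot.meets_target),
            "target_pct": config.coverage_target_pct,
            "bcpa_overlap_pa_pct": overlap_pct(pa_only, bundle.bcpa_polygons),
            "bcpa_overlap_pan_pct": overlap_pct(foot, bundle.bcpa_polygons),
            "composition_pct": composition(foot, bundle.landcover),
            "n_paths": len(state["paths"]),
            "n_pinch_points": len(state["pinch"]),
            "n_barrier_points": len(state["barriers"]),
            "n_oecm": len(state["oecm"]),
            "n_cooccurrence_regions": len(state["cooccur"]),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))

    stage("assess", ["footprint.tif", "sdg_indicators.csv",
                     "sdg_spearman.csv", "report.json"],
          assess_state, assess_write)

    manifest.to_json(out / "manifest.json")
    return manifest
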