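"""Conservation-target accounting for the protected-area network (PAN).

The PAN footprint is the union of PA patches with every corridor cell whose
normalized least-cost value stays within a threshold ``t`` (conventionally
the mean least-cost distance between patches).  Coverage of the study area
is compared with the 30% area-based conservation target; overlap with
biodiversity-conservation priority areas (BCPAs), land-use composition of
the footprint, and four area-share SDG 15 indicator capacities per zone
(PA / PAN / region) follow from mask intersections, with indicator
synergies summarized by a Spearman rank-correlation matrix over sub-zones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import codes
from .corridors import CorridorRaster, LeastCostPath
from .geoio import RasterGrid, VectorLayer, rasterize

__all__ = [
    "PanFootprint",
    "pan_footprint",
    "mean_lcp_cost",
    "overlap_pct",
    "composition",
    "sdg_indicators",
    "spearman_matrix",
    "SDG_COLUMNS",
]

#: Indicator columns: forest share (15.1.1), protected share of
#: important-biodiversity area (15.1.2), degraded-land share (15.3.1,
#: lower is better), mountain green cover index (15.4.1).  All in percent.
SDG_COLUMNS = ("sdg_15_1_1", "sdg_15_1_2", "sdg_15_3_1", "sdg_15_4_1")

#: Polarity metadata: +1 higher is better, -1 lower is better.
SDG_POLARITY = {"sdg_15_1_1": 1, "sdg_15_1_2": 1, "sdg_15_3_1": -1, "sdg_15_4_1": 1}


@dataclass
class PanFootprint:
    mask: np.ndarray            # PA union thresholded corridors
    grid: RasterGrid
    threshold_used: float       # CWD units
    area_km2: float
    coverage_pct: float         # of the study area
    target_pct: float = 30.0

    @property
    def meets_target(self) -> bool:
        return self.coverage_pct >= self.target_pct


def mean_lcp_cost(paths: Sequence[LeastCostPath]) -> float:
    """Mean least-cost distance between patch pairs -- the conventional
    corridor threshold for footprint accounting."""
    if not paths:
        raise ValueError("no least-cost paths")
    return float(np.mean([p.cost for p in paths]))


def pan_footprint(pa_mask: np.ndarray,
                  corridors: Sequence[CorridorRaster],
                  grid: RasterGrid,
                  t: float,
                  study_mask: np.ndarray | None = None,
                  target_pct: float = 30.0) -> PanFootprint:
    """PAN footprint = PA cells union cells with min-over-pairs nlcc <= t.

    Coverage is reported against ``study_mask`` (default: all valid cells
    of the grid).  Pass an empty corridor list with t = 0 for the PA-only
    baseline."""
    pa_mask = np.asarray(pa_mask, dtype=bool)
    if not pa_mask.any() and not corridors:
        raise ValueError("no PAs and no corridors: footprint undefined")
    if t < 0:
        raise ValueError("threshold must be non-negative")
    study = grid.valid_mask() if study_mask is None else np.asarray(study_mask, bool)
    foot = pa_mask.copy()
    for cr in corridors:
        g = cr.nlcc
        foot |= g.valid_mask() & (g.values <= t)
    foot &= study | pa_mask
    area = grid.area_km2(foot & study)
    coverage = 100.0 * np.count_nonzero(foot & study) / max(np.count_nonzero(study), 1)
    return PanFootprint(mask=foot, grid=grid, threshold_used=float(t),
                        area_km2=area, coverage_pct=coverage,
                        target_pct=target_pct)


def overlap_pct(footprint: PanFootprint, bcpa: VectorLayer) -> float:
    """100 x area(BCPA intersect footprint) / area(BCPA), grid-native."""
    if len(bcpa) == 0:
        raise ValueError("BCPA layer is empty")
    bm = rasterize(bcpa, footprint.grid)
    denom = np.count_nonzero(bm)
    if denom == 0:
        raise ValueError("BCPA polygons rasterized to zero cells")
    return 100.0 * np.count_nonzero(bm & footprint.mask) / denom


def composition(footprint: PanFootprint, landcover: RasterGrid) -> dict[str, float]:
    """Per-class percentage share of the footprint area (sums to 100)."""
    footprint.grid.require_aligned(landcover, "landcover")
    vals = landcover.values[footprint.mask & landcover.valid_mask()]
    n = vals.size
    if n == 0:
        return {}
    out = {}
    for code in np.unique(vals):
        name = codes.LANDCOVER_NAMES.get(int(code), f"class {int(code)}")
        out[name] = 100.0 * np.count_nonzero(vals == code) / n
    return out


def sdg_indicators(zones: Mapping[str, np.ndarray],
                   landcover: RasterGrid,
                   dem: RasterGrid,
                   bcpa_mask: np.ndarray,
                   degraded_mask: np.ndarray,
                   forest_codes: frozenset[int] = frozenset({codes.FOREST}),
                   green_codes: frozenset[int] = frozenset(
                       {codes.FOREST, codes.GRASSLAND, codes.WETLAND}),
                   mountain_elev_m: float = 300.0) -> pd.DataFrame:
    """Area-share SDG 15 indicator capacities per zone, in percent.

    15.1.1 forest share of the zone; 15.1.2 share of the important-
    biodiversity (BCPA) area lying inside the zone; 15.3.1 degraded-land
    share of the zone (lower is better, reported as-is); 15.4.1 green-cover
    share of zone cells above ``mountain_elev_m`` (NaN when the zone has no
    mountain cells -- undefined, not zero)."""
    landcover.require_aligned(dem, "dem")
    lc = landcover.values
    bcpa_mask = np.asarray(bcpa_mask, dtype=bool)
    degraded_mask = np.asarray(degraded_mask, dtype=bool)
    forest = np.isin(lc, list(forest_codes))
    green = np.isin(lc, list(green_codes))
    mountain = dem.valid_mask() & (dem.values >= mountain_elev_m)
    n_bcpa = np.count_nonzero(bcpa_mask)

    rows = {}
    for name, zone in zones.items():
        zone = np.asarray(zone, dtype=bool) & landcover.valid_mask()
        nz = np.count_nonzero(zone)
        if nz == 0:
            raise ValueError(f"zone '{name}' has zero area")
        zmountain = np.count_nonzero(zone & mountain)
        rows[name] = {
            "sdg_15_1_1": 100.0 * np.count_nonzero(zone & forest) / nz,
            "sdg_15_1_2": (100.0 * np.count_nonzero(zone & bcpa_mask) / n_bcpa
                           if n_bcpa else np.nan),
            "sdg_15_3_1": 100.0 * np.count_nonzero(zone & degraded_mask) / nz,
            "sdg_15_4_1": (100.0 * np.count_nonzero(zone & mountain & green)
                           / zmountain if zmountain else np.nan),
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SDG_COLUMNS))


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation (average-rank ties) across the
    table's rows; symmetric with unit diagonal.  A constant column is
    undefined and reported as NaN."""
    if len(table) < 4:
        raise ValueError("need at least 4 sub-zone rows for rank correlation")
    cols = list(table.columns)
    n = len(cols)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            xi, xj = table.iloc[:, i].to_numpy(), table.iloc[:, j].to_numpy()
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 4 or np.unique(xi[ok]).size < 2 or np.unique(xj[ok]).size < 2:
                if i == j and np.unique(xi[ok]).size >= 2:
                    out[i, j] = 1.0
                continue
            rho = stats.spearmanr(xi[ok], xj[ok]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=cols, columns=cols)
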