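"""Single-factor resistance layers on the five-level movement-resistance
scale and their expert-weighted composite surface.

Each factor (five ecological-suitability layers E1..E5, five anthropogenic-
disturbance layers A1..A3) is reclassified onto the ordinal resistance levels
{1, 10, 25, 50, 100} -- 1 is unimpeded movement, 100 a complete barrier.
Continuous factors default to a Jenks k=5 partition of their own valid
values, oriented by the factor's ``direction``; categorical land cover uses
an explicit code -> level table.  The composite surface is the weight-
normalized sum R(x) = sum_i w_i * level_i(x), which with unit-sum weights is
bounded in [1, 100]; any global rescaling of R leaves least-cost paths,
corridors, current ratios and all Jenks classifications unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import codes
from .ahp import WeightVector
from .geoio import ClassBreaks, RasterGrid, jenks_breaks

__all__ = [
    "RESISTANCE_LEVELS",
    "DEFAULT_LANDCOVER_TABLE",
    "FactorLayer",
    "ResistanceSurface",
    "reclassify_factor",
    "composite_surface",
]

#: The five ordinal movement-resistance levels, lowest to highest.
RESISTANCE_LEVELS = (1, 10, 25, 50, 100)

#: Default land-cover (A1) category table.  The source study prints no table;
#: this is the package's explicit stand-in: closed natural cover is most
#: permeable, built-up land and open water crossings are barriers.
DEFAULT_LANDCOVER_TABLE: dict[int, int] = {
    codes.FOREST: 1,
    codes.WETLAND: 1,
    codes.GRASSLAND: 10,
    codes.CROPLAND: 25,
    codes.BARE: 50,
    codes.URBAN: 100,
    codes.WATER: 100,
    codes.SEA: 100,
}


@dataclass
class FactorLayer:
    """One resistance factor before reclassification.

    direction='ascending' means larger raw values carry more resistance
    (elevation, slope, relief); 'descending' means larger raw values carry
    less (NDVI, distance from roads/settlements).  ``category_table`` marks
    the factor as categorical and overrides breaks/direction.
    """

    factor_id: str
    raw: RasterGrid
    direction: str = "ascending"
    breaks: ClassBreaks | None = None
    category_table: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("ascending", "descending"):
            raise ValueError("direction must be 'ascending' or 'descending'")


@dataclass
class ResistanceSurface:
    """Composite resistance raster and the weights that built it."""

    grid: RasterGrid
    weights_used: WeightVector | None = None


def reclassify_factor(layer: FactorLayer) -> RasterGrid:
    """Map a factor onto the five resistance levels {1, 10, 25, 50, 100}.

    Continuous factors: Jenks k=5 on the layer's valid values (or the
    layer's explicit breaks), class 1..5 -> level, reversed for
    direction='descending'.  Categorical factors: table lookup; a land-cover
    code missing from the table raises naming the code.
    """
    raw = layer.raw
    valid = raw.valid_mask()
    out = np.full(raw.shape, raw.nodata, dtype=np.float64)

    if layer.category_table is not None:
        vals = raw.values[valid].astype(np.int64)
        table = dict(layer.category_table)
        missing = sorted(set(np.unique(vals).tolist()) - set(table))
        if missing:
            raise ValueError(
                f"factor {layer.factor_id}: land-cover code(s) {missing} "
                "absent from category table"
            )
        bad = sorted(set(table.values()) - set(RESISTANCE_LEVELS))
        if bad:
            raise ValueError(f"category table maps to non-level value(s) {bad}")
        lut = np.zeros(max(table) + 1, dtype=np.float64)
        for code, level in table.items():
            lut[code] = level
        out[valid] = lut[vals]
        return raw.like(out)

    vals = raw.values[valid].astype(np.float64)
    breaks = layer.breaks
    if breaks is None:
        if np.unique(vals).size < 5:
            raise ValueError(
                f"factor {layer.factor_id}: fewer than 5 distinct values; "
                "supply explicit breaks or a category table"
            )
        breaks = jenks_breaks(vals, k=5)
    elif breaks.k != 5:
        raise ValueError("reclassification breaks must define 5 classes")
    cls = breaks.classify(vals)  # 1..5
    levels = np.asarray(RESISTANCE_LEVELS, dtype=np.float64)
    if layer.direction == "descending":
        levels = levels[::-1]
    out[valid] = levels[cls - 1]
    return raw.like(out)


def composite_surface(layers: Mapping[str, RasterGrid],
                      w: WeightVector) -> ResistanceSurface:
    """Weighted overlay R(x) = sum_i w_i * level_i(x) over aligned factor
    rasters.  Labels of ``w`` must match the factor ids exactly; nodata in
    any factor propagates to the composite."""
    missing = [lab for lab in w.labels if lab not in layers]
    extra = [fid for fid in layers if fid not in w.labels]
    if missing or extra:
        raise ValueError(
            f"factor/weight mismatch: missing {missing or '-'}, unexpected {extra or '-'}"
        )
    grids = [layers[lab] for lab in w.labels]
    template = grids[0]
    for g, lab in zip(grids[1:], list(w.labels)[1:]):
        template.require_aligned(g, what=f"factor {lab}")

    acc = np.zeros(template.shape, dtype=np.float64)
    valid = np.ones(template.shape, dtype=bool)
    for wi, g in zip(w.w, grids):
        gv = g.valid_mask()
        valid &= gv
        acc += np.where(gv, g.values, 0.0) * wi
    out = np.where(valid, acc, template.nodata)
    return ResistanceSurface(grid=template.like(out), weights_used=w)
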