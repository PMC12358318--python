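"""Score a protected-area network (PAN) against area-based conservation
targets: coverage vs the 30% target, overlap with biodiversity-conservation
priority areas (BCPAs), land-use composition of the footprint, and SDG 15
indicator capacities for PA / PAN / whole region."""

import numpy as np

import panlink as pl
from panlink.assess import (composition, overlap_pct, pan_footprint,
                            sdg_indicators, mean_lcp_cost)
from panlink.corridors import corridor_raster
from panlink.geoio import rasterize

bundle = pl.generate(pl.LandscapeConfig(nrows=100, ncols=100, seed=7, n_pa=6))
weights = pl.compute_weights(pl.default_matrix())
R = pl.compute_resistance(bundle, weights)
patches = pl.label_patches(bundle.pa_polygons, R.grid,
                           valid_mask=R.grid.valid_mask())
paths, fields = pl.least_cost_paths(patches, R)
nlccs = [corridor_raster(p.pair, fields[p.pair[0]], fields[p.pair[1]], p.cost)
         for p in paths]

t = mean_lcp_cost(paths)  # the conventional corridor threshold
land = bundle.land_mask() & R.grid.valid_mask()
pan = pan_footprint(patches.mask(), nlccs, R.grid, t, study_mask=land)
pa_only = pan_footprint(patches.mask(), [], R.grid, 0.0, study_mask=land)

print(f"corridor threshold: mean least-cost distance = {t:,.0f} resistance*m")
print(f"PA-only coverage:  {pa_only.coverage_pct:.2f}% of the land area")
print(f"PAN coverage:      {pan.coverage_pct:.2f}% "
      f"({'meets' if pan.meets_target else 'misses'} the 30% target)")
print(f"BCPA overlap: {overlap_pct(pa_only, bundle.bcpa_polygons):.2f}% (PA) "
      f"-> {overlap_pct(pan, bundle.bcpa_polygons):.2f}% (PAN)")

comp = composition(pan, bundle.landcover)
print("PAN land-use composition (shares of footprint, sum 100%):")
for name, pct in sorted(comp.items(), key=lambda kv: -kv[1]):
    print(f"  {name:<10} {pct:5.1f}%")

bcpa_mask = rasterize(bundle.bcpa_polygons, R.grid)
zones = {"PA": patches.mask(), "PAN": pan.mask, "region": land}
table = sdg_indicators(zones, bundle.landcover, bundle.dem, bcpa_mask,
                       bundle.degraded.values > 0)
print("\nSDG 15 indicator capacities (%, 15.3.1 lower is better):")
print(table.round(2).to_string())
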