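# Methods

## Grid model and conventions

Every layer in an analysis shares one projected, square-celled grid:
row-major, row 0 at the north, half-open cell extents, 0-based indices.
Default cell size is 30 m. Areas are always cell count × cell_size²,
reported in km². Nothing resamples; layers that do not align are rejected,
and nodata propagates (a derived layer is nodata wherever an input is).
GeoTIFF (single-band float32/int32, via the standard ModelPixelScale /
ModelTiepoint / GeoKeyDirectory / GDAL_NODATA tags) is the only raster
dialect, GeoJSON the only vector dialect, CSV the table format.

Rasterization marks cells whose center lies inside a polygon; zero-area
geometries (points, polylines) are buffered by half a cell diagonal so the
nearest cell center is always covered. Distances are Euclidean
center-to-center after rasterization (`scipy.ndimage.distance_transform_edt`),
which keeps every operation grid-native and brute-force checkable.

Slope uses Horn's 3×3 finite differences (degrees, edge replication);
relief is max−min elevation in a square moving window (default 3×3).

## Jenks natural breaks

Four stages (pinch points, barrier points, corridor ratio classes,
centrality classes) depend on the same 1-D classifier, so it is exact: the
Fisher dynamic program minimizing total within-class sum of squared
deviations, O(k·n²), numba-compiled, no sampling. Ties resolve
deterministically toward the lowest break values (smallest class-start
index at each backtracking step). A break is the maximum value of its
class; `value <= break` assigns the lower class. Tests verify objective
equality with exhaustive partition enumeration (n ≤ 25) and with an
independently written pure-Python DP at n = 200.

## AHP weights

Weights are the normalized principal right eigenvector of the pairwise
comparison matrix, by power iteration (tolerance 1e−10 on the iterate, max
10,000 steps), with λmax from the Rayleigh quotient; CR uses Saaty's
random-index table {3: 0.58, …, 10: 1.49}. Reciprocity is a soft check —
published matrices carry rounded entries — warning above |a·a' − 1| = 0.02
and rejecting above 0.10. The geometric-mean alternative is deliberately
not offered: the eigenvector method is what the standard AHP tools
implement. The package ships a worked ten-factor example matrix; its
derived weights are reported as computed, never hard-coded.

## Cost distance, paths, corridors

The landscape graph is 8-connected; the edge between adjacent cells i, j
costs (Rᵢ+Rⱼ)/2 · s (orthogonal) or ·s√2 (diagonal) — the convention of
the standard cost-distance tools, so CWD is resistance×meters. Multi-source
Dijkstra (scipy's sparse csgraph) gives each patch's CWD field with
predecessors; a pair's cost is min over cells of cwd_a + cwd_b, the
meeting cell chosen deterministically in (row, col) order, and the LCP is
the two backtracked halves joined. Default pairing links patches whose
minimum-CWD allocation regions share a boundary (the sparse
Linkage-Pathways convention); all-pairs and k-nearest pairings are
available. Sea and nodata cells are impassable by default; a flag can
assign open water finite resistance for land–sea linkage experiments.
All of cost, corridors and classifications are invariant under global
rescaling of R, which is why the composite uses unit-sum weights
(R ∈ [1,100]) rather than unnormalized expert scores — the two differ only
by a positive global factor.

The corridor-width threshold is a single configurable CWD quantity (preset
10,000 resistance·m); the footprint stage instead uses the mean LCP cost
between patches, the conventional accounting threshold.

## Circuit solves

Cells are nodes, conductance is the reciprocal of the cost-distance edge
cost, and each patch is short-circuited into a supernode. Voltages solve
the reduced graph Laplacian by sparse direct factorization; components that
carry injection but no ground raise an error naming the component. Per-cell
current density is half the sum of absolute incident edge currents.
All-to-one mode grounds each patch in turn while every other patch injects
1 A, accumulating densities; analysis can be clipped to a corridor band
(default preset 10,000 CWD). Pinch points are 8-connected top-Jenks-class
(k = 5) current regions with area ≥ 0.1 km².

## Barrier detection

For linkage (a,b) with cost C, the improvement of a circular window W
(radii 100/300/500 m, from min 100 / max 500 / step 200) is
C − C_restored, where C_restored is the pair's least-cost distance after W
is set to the landscape minimum resistance. Because restoration only
lowers edge costs, C_restored is computed by a decrease-only Dijkstra
restart: the original CWD fields seed the queue at the window and its
neighbors, improvements propagate outward, and the new cost is the minimum
of cwd_a + cwd_b over improved cells. This is exactly equivalent to a full
re-solve (tested to 1e−6 on grids ≤ 20×20) at a small fraction of the
cost. Scores attach to window centers, maximized over radii and linkages
(per-meter normalization is available via flag). Window centers scan a
band within one maximum radius of each LCP — a geometric band, because a
CWD-based band would exclude the blocked side of the very barrier under
test; windows are cropped at the grid edge so boundary barriers remain
detectable. Barrier points are the geometric centers (centroids) of
top-Jenks-class (k = 5) regions ≥ 0.05 km². Since scores attach to window
centers, maximal scores form plateaus and a reported centroid can sit up
to roughly one detection radius from the physical obstruction.

## Network prioritization

The patch graph carries edge resistance = LCP cost. Current-flow
centrality grounds each node of a component in turn, injects 1 A at every
other node, solves the dense Laplacian (components here have tens of
nodes), and accumulates |current| per node and edge; a node's iteration
current counts half its incident edge currents plus half its net
injection. Three Jenks classes are assigned with III highest. A corridor's
ensemble category is the ordered pair (ratio class, centrality class);
priority rank 1 is (low resistance, high centrality). Pinch–barrier
co-occurrence regions merge convex hulls of pinch-polygon/barrier-point
pairs within 1 km. OECM screening is conjunctive and per-predicate
toggleable: outside PAs, intersecting pinch focal areas, ≥ 0.1 km², mean
resistance below the landscape's 20th percentile, within 2 km of a
settlement (the proximity radius operationalizes "surrounded by human
communities"; no published value exists).

## Assessment

The PAN footprint is PA cells ∪ {min-over-pairs nlcc ≤ t} with t = mean
LCP cost by default; coverage is judged against a configurable 30% target
over the terrestrial study mask. BCPA overlap and land-use composition are
cell counts. SDG 15 indicators are area shares per zone: 15.1.1 forest
share; 15.1.2 share of the BCPA area inside the zone; 15.3.1 degraded-land
share (lower is better; reported raw with polarity metadata — the degraded
mask is an explicit input, emitted by the generator as bare ground plus
the cultivated fringe of urban areas, because no degradation model is
assumed); 15.4.1 green-cover share of zone cells above a 300 m mountain
threshold, reported as missing (not zero) when a zone has no mountain
cells. The synergy matrix is Spearman rank correlation (average-rank ties)
across sub-zones, which default to a 3×3 tiling of the landscape.

## Synthetic landscapes and planted truth

The generator emulates a densely settled coast: a wavy open-sea strip on
one side (default 10% of cells), a smoothed-noise DEM rising inland to a
mountainous interior, settlements seeded on coastal lowland with urban
cores grown to an exact target share (default 10%), roads connecting
settlements in three classes, rivers meandering to the coast, land cover
assembled to target fractions (forest 28% on high ground, cropland 35%,
wetland 4% on low coast, bare 2%), NDVI driven by cover with noise (hence
anticorrelated with urban), PA patches as buffered blobs on forest/wetland
in six categories, and BCPA rectangles partially overlapping PAs. All
randomness flows through one integer-seeded NumPy generator in a fixed
order, so bundles are bit-identical per (config, seed).

Planted structure defines recoverable truth. A planted corridor is a
forest strip (half-width 1 cell) carved between two patch centers, its
cells recorded in along-axis order. A planted barrier is a wall
perpendicular to the corridor — 300 m half-length, 2 cells thick — stamped
as urban cover *and* as an expressway segment along its axis, because a
land-cover change alone shifts the unit-sum composite by only ~17 points
and is simply crossed by least-cost paths; the road term makes the wall
behave like real transport infrastructure. Truth reports list corridor
cell paths and barrier footprints; helpers score path-in-strip fractions
and barrier recall.

What the generator does not emulate: real geomorphology, tides, seasonal
resistance, species occupancy, marine dispersal. Passing recovery tests
shows the detectors find planted structure under the stated conditions,
not that any particular real coastline would yield the same maps.

## Validation conditions and problem sizes

Unit and property tests run on grids of 5–60 cells a side with exhaustive
or independently implemented oracles (networkx Dijkstra over an explicit
edge list; dense Laplacian pseudoinverse; brute-force window re-solves;
partition enumeration). The barrier-recovery benchmark uses 20 seeded
60×60 landscapes with two patches, one planted corridor and one planted
wall, generated with low ambient disturbance (urban fraction 0.04, three
roads): the experiment isolates the planted obstruction, since in
urban-heavy landscapes the dominant barrier on a linkage is often a
natural urban region rather than the planted wall — a correct answer to a
different question. Measured recall is 20/20. The end-to-end determinism
check runs the full seven-stage pipeline twice on a 150×150 coast (about
a minute per run) and compares artifact checksums. The pipeline's default
barrier-scan stride is 2 with nearest-scanned fill, trading a small amount
of score-field resolution for a several-fold speedup on large landscapes.

## Known limitations

- The AHP module accepts any reciprocal matrix but RI is tabulated only
  for n ≤ 10.
- Corridor pairing by adjacent allocation can drop long-range links that
  all-pairs would find; it is the default because it matches the sparse
  linkage convention and scales.
- The circuit solver short-circuits whole patches; within-patch resistance
  heterogeneity is ignored by construction.
- Pinch/barrier typing (central-urban vs coastal vs mountainous) is a
  visual-interpretation exercise and is out of computational scope.
- Jenks is exact but O(k·n²): classifying millions of cells is feasible
  (numba) yet not instant; the five continuous factors of a 150×150
  landscape take a few seconds each.
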