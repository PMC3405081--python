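# Methods

This note documents the model, the conventions, and the design choices
behind `windsift`, in enough detail to reproduce any number the package
emits bit for bit.

## Analysis grid and conventions

All layers live on one north-up raster of square cells in a projected,
meter-unit, equal-area coordinate system (default `EPSG:5070`). Cell
ownership is half-open: a cell owns its top and left edges, so a point on a
shared edge belongs to exactly one cell, and `xy_to_rowcol` uses
`floor((x - x0)/cell)` / `floor((y0 - y)/cell)`. All distances are planar
Euclidean distances between cell centers unless a rule burns exact geometry
(polygon and line-buffer rules test cell centers against shapely geometry,
boundary-inclusive). Masks are uint8 0/1 with 255 as nodata; in mask unions
a cell is nodata only when every contributing source is nodata — a source
with no evidence at a cell contributes 0, not unknown, because the
footprint is defined as "any mapped impact".

## Disturbance footprint

The footprint is the union of six independent sources:

| source | rule | default |
| --- | --- | --- |
| land cover | code ∈ disturbed set | {21, 22, 23, 24, 81, 82} (developed ×4, hay/pasture, crops) |
| impervious | fraction > threshold | threshold 0 (any mapped imperviousness) |
| topographic change | \|Δz\| ≥ threshold(land cover) | 10.21 m default, per-code map 10.21–17.57 m |
| well fields | kernel density ≥ threshold | quartic kernel, bandwidth 1,000 m, 1 well/km² |
| linear infrastructure | geometric intersection at 30 m sub-cells | any sub-cell hit ⇒ cell disturbed |
| settlements | cell center within buffer of a point | 300 m |

The well-field kernel is the quartic (biweight)
K(d) = 3/(πh²)·(1 − (d/h)²)² for d < h, with finite support equal to the
bandwidth h. Finite support makes an exact brute-force oracle possible and
the density integrates to the number of wells over the plane (mass is lost
only past the grid edge). The source analysis cites a kernel density of
well locations without printing kernel, bandwidth, or cutoff, so all three
are required configuration with the defaults above.

Linear features are rasterized by exact geometric intersection against
30 m sub-cell footprints and aggregated to the analysis cell by "any hit";
this is conservative (a road crossing any corner of a cell disturbs it).
The point-buffer operator additionally always marks the cell containing a
point, since the buffer contains the point itself at any radius; without
this a radius-0 buffer would mark nothing under the cell-center criterion.

## Wildlife exclusion rules

Rules are declarative records (`rule_id`, `source`, `operator`, `params`)
compiled independently and unioned, so composition is order-invariant and a
rule set is auditable layer by layer (the output mask's provenance lists
every contributing rule id). Seven jurisdictions are covered by five
shipped YAML rule sets; Alberta/Saskatchewan and North/South Dakota each
share one set because their methodologies are identical.

Choices the rule language forced:

* **Ordinal orientation.** The statewide 1–6 sensitivity ranking treats 6
  as most sensitive, so "four most sensitive categories" compiles to
  `category_in_set {3,4,5,6}`; the 1–4 crucial-areas layers treat 4 as
  highest concern, so "two categories of highest concern" compiles to
  `category_at_least 3`. Both operators accept arbitrary sets/thresholds,
  so an inverted source layer needs only a different parameter, not code.
* **Stopover sites from observations.** The stopover rule is defined on
  *sites*, but the data are dated observation points. Observations are
  clustered into sites by single-linkage at a configurable `site_radius`
  (default one cell); a site qualifies when its observations span ≥ 2
  distinct years or ≥ 3 distinct days within one year, and qualifying
  sites (centroid representative points) are buffered by 3.2 km. Dates are
  ISO-8601 strings; an unparseable date aborts with the record index.
* **Density threshold.** The waterfowl rule uses ≥ (boundary inclusive),
  matching "104 pairs per km² or greater".
* **River corridors.** Implemented as a 1.6 km `line_buffer` restricted by
  an attribute filter to the named major rivers; river identity is an
  attribute of the line layer, not a geometric property.
* **Protected areas.** GAP-coded polygons are burned through the same
  `polygon_burn` operator with a `gap_code ∈ {1,2}` attribute filter; the
  suitability stage reuses the exclusion-engine implementation rather than
  duplicating it.

## Suitability and patch filter

The candidate surface is
`disturbed ∧ viable ∧ ¬excluded ∧ ¬protected ∧ ¬urban ∧ ¬water`, with
viability `WPC ≥ 3` (inclusive), urban cores as developed medium/high
land-cover codes {23, 24}, and water/wetland codes {11, 90, 95}. Wind data
of a different resolution are aligned by nearest-neighbor regridding at
template cell centers.

The patch filter labels connected components (8-connectivity by default —
the flag is exposed; 8 is the conservative choice because it merges more
area into retainable patches), keeps every patch of area ≥ 1 km², and
keeps a smaller patch iff its minimum center-to-center cell distance to any
≥ 1 km² patch is ≤ 800 m. A patch of exactly 1 km² counts as an anchor
(the ≥ reading), since the removal criterion targets patches *smaller
than* 1 km². Distances come from an exact Euclidean distance transform
seeded on anchor-patch cells, which matches the all-pairs cell-center
oracle by construction. The filter is idempotent and only removes cells.

## Capacity and audit arithmetic

Capacity densities are the published per-class lookup (WPC 3–7 → 4.3, 4.8,
5.2, 5.5, 6.0 MW/km²; classes 1–2 → 0). The 5 MW/km² at 44.5% capacity
factor figures are stored as metadata only: the per-class capacity factors
behind the lookup are not published, so the lookup is authoritative and is
not re-derived. Regional GW is the sum over low-impact cells of
cell area × density / 1000; a low-impact cell with nodata wind class
counts 0 and is logged.

Percentages (percent of goal, percent of turbines in low-impact areas) are
computed from **unrounded** numerators and denominators and then rounded
half away from zero to integers; total rows sum the unrounded inputs before
computing their percentage. This is the only scheme consistent with most of
the published rows (e.g. Montana 139/5.26 → 2643%); the published Alberta
and Wyoming percentages (2215%, 2662%) are not reproducible from the
*rounded printed* GW values (91/4.11 → 2214%, 34/1.28 → 2656%) and were
evidently computed from unrounded capacity before printing — the package
therefore reproduces exactly the rows whose printed inputs are
self-consistent (Montana, North Dakota, Saskatchewan, Nebraska, South
Dakota, and all totals).

Turbines are audited by sampling the mask cell containing each point under
the half-open convention; out-of-bounds points are flagged, kept, counted
as not-low-impact, and warned about.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes, not
the geography of any real place:

* **Land cover**: a Gaussian random field smoothed at `lc_patch_scale`
  (default 1,200 m) and discretized at rank quantiles matching
  `class_proportions` — realized class fractions are exact to within
  discretization, and patches are contiguous as in real land-cover texture.
* **Wind power class**: an independent field smoothed at `wpc_corr_length`
  (default 5,000 m, reflecting the smoothness of modeled wind atlases)
  discretized into equal-probability classes over `wpc_range`.
* **Wells**: a parent/offspring cluster process (6 parents, offspring
  scatter `well_cluster_sd` = 1,500 m) mimicking oil/gas field clustering.
* **Crane observations**: planted sites alternating positives (multi-year
  and three-day clauses, deterministically covering both) and near-miss
  negatives (one or two days of a single year), with ground-truth labels
  returned. Sites are rejection-sampled to a minimum separation (1 km,
  shrunk on small tiles) so distinct planted sites cannot merge under the
  downstream clustering radius and invalidate the labels.
* **Other layers**: sparse mine-like topographic-change blobs (12–40 m),
  impervious fractions inside developed cells, a smooth non-negative
  waterfowl density surface (mean 60, sd 40 pairs/km²), random rectangular
  priority/protected/sensitivity polygons with cycling kind/GAP/category
  attributes, straight-ish roads and wavy rivers crossing the tile (the
  first river named "Missouri River" so the corridor rule binds), and
  uniform turbine points tagged existing/proposed and by region.

One global seed drives per-layer substreams (`seed + fixed offset`), so any
single layer is reproducible while others' parameters change. Defaults
describe a 256 × 256 tile at 100 m (655 km²) — large enough for the 1 km²
patch criterion to bind (100 cells) while keeping a full pipeline run
around a second.

What the generator does **not** emulate: real spatial covariance between
layers (cropland does not preferentially occupy good wind resource; wells
ignore geology), realistic road networks, or calibrated wildlife densities.
Passing tests therefore demonstrate the correctness of the *computation* —
masks, filters, arithmetic, invariants — on data of the right statistical
shape, not the reproduction of any regional result, which would require the
proprietary and agency source layers.

## Numerical choices and degenerate inputs

* Empty well/line/point layers yield all-zero masks, not errors; an empty
  rule set excludes nothing.
* Quantile discretization uses stable rank ordering, so ties in the
  smoothed field break deterministically.
* `round_half_away(x) = sign(x)·floor(|x| + 0.5)` avoids banker's rounding
  on .5 percentages.
* Mask values are validated on construction (only 0/1/255 admitted).
* Patch-filter `max_distance = ∞` reduces to the pure area criterion;
  no-anchor landscapes lose every patch.
* GeoTIFFs are written with pixel-scale + tiepoint tags, a minimal GeoKey
  directory carrying the EPSG code, and the GDAL nodata convention; a file
  without georeferencing or CRS is rejected on read.

## Problem sizes used in the test and acceptance runs

Unit oracles run on 3×3–64×64 grids; the brute-force equivalence suites use
100 random 32×32 fixtures (capacity aggregation), 100 random 64×64 masks
(patch filter), and 20 random 64×64 grids with up to 50 wells (kernel
density). The end-to-end checks run the full pipeline on 64×64–256×256
landscapes. These sizes exercise every code path (multi-patch topologies,
kernel supports spanning many cells, both turbine statuses and regions)
while keeping the whole suite around ten seconds.

## Known limitations

* Reprojection between coordinate systems is out of scope; all inputs must
  share one projected CRS (only nearest-neighbor regridding between
  resolutions is provided).
* Shapefile input is not supported; GeoJSON is the vector format.
* The patch-distance convention is cell-center to cell-center; a true
  edge-to-edge convention would differ by up to one cell diagonal.
* Rule sets reference layers by name; validating that a user's layer
  semantically matches a rule (e.g. density units) is the user's
  responsibility.
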