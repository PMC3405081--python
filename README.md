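# windsift

Low-impact wind-energy siting analysis on human-disturbance footprints.

Wind development has a large land footprint per gigawatt, and in grassland
regions such as the Northern Great Plains (NGP) it competes with some of the
least-protected intact habitat on the continent. One way to decouple clean
energy build-out from wildlife impact is to steer turbines onto lands that
are *already* disturbed — cropland, developed areas, oil and gas fields,
road corridors — provided those lands also have a viable wind resource and
are not themselves wildlife-sensitive. `windsift` implements that analysis
as a reusable, tested pipeline:

1. **Disturbance footprint** — a binary disturbed/undisturbed raster built
   as the union of: disturbed land-cover classes (cultivated crops,
   hay/pasture, the four developed classes), impervious surface, significant
   topographic change (surface mines; thresholds of 10.21–17.57 m by land
   cover), oil/gas well fields delineated by a kernel density of well points,
   linear infrastructure rasterized at 30 m, and settlements buffered by
   300 m.
2. **Wildlife exclusions** — declarative, jurisdiction-specific rule sets
   (shipped as YAML for AB/SK, MT, NE, ND/SD, WY) compiled to masks:
   priority-area polygon burns, sensitivity-category thresholds, a waterfowl
   breeding-pair density cutoff (≥ 104 pairs/km²), 3.2 km buffers around
   repeated whooping-crane stopover sites (observations in multiple years or
   on ≥ 3 days of one year), and 1.6 km river-corridor buffers. Excluded
   areas are withheld even where already disturbed.
3. **Suitability** — keep disturbed cells with wind power class (WPC) ≥ 3
   (≥ 6.4 m/s at 50 m), outside permanently protected areas (GAP codes 1–2),
   urban cores, and wetlands/water.
4. **Patch filter** — remove disturbed patches smaller than 1 km² that lie
   more than 800 m from any patch of at least 1 km².
5. **Capacity** — convert surviving area to installable nameplate capacity
   using per-class densities (WPC 3–7 → 4.3, 4.8, 5.2, 5.5, 6.0 MW/km²,
   consistent with 5 MW/km² at a 44.5% average capacity factor), aggregate
   per region, and report percent of each region's development goal.
6. **Turbine audit** — sample existing and proposed turbine points against
   the low-impact surface and summarize the share sited inside it.

No public archive provides the input stack, so the package includes a seeded
synthetic-landscape generator (`windsift.synth`) producing all layers —
neutral-landscape land cover, an autocorrelated WPC surface, clustered
wells, dated crane observations with ground-truth labels, wildlife polygons,
rivers, turbines — on a common projected equal-area grid, so every stage is
testable end to end.

## Worked example

```python
import windsift as ws

params = ws.LandscapeParams(seed=1)          # 256 x 256 cells at 100 m
landscape = ws.generate_landscape(params)
result = ws.run_pipeline(
    landscape, ws.PipelineConfig(jurisdiction="north_south_dakota")
)
print(result.region_summary.to_string(index=False))
```

```
  region  goal_gw  low_impact_gw  pct_of_goal
region_A      0.5       0.299280           60
region_B      0.5       0.535791          107
   Total      1.0       0.835071           84
```

Of the 655 km² tile, 347.68 km² is disturbed and 163.93 km² survives the
exclusion and patch filters as low-impact; at the per-class capacity
densities that area supports 0.84 GW of nameplate capacity, 84% of the
combined 1.0 GW regional goal. The turbine audit on the same run reports
21% of existing and 22% of proposed synthetic turbines inside the
low-impact surface:

```
  region   status  n_turbines  n_low_impact  pct_low_impact
   Total existing         150            32              21
   Total proposed         300            65              22
```

The same pipeline is scriptable from a shell:

```sh
windsift simulate --out sim/ --seed 1
windsift run --out results/ --seed 1 --jurisdiction north_south_dakota
```

For the real NGP study region the package ships the published reference
tables (`windsift.datasets`): per-jurisdiction development goals and
low-impact capacity, and turbine counts by status. Running the summary code
on them reproduces the headline figures — 1,056 GW of low-impact capacity
against a 29.95 GW goal (3526%), with 34% of existing and 30% of proposed
turbines inside low-impact areas.

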