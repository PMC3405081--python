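"""Seeded synthetic landscapes for exercising the siting pipeline.

No public archive ships the stack of layers the analysis consumes (land
cover, impervious surface, topographic change, wind power class, wells,
settlements, rivers, wildlife layers, turbines), so this module generates
landscapes that carry the statistical structure the analysis assumes:

* categorical land cover with contiguous patches, built by thresholding a
  smoothed Gaussian random field at quantiles matching target class
  proportions (a neutral landscape model);
* a spatially autocorrelated ordinal wind-power-class surface, built by
  discretizing a second, independently seeded smoothed field;
* clustered well points (a Thomas-like parent/offspring process);
* dated migratory-bird observations at planted sites, with machine-readable
  ground-truth labels for the repeated-stopover rule;
* wildlife polygons, protected areas with protection (GAP) codes,
  sensitivity rasters, rivers and roads, turbines with status and region.

One global integer seed drives independent per-layer substreams (seed plus
a fixed per-layer offset), so a layer is reproducible even when parameters
of other layers change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import box as shapely_box
from shapely.geometry import LineString, Point

from .features import FeatureSet
from .grid import Grid

__all__ = [
    "LandscapeParams",
    "SyntheticLandscape",
    "ParameterError",
    "generate_landscape",
    "generate_crane_history",
]

# fixed per-layer seed offsets (decoupled substreams)
_LAYER_OFFSETS = {
    "landcover": 11,
    "impervious": 13,
    "topo_change": 17,
    "wpc": 19,
    "waterfowl": 23,
    "sensitivity": 29,
    "caps": 31,
    "wells": 37,
    "hamlets": 41,
    "crane": 43,
    "turbines": 47,
    "roads": 53,
    "rivers": 59,
    "priority": 61,
    "protected": 67,
    "sensitivity_zones": 71,
}

# NLCD-style land-cover codes used throughout the synthetic schema
LC_OPEN_WATER = 11
LC_DEV_OPEN = 21
LC_DEV_LOW = 22
LC_DEV_MED = 23
LC_DEV_HIGH = 24
LC_FOREST = 41
LC_GRASSLAND = 71
LC_HAY_PASTURE = 81
LC_CROPLAND = 82
LC_WETLAND = 95

DEFAULT_CLASS_PROPORTIONS = {
    LC_GRASSLAND: 0.40,
    LC_CROPLAND: 0.30,
    LC_HAY_PASTURE: 0.08,
    LC_FOREST: 0.08,
    LC_WETLAND: 0.05,
    LC_OPEN_WATER: 0.04,
    LC_DEV_OPEN: 0.03,
    LC_DEV_LOW: 0.02,
}

PRIORITY_KINDS = (
    "iba",
    "ncc_priority",
    "tnc_priority",
    "playa",
    "swap_priority",
    "sage_grouse_core",
    "wetland_complex",
    "ungulate_corridor",
)


class ParameterError(ValueError):
    """A landscape parameter violates its invariant; names the field."""


@dataclass
class LandscapeParams:
    """Knobs of the synthetic landscape.

    Distances are meters; densities are breeding pairs per km².  The
    defaults describe a 25.6 km x 25.6 km tile at 100 m resolution with a
    grassland/cropland matrix, a moderately smooth wind resource, clustered
    oil/gas wells and a handful of settlements and wildlife layers.
    """

    grid_shape: tuple[int, int] = (256, 256)
    cell_size: float = 100.0
    seed: int = 0
    crs: str = "EPSG:5070"
    x_origin: float = 0.0
    y_origin: float | None = None  # defaults to rows * cell_size (south-west at 0,0)
    class_proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    lc_patch_scale: float = 1200.0
    n_wells: int = 300
    well_cluster_sd: float = 1500.0
    n_well_clusters: int = 6
    n_hamlets: int = 12
    wpc_range: tuple[int, int] = (1, 7)
    wpc_corr_length: float = 5000.0
    n_crane_sites: int = 8
    crane_obs_per_site: tuple[int, int] = (1, 5)
    crane_years: tuple[int, ...] = (2008, 2009, 2010, 2011)
    waterfowl_density_mean: float = 60.0
    waterfowl_density_sd: float = 40.0
    waterfowl_corr_length: float = 2000.0
    n_priority_polygons: int = 8
    n_protected_areas: int = 4
    n_sensitivity_zones: int = 5
    n_roads: int = 6
    n_rivers: int = 2
    n_turbines_existing: int = 150
    n_turbines_proposed: int = 300
    n_regions: int = 2
    region_goals_gw: tuple[float, ...] = (0.5, 0.5)

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ParameterError("grid_shape: rows and cols must be positive")
        if self.cell_size <= 0:
            raise ParameterError("cell_size: must be positive")
        props = self.class_proportions
        if any(v < 0 for v in props.values()):
            raise ParameterError("class_proportions: fractions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ParameterError(
                f"class_proportions: fractions must sum to 1, got {sum(props.values())}"
            )
        lo, hi = self.wpc_range
        if not (1 <= lo <= hi <= 7):
            raise ParameterError("wpc_range: must satisfy 1 <= min <= max <= 7")
        for name in (
            "n_wells", "n_hamlets", "n_crane_sites", "n_priority_polygons",
            "n_protected_areas", "n_sensitivity_zones", "n_roads", "n_rivers",
            "n_turbines_existing", "n_turbines_proposed",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name}: must be non-negative")
        if self.lc_patch_scale <= 0:
            raise ParameterError("lc_patch_scale: must be positive")
        if self.wpc_corr_length <= 0:
            raise ParameterError("wpc_corr_length: must be positive")
        if self.well_cluster_sd <= 0:
            raise ParameterError("well_cluster_sd: must be positive")
        if self.n_regions < 1:
            raise ParameterError("n_regions: must be at least 1")
        if len(self.region_goals_gw) != self.n_regions:
            raise ParameterError("region_goals_gw: one goal per region required")

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, dict):
                v = {str(k): val for k, val in v.items()}
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, obj: dict) -> "LandscapeParams":
        kwargs = dict(obj)
        for name in ("grid_shape", "wpc_range", "crane_obs_per_site",
                     "crane_years", "region_goals_gw"):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = tuple(kwargs[name])
        if "class_proportions" in kwargs:
            kwargs["class_proportions"] = {
                int(k): float(v) for k, v in kwargs["class_proportions"].items()
            }
        return cls(**kwargs)


@dataclass
class SyntheticLandscape:
    """A bundle of aligned grids, vector layers, goals and ground truth."""

    landcover: Grid
    impervious: Grid
    topo_change: Grid
    wpc: Grid
    waterfowl_density: Grid
    sensitivity: Grid          # 1-6 ordinal wildlife-sensitivity raster
    caps: Grid                 # 1-4 ordinal crucial-areas raster
    regions: Grid
    wells: FeatureSet
    hamlets: FeatureSet
    crane_obs: FeatureSet
    turbines: FeatureSet
    roads: FeatureSet
    rivers: FeatureSet
    priority_polygons: FeatureSet
    protected_areas: FeatureSet
    sensitivity_zones: FeatureSet
    goals: pd.DataFrame
    region_names: dict[int, str]
    truth: dict

    def layer_map(self) -> dict:
        """Name -> layer mapping as consumed by the exclusion rule engine."""
        return {
            "landcover": self.landcover,
            "impervious": self.impervious,
            "topo_change": self.topo_change,
            "wpc": self.wpc,
            "waterfowl_density": self.waterfowl_density,
            "sensitivity": self.sensitivity,
            "caps": self.caps,
            "regions": self.regions,
            "wells": self.wells,
            "hamlets": self.hamlets,
            "crane_obs": self.crane_obs,
            "turbines": self.turbines,
            "roads": self.roads,
            "rivers": self.rivers,
            "priority_polygons": self.priority_polygons,
            "protected_areas": self.protected_areas,
            "sensitivity_zones": self.sensitivity_zones,
        }

    @property
    def grids(self) -> dict[str, Grid]:
        return {k: v for k, v in self.layer_map().items() if isinstance(v, Grid)}

    @property
    def vectors(self) -> dict[str, FeatureSet]:
        return {k: v for k, v in self.layer_map().items() if isinstance(v, FeatureSet)}


# ---------------------------------------------------------------------------
# random-field helpers


def _rng(params_seed: int, layer: str) -> np.random.Generator:
    return np.random.default_rng(int(params_seed) + _LAYER_OFFSETS[layer])


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], corr_cells: float
) -> np.ndarray:
    """White noise smoothed by a Gaussian kernel, standardized to N(0,1)."""
    noise = rng.standard_normal(shape)
    sigma = max(corr_cells, 1e-6)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _threshold_at_quantiles(
    sfield: np.ndarray, proportions: dict[int, float]
) -> np.ndarray:
    """Discretize a continuous field into codes matching target fractions.

    Classes are assigned to successive quantile bands of the field in sorted
    code order, so each class occupies contiguous value ranges and hence
    spatially contiguous patches.
    """
    codes = sorted(proportions)
    fracs = np.array([proportions[c] for c in codes], dtype=float)
    # ranks give exact areal fractions regardless of the field's distribution
    flat = sfield.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    boundaries = np.floor(np.cumsum(fracs) * n + 0.5).astype(int)
    out_flat = np.empty(n, dtype=np.int16)
    start = 0
    for code, stop in zip(codes, boundaries):
        out_flat[order[start:stop]] = code
        start = stop
    if start < n:  # numerical slack -> assign remainder to the last class
        out_flat[order[start:]] = codes[-1]
    return out_flat.reshape(sfield.shape)


def _random_points_in_bounds(
    rng: np.random.Generator, n: int, bounds: tuple[float, float, float, float]
) -> np.ndarray:
    w, s, e, nn = bounds
    xs = rng.uniform(w, e, size=n)
    ys = rng.uniform(s, nn, size=n)
    return np.column_stack([xs, ys])


# ---------------------------------------------------------------------------
# crane observation histories


def generate_crane_history(
    n_sites: int,
    years,
    seed: int,
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 25600.0, 25600.0),
    obs_per_site: tuple[int, int] = (1, 5),
    site_jitter: float = 30.0,
    min_separation: float = 1000.0,
) -> tuple[FeatureSet, list[bool]]:
    """Dated observation points at ``n_sites`` locations, with truth labels.

    Half the sites (alternating) are planted to satisfy the repeated-
    stopover rule — via multiple years or via three-plus distinct days in
    one year — and the rest are near-miss negatives (a single day, or two
    days within one year).  Returns the observation layer and one boolean
    per site: True when the site's history satisfies the rule.
    """
    years = list(years)
    if n_sites < 1:
        raise ParameterError("n_sites: must be at least 1")
    if not years:
        raise ParameterError("years: must be nonempty")
    rng = np.random.default_rng(int(seed) + _LAYER_OFFSETS["crane"])
    # rejection-sample site locations so distinct sites cannot merge under
    # the clustering radius downstream (keeps truth labels sound); on small
    # tiles the separation shrinks to what the area can accommodate
    w_, s_, e_, n_ = bounds
    fit = 0.4 * np.sqrt((e_ - w_) * (n_ - s_) / max(n_sites, 1))
    separation = min(min_separation, fit)
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_sites and attempts < 10_000:
        cand = _random_points_in_bounds(rng, 1, bounds)[0]
        if all(np.hypot(*(cand - p)) >= separation for p in accepted):
            accepted.append(cand)
        attempts += 1
    if len(accepted) < n_sites:
        raise ParameterError(
            "n_sites: too many sites for the bounds at the requested separation"
        )
    sites = np.array(accepted)
    geoms, attrs = [], []
    labels: list[bool] = []
    for i, (x, y) in enumerate(sites):
        positive = i % 2 == 0
        if positive and len(years) >= 2 and (i // 2) % 2 == 0:
            # alternate qualifying clause so fixtures always cover both
            # clause 1: observations in multiple years
            yrs = rng.choice(years, size=2, replace=False)
            obs_dates = [date(int(yr), 4, int(rng.integers(1, 29))) for yr in yrs]
        elif positive:
            # clause 2: three or more distinct days within one year
            yr = int(rng.choice(years))
            days = rng.choice(np.arange(1, 29), size=3, replace=False)
            obs_dates = [date(yr, 4, int(d)) for d in days]
        else:
            # near-miss negative: one or two distinct days, single year
            yr = int(rng.choice(years))
            k = 1 + (i // 2) % 2
            days = rng.choice(np.arange(1, 29), size=k, replace=False)
            obs_dates = [date(yr, 4, int(d)) for d in days]
        # possibly more sightings on the same days (does not change the label)
        extra = int(rng.integers(obs_per_site[0], obs_per_site[1] + 1)) - len(obs_dates)
        for _ in range(max(extra, 0)):
            obs_dates.append(obs_dates[int(rng.integers(len(obs_dates)))])
        for d in obs_dates:
            jx = x + rng.normal(scale=site_jitter)
            jy = y + rng.normal(scale=site_jitter)
            w, s, e, n = bounds
            jx = float(np.clip(jx, w, np.nextafter(e, w)))
            jy = float(np.clip(jy, np.nextafter(s, n), n))
            geoms.append(Point(jx, jy))
            attrs.append({"site_id": i, "date": d.isoformat()})
        labels.append(positive)
    return FeatureSet(kind="point", geometries=geoms, attributes=attrs), labels


# ---------------------------------------------------------------------------
# landscape generator


def generate_landscape(params: LandscapeParams) -> SyntheticLandscape:
    """Generate a complete synthetic landscape; deterministic in the seed."""
    params.validate()
    rows, cols = params.grid_shape
    cell = params.cell_size
    y_origin = params.y_origin if params.y_origin is not None else rows * cell
    x_origin = params.x_origin

    def make_grid(data, nodata=None) -> Grid:
        return Grid(
            data=data, x_origin=x_origin, y_origin=y_origin,
            cell_size=cell, crs=params.crs, nodata=nodata,
        )

    template = make_grid(np.zeros((rows, cols), dtype=np.uint8))
    bounds = template.bounds
    w, s, e, n = bounds

    def clip_points(pts: np.ndarray) -> np.ndarray:
        pts = pts.copy()
        pts[:, 0] = np.clip(pts[:, 0], w, np.nextafter(e, w))
        pts[:, 1] = np.clip(pts[:, 1], np.nextafter(s, n), n)
        return pts

    # land cover: quantile-thresholded smoothed field
    lc_corr = params.lc_patch_scale / cell
    lc_field = _smooth_field(_rng(params.seed, "landcover"), (rows, cols), lc_corr)
    landcover = make_grid(
        _threshold_at_quantiles(lc_field, params.class_proportions), nodata=255
    )

    # impervious fraction: nonzero only in developed cells, plus rare specks
    rng_imp = _rng(params.seed, "impervious")
    imperv = np.zeros((rows, cols))
    dev = np.isin(landcover.data, (LC_DEV_OPEN, LC_DEV_LOW, LC_DEV_MED, LC_DEV_HIGH))
    imperv[dev] = rng_imp.uniform(0.2, 0.9, size=int(dev.sum()))
    speck = rng_imp.random((rows, cols)) < 0.001
    imperv[speck & ~dev] = rng_imp.uniform(0.05, 0.3, size=int((speck & ~dev).sum()))
    impervious = make_grid(imperv, nodata=-9999.0)

    # topographic change: sparse mine-like blobs with tens-of-meters relief
    rng_topo = _rng(params.seed, "topo_change")
    topo = np.zeros((rows, cols))
    n_mines = max(1, (rows * cols) // 16384)
    for _ in range(n_mines):
        r0 = int(rng_topo.integers(rows))
        c0 = int(rng_topo.integers(cols))
        rad = int(rng_topo.integers(2, max(3, rows // 32)))
        rr, cc = np.ogrid[:rows, :cols]
        blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        topo[blob] = rng_topo.uniform(12.0, 40.0)
    topo_change = make_grid(topo, nodata=-9999.0)

    # wind power class: discretized independent smoothed field
    lo, hi = params.wpc_range
    wpc_field = _smooth_field(
        _rng(params.seed, "wpc"), (rows, cols), params.wpc_corr_length / cell
    )
    n_classes = hi - lo + 1
    wpc_props = {lo + k: 1.0 / n_classes for k in range(n_classes)}
    wpc = make_grid(
        _threshold_at_quantiles(wpc_field, wpc_props).astype(np.int16), nodata=-1
    )

    # waterfowl breeding-pair density: smooth, non-negative
    wf_field = _smooth_field(
        _rng(params.seed, "waterfowl"), (rows, cols),
        params.waterfowl_corr_length / cell,
    )
    waterfowl = make_grid(
        np.clip(
            params.waterfowl_density_mean + params.waterfowl_density_sd * wf_field,
            0.0, None,
        ),
        nodata=-9999.0,
    )

    # ordinal sensitivity rasters (1-6 statewide ranking; 1-4 crucial areas)
    sens_field = _smooth_field(
        _rng(params.seed, "sensitivity"), (rows, cols), lc_corr
    )
    sensitivity = make_grid(
        _threshold_at_quantiles(sens_field, {k: 1 / 6 for k in range(1, 7)}).astype(
            np.int16
        ),
        nodata=-1,
    )
    caps_field = _smooth_field(_rng(params.seed, "caps"), (rows, cols), lc_corr)
    caps = make_grid(
        _threshold_at_quantiles(caps_field, {k: 1 / 4 for k in range(1, 5)}).astype(
            np.int16
        ),
        nodata=-1,
    )

    # regions: vertical bands of equal width
    col_idx = np.arange(cols)
    band = np.minimum(
        (col_idx * params.n_regions) // cols, params.n_regions - 1
    )
    regions = make_grid(np.tile(band.astype(np.int16), (rows, 1)), nodata=-1)
    region_names = {i: f"region_{chr(ord('A') + i)}" for i in range(params.n_regions)}
    goals = pd.DataFrame(
        {
            "region": [region_names[i] for i in range(params.n_regions)],
            "goal_gw": list(params.region_goals_gw),
        }
    )

    # wells: parent/offspring cluster process
    rng_wells = _rng(params.seed, "wells")
    if params.n_wells > 0:
        centers = _random_points_in_bounds(rng_wells, params.n_well_clusters, bounds)
        assignment = rng_wells.integers(params.n_well_clusters, size=params.n_wells)
        offsets = rng_wells.normal(scale=params.well_cluster_sd,
                                   size=(params.n_wells, 2))
        pts = clip_points(centers[assignment] + offsets)
        wells = FeatureSet(
            kind="point",
            geometries=[Point(x, y) for x, y in pts],
            attributes=[{"well_id": i} for i in range(params.n_wells)],
        )
    else:
        wells = FeatureSet(kind="point")

    # hamlets: uniform points
    rng_ham = _rng(params.seed, "hamlets")
    ham_pts = _random_points_in_bounds(rng_ham, params.n_hamlets, bounds)
    hamlets = FeatureSet(
        kind="point",
        geometries=[Point(x, y) for x, y in ham_pts],
        attributes=[{"name": f"hamlet_{i}"} for i in range(params.n_hamlets)],
    )

    # crane observation history with ground-truth labels
    crane_obs, crane_labels = generate_crane_history(
        params.n_crane_sites, params.crane_years, params.seed,
        bounds=bounds, obs_per_site=params.crane_obs_per_site,
        site_jitter=cell / 4,
    )

    # roads: straight-ish polylines crossing the tile; rivers: wavy lines
    def make_lines(rng_l, n_lines, wavy=False):
        geoms = []
        for _ in range(n_lines):
            if rng_l.random() < 0.5:  # west-east
                y0_, y1_ = rng_l.uniform(s, n, size=2)
                xs = np.linspace(w, np.nextafter(e, w), 8)
                ys = np.linspace(y0_, y1_, 8)
            else:  # north-south
                x0_, x1_ = rng_l.uniform(w, e, size=2)
                ys = np.linspace(np.nextafter(s, n), n, 8)
                xs = np.linspace(x0_, x1_, 8)
            if wavy:
                amp = 0.04 * min(e - w, n - s)
                xs = np.clip(xs + rng_l.normal(scale=amp, size=8), w, np.nextafter(e, w))
                ys = np.clip(ys + rng_l.normal(scale=amp, size=8), np.nextafter(s, n), n)
            geoms.append(LineString(np.column_stack([xs, ys])))
        return geoms

    roads = FeatureSet(
        kind="line",
        geometries=make_lines(_rng(params.seed, "roads"), params.n_roads),
        attributes=[{"kind": "road"} for _ in range(params.n_roads)],
    )
    river_geoms = make_lines(_rng(params.seed, "rivers"), params.n_rivers, wavy=True)
    river_names = ["Missouri River"] + [f"river_{i}" for i in range(1, params.n_rivers)]
    rivers = FeatureSet(
        kind="line",
        geometries=river_geoms,
        attributes=[{"name": river_names[i]} for i in range(params.n_rivers)],
    )

    # wildlife priority polygons (kinds cycle through the catalogue)
    def random_boxes(rng_p, n_boxes, frac_lo=0.03, frac_hi=0.12):
        geoms = []
        for _ in range(n_boxes):
            bw = rng_p.uniform(frac_lo, frac_hi) * (e - w)
            bh = rng_p.uniform(frac_lo, frac_hi) * (n - s)
            bx = rng_p.uniform(w, e - bw)
            by = rng_p.uniform(s, n - bh)
            geoms.append(shapely_box(bx, by, bx + bw, by + bh))
        return geoms

    rng_prio = _rng(params.seed, "priority")
    priority_polygons = FeatureSet(
        kind="polygon",
        geometries=random_boxes(rng_prio, params.n_priority_polygons),
        attributes=[
            {"kind": PRIORITY_KINDS[i % len(PRIORITY_KINDS)], "poly_id": i}
            for i in range(params.n_priority_polygons)
        ],
    )

    rng_prot = _rng(params.seed, "protected")
    protected_areas = FeatureSet(
        kind="polygon",
        geometries=random_boxes(rng_prot, params.n_protected_areas),
        attributes=[
            {"gap_code": 1 + i % 4, "name": f"pa_{i}"}
            for i in range(params.n_protected_areas)
        ],
    )

    rng_sz = _rng(params.seed, "sensitivity_zones")
    sensitivity_zones = FeatureSet(
        kind="polygon",
        geometries=random_boxes(rng_sz, params.n_sensitivity_zones),
        attributes=[
            {"category": 1 + i % 4, "zone_id": i}
            for i in range(params.n_sensitivity_zones)
        ],
    )

    # turbines: uniform points with status and region attribute
    rng_turb = _rng(params.seed, "turbines")
    n_turb = params.n_turbines_existing + params.n_turbines_proposed
    turb_pts = _random_points_in_bounds(rng_turb, n_turb, bounds)
    statuses = ["existing"] * params.n_turbines_existing + (
        ["proposed"] * params.n_turbines_proposed
    )
    t_rows, t_cols = template.xy_to_rowcol(turb_pts[:, 0], turb_pts[:, 1])
    t_cols = np.clip(t_cols, 0, cols - 1)
    t_rows = np.clip(t_rows, 0, rows - 1)
    t_regions = regions.data[t_rows, t_cols]
    turbines = FeatureSet(
        kind="point",
        geometries=[Point(x, y) for x, y in turb_pts],
        attributes=[
            {
                "turbine_id": i,
                "status": statuses[i],
                "region": region_names[int(t_regions[i])],
            }
            for i in range(n_turb)
        ],
    )

    # machine-readable ground truth for downstream scoring
    truth = {
        "crane_site_labels": list(crane_labels),
        "disturbed_lc_truth": np.isin(
            landcover.data, sorted({LC_DEV_OPEN, LC_DEV_LOW, LC_DEV_MED,
                                    LC_DEV_HIGH, LC_HAY_PASTURE, LC_CROPLAND})
        ),
        "class_proportions_target": dict(params.class_proportions),
        "well_cluster_centers": (
            centers.tolist() if params.n_wells > 0 else []
        ),
    }

    return SyntheticLandscape(
        landcover=landcover,
        impervious=impervious,
        topo_change=topo_change,
        wpc=wpc,
        waterfowl_density=waterfowl,
        sensitivity=sensitivity,
        caps=caps,
        regions=regions,
        wells=wells,
        hamlets=hamlets,
        crane_obs=crane_obs,
        turbines=turbines,
        roads=roads,
        rivers=rivers,
        priority_polygons=priority_polygons,
        protected_areas=protected_areas,
        sensitivity_zones=sensitivity_zones,
        goals=goals,
        region_names=region_names,
        truth=truth,
    )
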