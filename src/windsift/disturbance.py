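"""Build the binary disturbed/undisturbed footprint.

A cell is disturbed if it carries any mapped human impact: a disturbed
land-cover class (cropland, developed classes, hay/pasture), impervious
surface, significant topographic change (surface mines), an active well
field (kernel density of well points), linear infrastructure (roads,
pipelines, railways, transmission lines), or a buffered settlement.

Each source becomes its own :class:`~windsift.grid.Mask`; the footprint is
their cellwise union.  Nodata in a single source is treated as "no evidence
of disturbance" from that source; a cell is nodata in the union only when
every contributing source is nodata there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely import box as shapely_box

from .features import FeatureSet
from .grid import MASK_NODATA, Grid, Mask

__all__ = [
    "DisturbanceConfig",
    "ConfigurationError",
    "landcover_mask",
    "impervious_mask",
    "topo_change_mask",
    "well_field_mask",
    "linear_mask",
    "point_buffer_mask",
    "union_masks",
    "disturbance_footprint",
]

# NLCD-style codes treated as disturbed by default: developed open space /
# low / medium / high intensity, hay/pasture, cultivated crops.
DEFAULT_DISTURBED_LC_CODES = frozenset({21, 22, 23, 24, 81, 82})

# Mapped topographic change flags surface mines; the source product applies
# a land-cover-dependent significance threshold between 10.21 and 17.57 m.
TOPO_THRESHOLD_RANGE_M = (10.21, 17.57)


class ConfigurationError(ValueError):
    """A disturbance configuration references codes/layers it should not."""


@dataclass
class DisturbanceConfig:
    """Parameters of the disturbance footprint.

    ``kde_bandwidth`` is the finite support radius (meters) of the quartic
    kernel used for well-field density; ``kde_threshold`` is in wells/km².
    ``linear_raster_resolution`` is the fine rasterization step for linear
    features (meters); ``hamlet_buffer`` the settlement buffer radius.
    """

    disturbed_lc_codes: frozenset[int] = DEFAULT_DISTURBED_LC_CODES
    impervious_threshold: float = 0.0
    topo_change_threshold_by_lc: dict[int, float] = field(default_factory=dict)
    topo_change_default_threshold: float = TOPO_THRESHOLD_RANGE_M[0]
    kde_bandwidth: float = 1000.0
    kde_threshold: float = 1.0
    linear_raster_resolution: float = 30.0
    hamlet_buffer: float = 300.0

    def __post_init__(self) -> None:
        if self.kde_bandwidth <= 0:
            raise ConfigurationError("kde_bandwidth must be positive")
        if self.kde_threshold < 0:
            raise ConfigurationError("kde_threshold must be non-negative")
        if self.linear_raster_resolution <= 0:
            raise ConfigurationError("linear_raster_resolution must be positive")
        if self.hamlet_buffer < 0:
            raise ConfigurationError("hamlet_buffer must be non-negative")
        for code, thr in self.topo_change_threshold_by_lc.items():
            if thr < 0:
                raise ConfigurationError(
                    f"topographic-change threshold for code {code} is negative"
                )


def landcover_mask(
    landcover: Grid, disturbed_lc_codes, schema_codes=None
) -> Mask:
    """Cells whose land-cover code is in the disturbed set.

    ``schema_codes``, when given, is the set of codes legal in the land-cover
    schema; a disturbed code outside it raises :class:`ConfigurationError`.
    Nodata cells stay nodata.
    """
    codes = set(int(c) for c in disturbed_lc_codes)
    if schema_codes is not None:
        unknown = codes - set(int(c) for c in schema_codes)
        if unknown:
            raise ConfigurationError(
                f"disturbed land-cover codes {sorted(unknown)} are not in the schema"
            )
    hit = np.isin(landcover.data, sorted(codes))
    out = hit.astype(np.uint8)
    out[landcover.nodata_mask()] = MASK_NODATA
    return Mask(grid=landcover.like(out, nodata=MASK_NODATA), provenance=["landcover"])


def impervious_mask(impervious: Grid, threshold: float = 0.0) -> Mask:
    """Cells with impervious fraction strictly above ``threshold``."""
    out = (impervious.data > threshold).astype(np.uint8)
    out[impervious.nodata_mask()] = MASK_NODATA
    return Mask(grid=impervious.like(out, nodata=MASK_NODATA), provenance=["impervious"])


def topo_change_mask(
    topo_change: Grid,
    landcover: Grid,
    threshold_by_lc: dict[int, float],
    default_threshold: float | None = None,
) -> Mask:
    """Cells with |topographic change| at or above the land-cover-specific
    significance threshold.

    Every land-cover code present on the grid must have a threshold either in
    ``threshold_by_lc`` or via ``default_threshold``; a missing code is a
    configuration error.
    """
    topo_change.require_aligned(landcover, "landcover")
    lc = landcover.data
    valid = ~landcover.nodata_mask()
    present = np.unique(lc[valid]).tolist()
    thresholds = {int(k): float(v) for k, v in threshold_by_lc.items()}
    missing = [c for c in present if int(c) not in thresholds]
    if missing and default_threshold is None:
        raise ConfigurationError(
            f"no topographic-change threshold for land-cover codes {missing}"
        )
    thr = np.full(topo_change.shape, np.inf)
    for code in present:
        thr[lc == code] = thresholds.get(int(code), default_threshold)
    magnitude = np.abs(np.asarray(topo_change.data, dtype=float))
    hit = magnitude >= thr
    out = hit.astype(np.uint8)
    out[topo_change.nodata_mask() | landcover.nodata_mask()] = MASK_NODATA
    return Mask(grid=topo_change.like(out, nodata=MASK_NODATA), provenance=["topo_change"])


def well_density(
    wells: FeatureSet, grid_template: Grid, bandwidth: float
) -> np.ndarray:
    """Quartic (biweight) kernel density of well points, in wells per km².

    The kernel has finite support equal to ``bandwidth`` (meters) and unit
    mass, so the density surface integrates to the number of wells over the
    plane (mass is lost only where the support extends past the grid edge).
    """
    if bandwidth <= 0:
        raise ConfigurationError("bandwidth must be positive")
    rows, cols = grid_template.shape
    density = np.zeros((rows, cols))
    if len(wells) == 0:
        return density
    cell = grid_template.cell_size
    # per-well kernel: K(d) = 3/(pi h^2) (1 - (d/h)^2)^2 for d < h (per m^2)
    norm = 3.0 / (np.pi * bandwidth**2) * 1e6  # -> wells per km^2
    reach = int(np.ceil(bandwidth / cell)) + 1
    xs = grid_template.x_origin + (np.arange(cols) + 0.5) * cell
    ys = grid_template.y_origin - (np.arange(rows) + 0.5) * cell
    for x, y in wells.coords():
        r0, c0 = grid_template.xy_to_rowcol(x, y)
        rlo, rhi = max(int(r0) - reach, 0), min(int(r0) + reach + 1, rows)
        clo, chi = max(int(c0) - reach, 0), min(int(c0) + reach + 1, cols)
        if rlo >= rhi or clo >= chi:
            # well far outside the grid may still touch it; fall back to full
            # window only when its kernel support overlaps the bounds
            w, s, e, n = grid_template.bounds
            if (x + bandwidth < w or x - bandwidth >= e
                    or y + bandwidth <= s or y - bandwidth > n):
                continue
            rlo, rhi, clo, chi = 0, rows, 0, cols
        dx = xs[clo:chi] - x
        dy = ys[rlo:rhi] - y
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        u2 = d2 / bandwidth**2
        contrib = np.where(u2 < 1.0, norm * (1.0 - u2) ** 2, 0.0)
        density[rlo:rhi, clo:chi] += contrib
    return density


def well_field_mask(
    wells: FeatureSet, grid_template: Grid, bandwidth: float, threshold: float
) -> Mask:
    """Cells where well kernel density reaches ``threshold`` wells/km²."""
    if threshold < 0:
        raise ConfigurationError("threshold must be non-negative")
    density = well_density(wells, grid_template, bandwidth)
    return Mask.from_bool(grid_template, density >= threshold, ["well_field"])


def linear_mask(
    lines: FeatureSet, grid_template: Grid, resolution: float = 30.0
) -> Mask:
    """Rasterize linear infrastructure at ``resolution`` meters.

    A fine sub-cell (resolution-sized footprint) is hit when a line
    intersects it; an analysis cell is 1 when any of its sub-cells is hit.
    With ``resolution >= cell_size`` this degrades to direct cell-footprint
    intersection.
    """
    if resolution <= 0:
        raise ConfigurationError("resolution must be positive")
    rows, cols = grid_template.shape
    hit = np.zeros((rows, cols), dtype=bool)
    if len(lines) == 0:
        return Mask.from_bool(grid_template, hit, ["linear"])
    cell = grid_template.cell_size
    sub = max(1, int(round(cell / resolution)))
    substep = cell / sub
    x0, y0 = grid_template.x_origin, grid_template.y_origin
    w, s, e, n = grid_template.bounds
    for geom, _ in lines:
        gw, gs, ge, gn = geom.bounds
        # candidate analysis-cell window from the geometry's bbox
        clo = max(int(np.floor((gw - x0) / cell)), 0)
        chi = min(int(np.floor((ge - x0) / cell)) + 1, cols)
        rlo = max(int(np.floor((y0 - gn) / cell)), 0)
        rhi = min(int(np.floor((y0 - gs) / cell)) + 1, rows)
        for r in range(rlo, rhi):
            for c in range(clo, chi):
                if hit[r, c]:
                    continue
                cx0 = x0 + c * cell
                cy1 = y0 - r * cell
                if not geom.intersects(shapely_box(cx0, cy1 - cell, cx0 + cell, cy1)):
                    continue
                if sub == 1:
                    hit[r, c] = True
                    continue
                # test resolution-sized sub-cells within the analysis cell
                for sr in range(sub):
                    done = False
                    for sc in range(sub):
                        bx0 = cx0 + sc * substep
                        by1 = cy1 - sr * substep
                        if geom.intersects(
                            shapely_box(bx0, by1 - substep, bx0 + substep, by1)
                        ):
                            hit[r, c] = True
                            done = True
                            break
                    if done:
                        break
    return Mask.from_bool(grid_template, hit, ["linear"])


def point_buffer_mask(
    points: FeatureSet, grid_template: Grid, radius: float
) -> Mask:
    """Cells whose center lies within ``radius`` meters of any point.

    The cell containing a point is always marked, whatever the radius: the
    buffer degenerates to the point itself at radius 0 and that point lies
    in its containing cell.
    """
    if radius < 0:
        raise ConfigurationError("radius must be non-negative")
    rows, cols = grid_template.shape
    hit = np.zeros((rows, cols), dtype=bool)
    if len(points) == 0:
        return Mask.from_bool(grid_template, hit, ["point_buffer"])
    cell = grid_template.cell_size
    xs = grid_template.x_origin + (np.arange(cols) + 0.5) * cell
    ys = grid_template.y_origin - (np.arange(rows) + 0.5) * cell
    reach = int(np.ceil(radius / cell)) + 1
    for x, y in points.coords():
        r0, c0 = grid_template.xy_to_rowcol(x, y)
        if 0 <= r0 < rows and 0 <= c0 < cols:
            hit[int(r0), int(c0)] = True
        rlo, rhi = max(int(r0) - reach, 0), min(int(r0) + reach + 1, rows)
        clo, chi = max(int(c0) - reach, 0), min(int(c0) + reach + 1, cols)
        if rlo >= rhi or clo >= chi:
            continue
        dx = xs[clo:chi] - x
        dy = ys[rlo:rhi] - y
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        hit[rlo:rhi, clo:chi] |= d2 <= radius**2
    return Mask.from_bool(grid_template, hit, ["point_buffer"])


def union_masks(masks: list[Mask]) -> Mask:
    """Cellwise OR of aligned masks; provenance lists are concatenated.

    A cell is nodata in the result only when it is nodata in every input.
    """
    if not masks:
        raise ValueError("union_masks requires at least one mask")
    template = masks[0].grid
    for m in masks[1:]:
        template.require_aligned(m.grid, "mask")
    any_hit = np.zeros(template.shape, dtype=bool)
    all_nodata = np.ones(template.shape, dtype=bool)
    provenance: list[str] = []
    for m in masks:
        any_hit |= m.values
        all_nodata &= m.grid.data == MASK_NODATA
        provenance.extend(m.provenance)
    out = any_hit.astype(np.uint8)
    out[all_nodata & ~any_hit] = MASK_NODATA
    return Mask(grid=template.like(out, nodata=MASK_NODATA), provenance=provenance)


def disturbance_footprint(
    landcover: Grid,
    impervious: Grid | None,
    topo_change: Grid | None,
    wells: FeatureSet | None,
    lines: FeatureSet | None,
    hamlets: FeatureSet | None,
    config: DisturbanceConfig,
) -> Mask:
    """Union of all configured disturbance sources on the land-cover grid."""
    masks = [landcover_mask(landcover, config.disturbed_lc_codes)]
    if impervious is not None:
        landcover.require_aligned(impervious, "impervious")
        masks.append(impervious_mask(impervious, config.impervious_threshold))
    if topo_change is not None:
        masks.append(
            topo_change_mask(
                topo_change,
                landcover,
                config.topo_change_threshold_by_lc,
                config.topo_change_default_threshold,
            )
        )
    if wells is not None:
        masks.append(
            well_field_mask(wells, landcover, config.kde_bandwidth, config.kde_threshold)
        )
    if lines is not None:
        masks.append(linear_mask(lines, landcover, config.linear_raster_resolution))
    if hamlets is not None:
        masks.append(point_buffer_mask(hamlets, landcover, config.hamlet_buffer))
    return union_masks(masks)
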