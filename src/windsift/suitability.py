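"""Combine footprint, exclusions, wind viability and hard constraints.

The candidate low-impact surface is the subset of disturbed cells where wind
is economically viable (wind power class at or above the configured minimum,
class 3 by default, i.e. mean annual wind speed >= 6.4 m/s at 50 m) that is
outside all of: wildlife exclusions, permanently protected areas (protection
codes 1-2), urban cores, and wetlands/water bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, Mask

__all__ = [
    "SuitabilityConfig",
    "WindClassError",
    "wind_viability_mask",
    "candidate_mask",
    "regrid_nearest",
]

DEFAULT_WATER_LC_CODES = frozenset({11, 90, 95})
DEFAULT_URBAN_CORE_LC_CODES = frozenset({23, 24})


class WindClassError(ValueError):
    """Wind power class values outside the ordinal 1-7 range."""


@dataclass
class SuitabilityConfig:
    min_wpc: int = 3
    water_lc_codes: frozenset[int] = DEFAULT_WATER_LC_CODES
    urban_core_lc_codes: frozenset[int] = DEFAULT_URBAN_CORE_LC_CODES
    gap_exclude_codes: frozenset[int] = frozenset({1, 2})

    def __post_init__(self) -> None:
        if not 1 <= self.min_wpc <= 7:
            raise ValueError("min_wpc must be within [1, 7]")


def wind_viability_mask(wpc: Grid, min_wpc: int = 3) -> Mask:
    """Cells with wind power class >= ``min_wpc`` (inclusive boundary)."""
    if not 1 <= min_wpc <= 7:
        raise ValueError("min_wpc must be within [1, 7]")
    data = np.asarray(wpc.data)
    valid = ~wpc.nodata_mask()
    values = data[valid]
    if values.size and (values.min() < 1 or values.max() > 7):
        bad = np.unique(values[(values < 1) | (values > 7)])
        raise WindClassError(f"wind power class values outside [1, 7]: {bad}")
    return Mask.from_bool(wpc, valid & (data >= min_wpc), ["wind_viability"])


def candidate_mask(
    disturbed: Mask,
    exclusions: Mask,
    viability: Mask,
    protected: Mask,
    urban: Mask,
    water: Mask,
) -> Mask:
    """disturbed AND viable AND NOT (excluded | protected | urban | water)."""
    template = disturbed.grid
    for m in (exclusions, viability, protected, urban, water):
        template.require_aligned(m.grid, "mask")
    keep = (
        disturbed.values
        & viability.values
        & ~exclusions.values
        & ~protected.values
        & ~urban.values
        & ~water.values
    )
    return Mask.from_bool(template, keep, ["candidate"])


def regrid_nearest(source: Grid, template: Grid) -> Grid:
    """Resample ``source`` onto ``template`` by nearest neighbor.

    Each template cell takes the source value at its center.  Template cells
    whose center falls outside the source extent become nodata (the source's
    sentinel, or NaN for float data without one).
    """
    if source.crs != template.crs:
        from .grid import AlignmentError

        raise AlignmentError(
            f"CRS mismatch: source {source.crs!r} vs template {template.crs!r}"
        )
    X, Y = template.cell_centers()
    rows, cols = source.xy_to_rowcol(X, Y)
    srows, scols = source.shape
    inside = (rows >= 0) & (rows < srows) & (cols >= 0) & (cols < scols)
    rows_c = np.clip(rows, 0, srows - 1)
    cols_c = np.clip(cols, 0, scols - 1)
    values = np.asarray(source.data)[rows_c, cols_c]
    nodata = source.nodata
    if (~inside).any():
        if nodata is None:
            if np.issubdtype(values.dtype, np.floating):
                nodata = np.nan
            else:
                raise ValueError(
                    "template extends beyond source and source has no nodata value"
                )
        values = values.astype(values.dtype if nodata is not np.nan else float)
        values = np.where(inside, values, nodata)
    return template.like(values, nodata=nodata)
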