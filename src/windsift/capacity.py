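"""Installable wind capacity by wind power class and region.

Nameplate capacity per unit area follows the planning convention that an
average build-out installs 5 MW/km² at a fleet-average capacity factor of
44.5%, adjusted per wind power class (WPC): classes below the economic
minimum carry no capacity, and classes 3-7 carry 4.3, 4.8, 5.2, 5.5 and
6.0 MW/km² respectively.  Regional totals divide by 1000 to report GW, and
percent-of-goal is the rounded ratio of low-impact GW to the regional
development goal.  Percentages are computed from unrounded GW and rounded
half away from zero to integers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid, Mask

__all__ = [
    "CapacityDensityTable",
    "RegionSummary",
    "capacity_density",
    "aggregate_capacity",
    "percent_of_goal",
    "summarize_regions",
    "round_half_away",
]

log = logging.getLogger(__name__)

DEFAULT_DENSITY_BY_WPC = {3: 4.3, 4: 4.8, 5: 5.2, 6: 5.5, 7: 6.0}


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class CapacityDensityTable:
    """Mapping wind power class -> installable nameplate MW/km².

    ``reference_density`` and ``reference_capacity_factor`` record the
    fleet-average assumptions the per-class densities are consistent with;
    they are metadata, not inputs to the lookup.
    """

    density_by_wpc: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_BY_WPC)
    )
    reference_density: float = 5.0
    reference_capacity_factor: float = 0.445
    below_min: float = 0.0

    def __post_init__(self) -> None:
        classes = sorted(self.density_by_wpc)
        densities = [self.density_by_wpc[c] for c in classes]
        if any(d <= 0 for d in densities):
            raise ValueError("capacity densities must be positive")
        if any(b >= a for a, b in zip(densities[1:], densities[:-1])):
            raise ValueError("capacity densities must increase with wind power class")


class WindClassError(ValueError):
    pass


def capacity_density(wpc: int, table: CapacityDensityTable | None = None) -> float:
    """MW/km² installable at wind power class ``wpc``; 0 below the minimum."""
    if table is None:
        table = CapacityDensityTable()
    if not 1 <= wpc <= 7:
        raise WindClassError(f"wind power class {wpc} outside [1, 7]")
    return table.density_by_wpc.get(int(wpc), table.below_min)


def aggregate_capacity(
    low_impact: Mask,
    wpc: Grid,
    regions: Grid,
    table: CapacityDensityTable | None = None,
    region_names: dict[int, str] | None = None,
) -> list[tuple[str, float]]:
    """GW of installable capacity on low-impact cells, per region.

    ``regions`` is an integer raster assigning each cell to one region
    (``region_names`` maps codes to labels; codes are used as labels
    otherwise).  Low-impact cells with nodata wind class contribute 0 GW and
    are logged.
    """
    if table is None:
        table = CapacityDensityTable()
    template = low_impact.grid
    template.require_aligned(wpc, "wind power class grid")
    template.require_aligned(regions, "region grid")
    cell_km2 = template.cell_area_km2
    sel = low_impact.values
    wpc_vals = np.asarray(wpc.data)[sel]
    region_vals = np.asarray(regions.data)[sel]
    missing = (
        (wpc_vals == wpc.nodata) if wpc.nodata is not None
        else np.zeros(wpc_vals.shape, dtype=bool)
    )
    if missing.any():
        log.warning(
            "%d low-impact cells have nodata wind power class; counted at 0 MW",
            int(missing.sum()),
        )
    density = np.zeros(wpc_vals.shape)
    for cls, mwkm2 in table.density_by_wpc.items():
        density[(wpc_vals == cls) & ~missing] = mwkm2
    out: list[tuple[str, float]] = []
    for code in np.unique(np.asarray(regions.data)[~regions.nodata_mask()]):
        name = (region_names or {}).get(int(code), str(int(code)))
        gw = float(density[region_vals == code].sum() * cell_km2 / 1000.0)
        out.append((name, gw))
    return out


def percent_of_goal(low_impact_gw: float, goal_gw: float) -> int:
    """Integer percent of the development goal met by low-impact capacity."""
    if goal_gw <= 0:
        raise ValueError("goal_gw must be positive")
    return round_half_away(100.0 * low_impact_gw / goal_gw)


@dataclass
class RegionSummary:
    region: str
    goal_gw: float
    low_impact_gw: float
    pct_of_goal: int


def summarize_regions(
    per_region_gw: list[tuple[str, float]], goals: pd.DataFrame
) -> pd.DataFrame:
    """One row per region plus a Total row.

    ``goals`` needs columns ``region`` and ``goal_gw``.  The Total row sums
    goals and capacity before computing its percent, so it is consistent
    with unrounded regional values rather than with the rounded per-region
    prints.
    """
    goal_map = dict(zip(goals["region"], goals["goal_gw"].astype(float)))
    rows = []
    for region, gw in per_region_gw:
        if region not in goal_map:
            raise KeyError(f"no development goal for region {region!r}")
        rows.append(
            RegionSummary(region, goal_map[region], gw, percent_of_goal(gw, goal_map[region]))
        )
    total_goal = sum(r.goal_gw for r in rows)
    total_gw = sum(r.low_impact_gw for r in rows)
    rows.append(
        RegionSummary("Total", total_goal, total_gw, percent_of_goal(total_gw, total_goal))
    )
    return pd.DataFrame(
        {
            "region": [r.region for r in rows],
            "goal_gw": [r.goal_gw for r in rows],
            "low_impact_gw": [r.low_impact_gw for r in rows],
            "pct_of_goal": [r.pct_of_goal for r in rows],
        }
    )
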