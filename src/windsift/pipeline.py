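"""End-to-end pipeline: landscape in, low-impact surface and summaries out.

Stage order matches the analysis: (1) disturbance footprint, (2) wildlife
exclusions from the jurisdiction rule set, (3) hard suitability constraints
(wind viability, protected status, urban cores, water), (4) the small-
isolated-patch filter, (5) capacity aggregation against regional goals and
(6) the turbine audit.  Every run emits a provenance record listing the
rules, thresholds and layer checksums that produced the outputs, so a rerun
on identical inputs is bit-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .capacity import CapacityDensityTable, aggregate_capacity, summarize_regions
from .disturbance import DisturbanceConfig, disturbance_footprint
from .exclusions import ExclusionRule, RuleSet, compile_rule, compose_exclusions
from .grid import Grid, Mask
from .patches import filter_small_isolated
from .suitability import (
    SuitabilityConfig,
    candidate_mask,
    wind_viability_mask,
)
from .synth import SyntheticLandscape
from .turbines import classify_turbines, summarize_turbines

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineConfig:
    jurisdiction: str = "north_south_dakota"
    ruleset: RuleSet | None = None  # overrides jurisdiction lookup when given
    disturbance: DisturbanceConfig = field(default_factory=DisturbanceConfig)
    suitability: SuitabilityConfig = field(default_factory=SuitabilityConfig)
    capacity_table: CapacityDensityTable = field(default_factory=CapacityDensityTable)
    min_patch_area_km2: float = 1.0
    max_patch_distance_m: float = 800.0
    connectivity: int = 8

    def resolve_ruleset(self) -> RuleSet:
        if self.ruleset is not None:
            return self.ruleset
        return wio.load_shipped_ruleset(self.jurisdiction)


@dataclass
class PipelineResult:
    disturbed: Mask
    exclusions: Mask
    viability: Mask
    protected: Mask
    urban: Mask
    water: Mask
    candidate: Mask
    low_impact: Mask
    region_summary: pd.DataFrame
    turbine_summary: pd.DataFrame
    provenance: dict


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(
    landscape: SyntheticLandscape, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run every stage on an in-memory landscape bundle."""
    config = config or PipelineConfig()
    layers = landscape.layer_map()
    template = landscape.landcover

    disturbed = disturbance_footprint(
        landcover=landscape.landcover,
        impervious=landscape.impervious,
        topo_change=landscape.topo_change,
        wells=landscape.wells,
        lines=landscape.roads,
        hamlets=landscape.hamlets,
        config=config.disturbance,
    )

    ruleset = config.resolve_ruleset()
    exclusions = compose_exclusions(ruleset, layers, template)

    viability = wind_viability_mask(landscape.wpc, config.suitability.min_wpc)
    protected = compile_rule(
        ExclusionRule(
            rule_id="protected_gap_1_2",
            source="protected_areas",
            operator="polygon_burn",
            params={
                "where": {
                    "field": "gap_code",
                    "in": sorted(config.suitability.gap_exclude_codes),
                }
            },
        ),
        layers,
        template,
    )
    from .disturbance import landcover_mask

    urban = landcover_mask(
        landscape.landcover, config.suitability.urban_core_lc_codes
    )
    urban.provenance = ["urban_core"]
    water = landcover_mask(landscape.landcover, config.suitability.water_lc_codes)
    water.provenance = ["water_wetland"]

    candidate = candidate_mask(
        disturbed, exclusions, viability, protected, urban, water
    )
    low_impact = filter_small_isolated(
        candidate,
        min_area_km2=config.min_patch_area_km2,
        max_distance_m=config.max_patch_distance_m,
        connectivity=config.connectivity,
    )

    per_region = aggregate_capacity(
        low_impact,
        landscape.wpc,
        landscape.regions,
        config.capacity_table,
        landscape.region_names,
    )
    region_summary = summarize_regions(per_region, landscape.goals)
    classified = classify_turbines(landscape.turbines, low_impact)
    turbine_summary = summarize_turbines(classified)

    provenance = {
        "jurisdiction": ruleset.jurisdiction,
        "rules": [r.to_dict() for r in ruleset.rules],
        "disturbance": {
            "disturbed_lc_codes": sorted(config.disturbance.disturbed_lc_codes),
            "impervious_threshold": config.disturbance.impervious_threshold,
            "topo_change_default_threshold":
                config.disturbance.topo_change_default_threshold,
            "kde_bandwidth_m": config.disturbance.kde_bandwidth,
            "kde_threshold_wells_per_km2": config.disturbance.kde_threshold,
            "linear_raster_resolution_m":
                config.disturbance.linear_raster_resolution,
            "hamlet_buffer_m": config.disturbance.hamlet_buffer,
        },
        "suitability": {
            "min_wpc": config.suitability.min_wpc,
            "water_lc_codes": sorted(config.suitability.water_lc_codes),
            "urban_core_lc_codes": sorted(config.suitability.urban_core_lc_codes),
            "gap_exclude_codes": sorted(config.suitability.gap_exclude_codes),
        },
        "patch_filter": {
            "min_area_km2": config.min_patch_area_km2,
            "max_distance_m": config.max_patch_distance_m,
            "connectivity": config.connectivity,
        },
        "capacity_density_mw_per_km2": {
            str(k): v for k, v in config.capacity_table.density_by_wpc.items()
        },
        "layer_checksums": {
            name: _checksum(np.asarray(layer.data))
            for name, layer in landscape.grids.items()
        },
        "mask_cells": {
            "disturbed": disturbed.cell_count,
            "exclusions": exclusions.cell_count,
            "candidate": candidate.cell_count,
            "low_impact": low_impact.cell_count,
        },
    }
    return PipelineResult(
        disturbed=disturbed,
        exclusions=exclusions,
        viability=viability,
        protected=protected,
        urban=urban,
        water=water,
        candidate=candidate,
        low_impact=low_impact,
        region_summary=region_summary,
        turbine_summary=turbine_summary,
        provenance=provenance,
    )


def write_outputs(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write low-impact GeoTIFF, summary CSVs and the provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "low_impact": out / "low_impact.tif",
        "region_summary": out / "region_summary.csv",
        "turbine_summary": out / "turbine_summary.csv",
        "provenance": out / "provenance.json",
    }
    wio.write_grid(result.low_impact.grid, paths["low_impact"])
    result.region_summary.to_csv(paths["region_summary"], index=False)
    result.turbine_summary.to_csv(paths["turbine_summary"], index=False)
    paths["provenance"].write_text(json.dumps(result.provenance, indent=1))
    return paths
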