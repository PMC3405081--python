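"""Declarative wildlife-exclusion rule engine.

Each jurisdiction (state or province pair) contributes a :class:`RuleSet`: an
ordered list of :class:`ExclusionRule` records naming a source layer, an
operator and its parameters.  Rules compile independently to binary masks on
the analysis grid, and a rule set composes to the union of its rules, so the
result is invariant to rule order.  Areas matched by any rule are withheld
from low-impact designation even where they are already disturbed.

Supported operators
-------------------
polygon_burn
    Burn polygons (optionally attribute-filtered, e.g. protection code 1-2)
    into cells whose center falls inside a polygon.
category_at_least / category_in_set
    Threshold or membership test on a categorical sensitivity raster.
density_at_least
    Inclusive threshold on a continuous density raster (e.g. waterfowl
    breeding pairs per km²).
point_buffer / line_buffer
    Distance buffers around point or line features (cell-center distance).
repeated_stopover_buffer
    Buffer around repeatedly used migratory stopover sites, derived from
    dated observations: a site qualifies when its clustered observations
    span at least two distinct years, or at least three distinct days within
    a single year.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date

import numpy as np
from scipy.spatial import cKDTree
from shapely import intersects_xy, union_all
from shapely.geometry import Point

from .disturbance import point_buffer_mask, union_masks
from .features import FeatureSet
from .grid import Grid, Mask

__all__ = [
    "ExclusionRule",
    "RuleSet",
    "RuleError",
    "DataError",
    "OPERATORS",
    "repeated_stopover_sites",
    "compile_rule",
    "compose_exclusions",
    "polygon_mask",
    "line_buffer_mask",
]

OPERATORS = frozenset(
    {
        "polygon_burn",
        "category_at_least",
        "category_in_set",
        "density_at_least",
        "point_buffer",
        "line_buffer",
        "repeated_stopover_buffer",
    }
)


class RuleError(ValueError):
    """A rule is malformed or cannot be resolved against the layer map."""


class DataError(ValueError):
    """A layer record violates the rule's data contract (e.g. missing date)."""


@dataclass
class ExclusionRule:
    rule_id: str
    source: str
    operator: str
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise RuleError(
                f"rule {self.rule_id!r}: unknown operator {self.operator!r}"
            )
        for key in ("radius", "site_radius"):
            if key in self.params and self.params[key] < 0:
                raise RuleError(f"rule {self.rule_id!r}: {key} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "source": self.source,
            "operator": self.operator,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "ExclusionRule":
        return cls(
            rule_id=obj["rule_id"],
            source=obj["source"],
            operator=obj["operator"],
            params=dict(obj.get("params") or {}),
        )


@dataclass
class RuleSet:
    jurisdiction: str
    rules: list[ExclusionRule] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RuleError(f"duplicate rule_ids in {self.jurisdiction!r}: {dupes}")

    def to_dict(self) -> dict:
        return {
            "jurisdiction": self.jurisdiction,
            "rules": [r.to_dict() for r in self.rules],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "RuleSet":
        return cls(
            jurisdiction=obj["jurisdiction"],
            rules=[ExclusionRule.from_dict(r) for r in obj.get("rules", [])],
        )


# ---------------------------------------------------------------------------
# stopover-site detection


def _parse_date(value, index: int) -> date:
    try:
        return date.fromisoformat(str(value))
    except (TypeError, ValueError):
        raise DataError(
            f"observation {index} has no parseable ISO date (got {value!r})"
        ) from None


def _cluster_points(coords: np.ndarray, radius: float) -> np.ndarray:
    """Single-linkage clustering: points within ``radius`` share a label."""
    n = len(coords)
    labels = np.arange(n)

    def find(i):
        while labels[i] != i:
            labels[i] = labels[labels[i]]
            i = labels[i]
        return i

    if radius > 0 and n > 1:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(radius):
            ri, rj = find(i), find(j)
            if ri != rj:
                labels[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, dense = np.unique(roots, return_inverse=True)
    return dense


def repeated_stopover_sites(
    observations: FeatureSet, site_radius: float = 100.0
) -> FeatureSet:
    """Representative points of repeatedly used stopover sites.

    Observations are clustered into sites by single linkage at
    ``site_radius`` meters.  A site is *repeated* when its observations span
    two or more distinct years, or include three or more distinct days within
    one year.  One representative point (the centroid of the site's
    observations) is returned per qualifying site, carrying ``n_obs``,
    ``n_years`` and ``max_days_one_year`` attributes.
    """
    if len(observations) == 0:
        return FeatureSet(kind="point")
    dates = [
        _parse_date(attrs.get("date"), i)
        for i, (_, attrs) in enumerate(observations)
    ]
    coords = observations.coords()
    labels = _cluster_points(coords, site_radius)
    out_geoms, out_attrs = [], []
    for lab in range(labels.max() + 1):
        idx = np.flatnonzero(labels == lab)
        site_dates = [dates[i] for i in idx]
        years = {d.year for d in site_dates}
        days_per_year = {
            y: len({d for d in site_dates if d.year == y}) for y in years
        }
        max_days = max(days_per_year.values())
        if len(years) >= 2 or max_days >= 3:
            cx, cy = coords[idx].mean(axis=0)
            out_geoms.append(Point(cx, cy))
            out_attrs.append(
                {
                    "n_obs": int(len(idx)),
                    "n_years": int(len(years)),
                    "max_days_one_year": int(max_days),
                }
            )
    return FeatureSet(kind="point", geometries=out_geoms, attributes=out_attrs)


# ---------------------------------------------------------------------------
# mask builders shared across operators


def polygon_mask(polygons: FeatureSet, template: Grid, provenance=()) -> Mask:
    """Cells whose center lies inside (or on the boundary of) any polygon."""
    if len(polygons) == 0:
        return Mask.zeros(template, provenance)
    geom = union_all(list(polygons.geometries))
    X, Y = template.cell_centers()
    inside = intersects_xy(geom.buffer(0), X.ravel(), Y.ravel()).reshape(template.shape)
    return Mask.from_bool(template, inside, provenance)


def line_buffer_mask(
    lines: FeatureSet, template: Grid, radius: float, provenance=()
) -> Mask:
    """Cells whose center is within ``radius`` meters of any line."""
    if len(lines) == 0:
        return Mask.zeros(template, provenance)
    geom = union_all(list(lines.geometries)).buffer(radius)
    X, Y = template.cell_centers()
    inside = intersects_xy(geom, X.ravel(), Y.ravel()).reshape(template.shape)
    return Mask.from_bool(template, inside, provenance)


def _apply_where(layer: FeatureSet, params: dict) -> FeatureSet:
    where = params.get("where")
    if not where:
        return layer
    return layer.where(where["field"], where["in"])


def compile_rule(rule: ExclusionRule, layers: dict, template: Grid) -> Mask:
    """Compile one exclusion rule to a mask on the analysis grid."""
    if rule.source not in layers:
        raise RuleError(
            f"rule {rule.rule_id!r}: source layer {rule.source!r} not provided"
        )
    layer = layers[rule.source]
    op = rule.operator
    p = rule.params

    def need(kind: str):
        if not isinstance(layer, FeatureSet) or layer.kind != kind:
            raise RuleError(
                f"rule {rule.rule_id!r}: source {rule.source!r} must be a "
                f"{kind} layer"
            )
        return _apply_where(layer, p)

    def need_grid() -> Grid:
        if not isinstance(layer, Grid):
            raise RuleError(
                f"rule {rule.rule_id!r}: source {rule.source!r} must be a raster"
            )
        template.require_aligned(layer, rule.source)
        return layer

    prov = [rule.rule_id]
    if op == "polygon_burn":
        return polygon_mask(need("polygon"), template, prov)
    if op == "category_at_least":
        grid = need_grid()
        return Mask.from_bool(template, grid.data >= p["min_category"], prov)
    if op == "category_in_set":
        grid = need_grid()
        cats = sorted(int(c) for c in p["categories"])
        return Mask.from_bool(template, np.isin(grid.data, cats), prov)
    if op == "density_at_least":
        grid = need_grid()
        hit = np.asarray(grid.data, dtype=float) >= p["threshold"]
        if grid.nodata is not None:
            hit &= ~grid.nodata_mask()
        return Mask.from_bool(template, hit, prov)
    if op == "point_buffer":
        mask = point_buffer_mask(need("point"), template, p["radius"])
        mask.provenance = prov
        return mask
    if op == "line_buffer":
        return line_buffer_mask(need("line"), template, p["radius"], prov)
    if op == "repeated_stopover_buffer":
        sites = repeated_stopover_sites(
            need("point"), p.get("site_radius", template.cell_size)
        )
        mask = point_buffer_mask(sites, template, p["radius"])
        mask.provenance = prov
        return mask
    raise RuleError(f"rule {rule.rule_id!r}: unknown operator {op!r}")


def compose_exclusions(ruleset: RuleSet, layers: dict, template: Grid) -> Mask:
    """Union of all rule masks in the set; empty rule set excludes nothing."""
    if not ruleset.rules:
        return Mask.zeros(template, [f"{ruleset.jurisdiction}:empty"])
    masks = []
    for rule in ruleset.rules:
        try:
            masks.append(compile_rule(rule, layers, template))
        except (RuleError, DataError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise RuleError(f"rule {rule.rule_id!r} failed: {exc}") from exc
    return union_masks(masks)
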