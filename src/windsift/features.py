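"""Vector feature container built on shapely geometries.

A ``FeatureSet`` is an ordered collection of shapely geometries of a single
kind (points, lines, or polygons) with one attribute mapping per feature.
Dates are carried as ISO-8601 strings so year/day extraction is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = ["FeatureSet", "GeometryTypeError"]

_KIND_TYPES = {
    "point": {"Point", "MultiPoint"},
    "line": {"LineString", "MultiLineString"},
    "polygon": {"Polygon", "MultiPolygon"},
}


class GeometryTypeError(TypeError):
    """A geometry's type does not match the layer's declared kind."""


@dataclass
class FeatureSet:
    """Typed vector records: geometries plus per-feature attributes.

    Parameters
    ----------
    kind:
        One of ``"point"``, ``"line"``, ``"polygon"``.
    geometries:
        Shapely geometries, all consistent with ``kind``.
    attributes:
        One dict per geometry (defaults to empty dicts).
    """

    kind: str
    geometries: list[BaseGeometry] = field(default_factory=list)
    attributes: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in _KIND_TYPES:
            raise ValueError(f"kind must be one of {sorted(_KIND_TYPES)}, got {self.kind!r}")
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        if len(self.attributes) != len(self.geometries):
            raise ValueError("geometries and attributes lengths differ")
        allowed = _KIND_TYPES[self.kind]
        for geom in self.geometries:
            if geom.geom_type not in allowed:
                raise GeometryTypeError(
                    f"expected {self.kind} layer, found {geom.geom_type}"
                )

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self) -> Iterator[tuple[BaseGeometry, dict[str, Any]]]:
        return iter(zip(self.geometries, self.attributes))

    def coords(self) -> np.ndarray:
        """(n, 2) array of point coordinates; only valid for point layers."""
        if self.kind != "point":
            raise GeometryTypeError("coords() requires a point layer")
        if not self.geometries:
            return np.empty((0, 2))
        return np.array([(g.x, g.y) for g in self.geometries])

    def filter(self, predicate) -> "FeatureSet":
        keep = [(g, a) for g, a in self if predicate(a)]
        return FeatureSet(
            kind=self.kind,
            geometries=[g for g, _ in keep],
            attributes=[dict(a) for _, a in keep],
        )

    def where(self, field_name: str, values) -> "FeatureSet":
        """Subset of features whose attribute ``field_name`` is in ``values``."""
        values = set(values)
        return self.filter(lambda a: a.get(field_name) in values)

    # -- GeoJSON interop ---------------------------------------------------

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": geom.__geo_interface__,
                    "properties": dict(attrs),
                }
                for geom, attrs in self
            ],
        }

    @classmethod
    def from_geojson(cls, obj: dict, kind: str) -> "FeatureSet":
        feats = obj.get("features", [])
        geoms = [_shapely_shape(f["geometry"]) for f in feats]
        attrs = [dict(f.get("properties") or {}) for f in feats]
        return cls(kind=kind, geometries=geoms, attributes=attrs)
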