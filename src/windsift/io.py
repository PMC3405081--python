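"""Readers and writers: single-band GeoTIFF, GeoJSON, CSV tables, YAML rules.

Rasters travel as single-band GeoTIFF with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, a minimal GeoKey directory carrying the
EPSG code, and the GDAL nodata convention).  Vectors travel as GeoJSON, one
FeatureCollection per layer, with dates as ISO-8601 attribute strings.
Jurisdiction rule sets travel as YAML; five sets covering the seven study
jurisdictions ship with the package.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exclusions import RuleSet
from .features import FeatureSet, GeometryTypeError
from .grid import Grid

__all__ = [
    "GridIOError",
    "read_grid",
    "write_grid",
    "read_features",
    "write_features",
    "read_goals",
    "write_goals",
    "read_ruleset",
    "write_ruleset",
    "load_shipped_ruleset",
    "shipped_ruleset_names",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


class GridIOError(IOError):
    """A raster file is unreadable or lacks required georeferencing."""


def write_grid(grid: Grid, path) -> None:
    """Write a grid as a single-band GeoTIFF."""
    path = Path(path)
    epsg = 32767  # user-defined unless the CRS is an EPSG code
    m = re.fullmatch(r"EPSG:(\d+)", grid.crs, flags=re.IGNORECASE)
    if m:
        epsg = int(m.group(1))
    # minimal GeoKey directory: projected model type + projected CRS code
    geokeys = (
        1, 1, 0, 3,
        1024, 0, 1, 1,       # GTModelType = projected
        1025, 0, 1, 1,       # RasterPixelIsArea
        3072, 0, 1, epsg,    # ProjectedCRS
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, grid.crs + "|"),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)))
    tifffile.imwrite(path, np.asarray(grid.data), extratags=extratags)


def read_grid(path) -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_grid` (or any
    GeoTIFF carrying pixel-scale + tiepoint georeferencing)."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tag_values = {
                code: (page.tags[code].value if code in page.tags else None)
                for code in (
                    _TAG_MODEL_PIXEL_SCALE,
                    _TAG_MODEL_TIEPOINT,
                    _TAG_GEO_KEY_DIRECTORY,
                    _TAG_GEO_ASCII_PARAMS,
                    _TAG_GDAL_NODATA,
                )
            }
    except (OSError, ValueError) as exc:
        raise GridIOError(f"cannot read raster {path}: {exc}") from exc
    scale = tag_values[_TAG_MODEL_PIXEL_SCALE]
    tiepoint = tag_values[_TAG_MODEL_TIEPOINT]
    if scale is None or tiepoint is None:
        raise GridIOError(f"{path} lacks georeferencing (pixel scale/tiepoint)")
    sx, sy = scale[0], scale[1]
    if not np.isclose(sx, sy):
        raise GridIOError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    i, j, _, x, y, _ = tiepoint[:6]
    x_origin = x - j * sx
    y_origin = y + i * sy
    crs = None
    if tag_values[_TAG_GEO_ASCII_PARAMS] is not None:
        crs = str(tag_values[_TAG_GEO_ASCII_PARAMS]).rstrip("|").strip() or None
    if crs is None and tag_values[_TAG_GEO_KEY_DIRECTORY] is not None:
        vals = list(tag_values[_TAG_GEO_KEY_DIRECTORY])
        for k in range(4, len(vals) - 3, 4):
            if vals[k] == 3072 and vals[k + 3] != 32767:
                crs = f"EPSG:{vals[k + 3]}"
                break
    if crs is None:
        raise GridIOError(f"{path} carries no coordinate reference system")
    nodata = None
    if tag_values[_TAG_GDAL_NODATA] is not None:
        text = str(tag_values[_TAG_GDAL_NODATA]).strip()
        nodata = float(text) if ("." in text or "e" in text.lower()) else int(text)
    if data.ndim != 2:
        raise GridIOError(f"{path}: expected a single-band raster")
    return Grid(
        data=data, x_origin=float(x_origin), y_origin=float(y_origin),
        cell_size=float(sx), crs=crs, nodata=nodata,
    )


# ---------------------------------------------------------------------------
# vectors


def write_features(features: FeatureSet, path) -> None:
    Path(path).write_text(json.dumps(features.to_geojson(), indent=1))


def read_features(path, kind: str) -> FeatureSet:
    """Read a GeoJSON FeatureCollection as a layer of the given kind.

    Raises :class:`~windsift.features.GeometryTypeError` when the file's
    geometry type does not match the expected layer kind.  An empty
    collection is valid and yields an empty FeatureSet.
    """
    obj = json.loads(Path(path).read_text())
    try:
        return FeatureSet.from_geojson(obj, kind)
    except GeometryTypeError as exc:
        raise GeometryTypeError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# tables and rule sets


def read_goals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"region", "goal_gw"} - set(df.columns)
    if missing:
        raise ValueError(f"goals table {path} lacks columns {sorted(missing)}")
    return df


def write_goals(goals: pd.DataFrame, path) -> None:
    goals.to_csv(path, index=False)


def read_ruleset(path) -> RuleSet:
    with open(path) as fh:
        return RuleSet.from_dict(yaml.safe_load(fh))


def write_ruleset(ruleset: RuleSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ruleset.to_dict(), fh, sort_keys=False)


def shipped_ruleset_names() -> list[str]:
    root = resources.files("windsift") / "rulesets"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_shipped_ruleset(name: str) -> RuleSet:
    root = resources.files("windsift") / "rulesets"
    candidate = root / f"{name}.yaml"
    if not candidate.is_file():
        raise FileNotFoundError(
            f"no shipped rule set {name!r}; available: {shipped_ruleset_names()}"
        )
    return RuleSet.from_dict(yaml.safe_load(candidate.read_text()))
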