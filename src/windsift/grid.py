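"""Raster grid and binary mask containers.

Everything downstream assumes a single analysis grid: a north-up raster of
square cells in a projected, meter-unit, equal-area coordinate system.  A
``Grid`` carries the cell values, the georeferencing (west/north origin and
cell size) and a nodata sentinel; a ``Mask`` is a thin wrapper around a 0/1
grid that additionally remembers which rules produced it.

Cell ownership follows the half-open raster convention: a cell owns its
top-left edge, so a point exactly on a shared edge belongs to the cell below
/ to the right of that edge's origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Grid", "Mask", "AlignmentError", "MASK_NODATA"]

#: nodata sentinel used for mask (uint8) grids
MASK_NODATA = 255


class AlignmentError(ValueError):
    """Two grids that must share shape/georeferencing do not."""


@dataclass
class Grid:
    """A single-band raster on a projected equal-area grid.

    Parameters
    ----------
    data:
        2-D array of cell values, row 0 at the northern edge.
    x_origin, y_origin:
        Projected coordinates (meters) of the grid's top-left corner.
    cell_size:
        Side length of a (square) cell in meters.
    crs:
        Coordinate reference system identifier, e.g. ``"EPSG:5070"``.
        Required; all grids entering one analysis must agree.
    nodata:
        Sentinel value marking missing cells, or ``None``.
    """

    data: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    crs: str = "EPSG:5070"
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"grid data must be 2-D, got shape {self.data.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not self.crs:
            raise ValueError("grid requires a CRS identifier")

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) in projected coordinates."""
        rows, cols = self.shape
        return (
            self.x_origin,
            self.y_origin - rows * self.cell_size,
            self.x_origin + cols * self.cell_size,
            self.y_origin,
        )

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def xy_to_rowcol(self, x, y):
        """Map projected coordinates to (row, col) indices.

        Half-open convention: a cell owns its top and left edges.  Indices
        may fall outside ``shape`` for out-of-bounds points; callers decide
        how to handle those.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.x_origin) / self.cell_size)
        row = np.floor((self.y_origin - np.asarray(y, dtype=float)) / self.cell_size)
        return row.astype(np.int64), col.astype(np.int64)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-center coordinates, each of ``shape``."""
        rows, cols = self.shape
        xs = self.x_origin + (np.arange(cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def contains_xy(self, x, y) -> np.ndarray:
        w, s, e, n = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= w) & (x < e) & (y > s) & (y <= n)

    # -- bookkeeping -------------------------------------------------------

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
            and self.crs == other.crs
        )

    def require_aligned(self, other: "Grid", what: str = "grid") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"{what} is not aligned with the analysis grid "
                f"(shape {other.shape} vs {self.shape}, "
                f"origin ({other.x_origin}, {other.y_origin}) vs "
                f"({self.x_origin}, {self.y_origin}), cell {other.cell_size} "
                f"vs {self.cell_size}, crs {other.crs!r} vs {self.crs!r})"
            )

    def nodata_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.zeros(self.shape, dtype=bool)
        return self.data == self.nodata

    def like(self, data: np.ndarray, nodata=None) -> "Grid":
        """A new grid sharing this grid's georeferencing."""
        return Grid(
            data=data,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            crs=self.crs,
            nodata=nodata,
        )

    def copy(self) -> "Grid":
        return replace(self, data=self.data.copy())


@dataclass
class Mask:
    """Binary 0/1 raster with rule provenance.

    ``grid.data`` holds uint8 values in {0, 1} plus the nodata sentinel 255.
    ``provenance`` lists the identifiers of the rules/sources that built it.
    """

    grid: Grid
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        data = np.asarray(self.grid.data)
        valid = np.isin(data, (0, 1, MASK_NODATA))
        if not valid.all():
            bad = np.unique(data[~valid])
            raise ValueError(f"mask values must be 0/1/{MASK_NODATA}, found {bad}")
        self.grid = replace(self.grid, data=data.astype(np.uint8), nodata=MASK_NODATA)

    @classmethod
    def from_bool(cls, template: Grid, values: np.ndarray, provenance=()) -> "Mask":
        data = np.asarray(values, dtype=bool).astype(np.uint8)
        return cls(grid=template.like(data, nodata=MASK_NODATA), provenance=list(provenance))

    @classmethod
    def zeros(cls, template: Grid, provenance=()) -> "Mask":
        return cls.from_bool(template, np.zeros(template.shape, dtype=bool), provenance)

    @property
    def values(self) -> np.ndarray:
        """Boolean view; nodata cells read as False."""
        return self.grid.data == 1

    @property
    def cell_count(self) -> int:
        return int(self.values.sum())

    def area_km2(self) -> float:
        return self.cell_count * self.grid.cell_area_km2

    def __invert__(self) -> "Mask":
        inv = np.where(
            self.grid.data == MASK_NODATA, MASK_NODATA, 1 - self.grid.data
        ).astype(np.uint8)
        return Mask(grid=self.grid.like(inv, nodata=MASK_NODATA),
                    provenance=[f"not({p})" for p in self.provenance] or ["not"])
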