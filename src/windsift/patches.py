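"""Patch labeling and the small-isolated-patch filter.

Scattered slivers of disturbance cannot host a wind facility.  Following the
footprint analysis convention, a connected patch of candidate cells is
removed when it is both smaller than a minimum area (1 km² by default) and
farther than a maximum distance (800 m by default) from any patch that meets
the minimum area.  Patches at or above the minimum area are always kept, and
a sub-minimum patch close enough to an anchor patch is kept as well.

Distances are minimum Euclidean distances between cell centers on the
projected grid.  Connectivity defaults to 8 (edge or corner adjacency).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid, Mask

__all__ = ["label_patches", "filter_small_isolated"]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def label_patches(mask: Mask, connectivity: int = 8) -> tuple[Grid, pd.DataFrame]:
    """Label maximal connected components of a binary mask.

    Returns a grid of integer patch ids (background 0, patches numbered from
    1) and a patch table with ``patch_id``, ``cell_count`` and ``area_km2``
    columns.
    """
    labels, n = ndimage.label(mask.values, structure=_structure(connectivity))
    cell_area = mask.grid.cell_area_km2
    if n:
        counts = np.bincount(labels.ravel())[1:]
    else:
        counts = np.empty(0, dtype=int)
    table = pd.DataFrame(
        {
            "patch_id": np.arange(1, n + 1),
            "cell_count": counts.astype(int),
            "area_km2": counts * cell_area,
        }
    )
    return mask.grid.like(labels.astype(np.int32), nodata=None), table


def filter_small_isolated(
    mask: Mask,
    min_area_km2: float = 1.0,
    max_distance_m: float = 800.0,
    connectivity: int = 8,
) -> Mask:
    """Drop patches smaller than ``min_area_km2`` that sit farther than
    ``max_distance_m`` from every patch meeting the minimum area.

    The operation is idempotent and only ever removes cells.  If no patch
    meets the minimum area, every patch is removed.
    """
    if min_area_km2 <= 0:
        raise ValueError("min_area_km2 must be positive")
    if max_distance_m < 0:
        raise ValueError("max_distance_m must be non-negative")
    label_grid, table = label_patches(mask, connectivity)
    labels = label_grid.data
    if table.empty:
        return Mask.from_bool(mask.grid, np.zeros(mask.grid.shape, dtype=bool),
                              mask.provenance + ["patch_filter"])
    large_ids = table.loc[table["area_km2"] >= min_area_km2, "patch_id"].to_numpy()
    large = np.isin(labels, large_ids)
    keep = large.copy()
    small_ids = table.loc[table["area_km2"] < min_area_km2, "patch_id"].to_numpy()
    if small_ids.size and large.any() and np.isfinite(max_distance_m):
        # distance from each cell center to the nearest large-patch cell center
        dist = ndimage.distance_transform_edt(
            ~large, sampling=(mask.grid.cell_size, mask.grid.cell_size)
        )
        near = dist <= max_distance_m
        for pid in small_ids:
            cells = labels == pid
            if near[cells].any():
                keep |= cells
    elif small_ids.size and large.any() and not np.isfinite(max_distance_m):
        keep = labels > 0
    return Mask.from_bool(mask.grid, keep, mask.provenance + ["patch_filter"])
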