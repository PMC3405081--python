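"""Audit turbine locations against the low-impact surface.

Existing and proposed turbine points are sampled against the low-impact
mask (half-open cell convention: a cell owns its top-left edge) and
summarized per region and status, mirroring the share of turbines that fall
inside low-impact disturbed lands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capacity import round_half_away
from .features import FeatureSet
from .grid import Mask

__all__ = [
    "TurbineSummary",
    "classify_turbines",
    "summarize_turbines",
    "summarize_turbine_counts",
]

log = logging.getLogger(__name__)


@dataclass
class TurbineSummary:
    region: str
    status: str
    n_turbines: int
    n_low_impact: int
    pct_low_impact: int


def classify_turbines(turbines: FeatureSet, low_impact: Mask) -> FeatureSet:
    """Tag each turbine point with ``in_low_impact``.

    A turbine inherits the value of the mask cell containing it.  Points
    outside the grid are kept, flagged ``in_low_impact = False`` and
    ``out_of_bounds = True``, and a warning is issued.
    """
    if turbines.kind != "point":
        raise TypeError("turbines must be a point layer")
    out_geoms, out_attrs = [], []
    grid = low_impact.grid
    values = low_impact.values
    rows_n, cols_n = grid.shape
    n_oob = 0
    for geom, attrs in turbines:
        r, c = grid.xy_to_rowcol(geom.x, geom.y)
        attrs = dict(attrs)
        if 0 <= r < rows_n and 0 <= c < cols_n:
            attrs["in_low_impact"] = bool(values[int(r), int(c)])
            attrs["out_of_bounds"] = False
        else:
            attrs["in_low_impact"] = False
            attrs["out_of_bounds"] = True
            n_oob += 1
        out_geoms.append(geom)
        out_attrs.append(attrs)
    if n_oob:
        msg = f"{n_oob} turbine(s) fall outside the analysis grid"
        warnings.warn(msg, stacklevel=2)
        log.warning(msg)
    return FeatureSet(kind="point", geometries=out_geoms, attributes=out_attrs)


def summarize_turbines(classified: FeatureSet) -> pd.DataFrame:
    """Counts and integer percentages per (region, status), plus Total rows.

    Total rows sum raw counts per status before computing the percentage.
    """
    records = []
    for _, attrs in classified:
        if "region" not in attrs or "status" not in attrs:
            raise KeyError("every turbine needs 'region' and 'status' attributes")
        records.append(
            (attrs["region"], attrs["status"], bool(attrs.get("in_low_impact")))
        )
    df = pd.DataFrame(records, columns=["region", "status", "in_low_impact"])
    rows: list[TurbineSummary] = []
    if not df.empty:
        grouped = df.groupby(["region", "status"], sort=True)
        for (region, status), grp in grouped:
            n = len(grp)
            n_li = int(grp["in_low_impact"].sum())
            rows.append(
                TurbineSummary(region, status, n, n_li,
                               round_half_away(100.0 * n_li / n) if n else 0)
            )
        for status, grp in df.groupby("status", sort=True):
            n = len(grp)
            n_li = int(grp["in_low_impact"].sum())
            rows.append(
                TurbineSummary("Total", status, n, n_li,
                               round_half_away(100.0 * n_li / n) if n else 0)
            )
    return pd.DataFrame(
        {
            "region": [r.region for r in rows],
            "status": [r.status for r in rows],
            "n_turbines": [r.n_turbines for r in rows],
            "n_low_impact": [r.n_low_impact for r in rows],
            "pct_low_impact": [r.pct_low_impact for r in rows],
        }
    )


def summarize_turbine_counts(
    counts: pd.DataFrame,
) -> pd.DataFrame:
    """Summarize from a pre-tabulated counts table.

    ``counts`` needs columns ``region``, ``status``, ``n_turbines`` and
    ``n_low_impact``; useful when auditing published counts rather than
    point data.
    """
    rows = []
    for _, rec in counts.iterrows():
        n, n_li = int(rec["n_turbines"]), int(rec["n_low_impact"])
        rows.append(
            TurbineSummary(rec["region"], rec["status"], n, n_li,
                           round_half_away(100.0 * n_li / n) if n else 0)
        )
    for status, grp in counts.groupby("status", sort=True):
        n = int(grp["n_turbines"].sum())
        n_li = int(grp["n_low_impact"].sum())
        rows.append(
            TurbineSummary("Total", status, n, n_li,
                           round_half_away(100.0 * n_li / n) if n else 0)
        )
    return pd.DataFrame(
        {
            "region": [r.region for r in rows],
            "status": [r.status for r in rows],
            "n_turbines": [r.n_turbines for r in rows],
            "n_low_impact": [r.n_low_impact for r in rows],
            "pct_low_impact": [r.pct_low_impact for r in rows],
        }
    )
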