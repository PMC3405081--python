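"""Published reference tables for the Northern Great Plains study region.

Two small tables ship with the package:

* regional wind development goals (GW) alongside the reported installable
  capacity (GW) on low-impact disturbed lands, for the seven NGP
  jurisdictions (Alberta, Saskatchewan, Montana, Nebraska, North Dakota,
  South Dakota, Wyoming);
* counts of existing and proposed turbines per jurisdiction, with the number
  falling inside the identified low-impact areas.

They serve as inputs for re-deriving the percent-of-goal and turbine-share
summaries, and as worked-example data in the documentation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_ngp_goals_capacity", "load_ngp_turbine_counts"]


def _read(name: str) -> pd.DataFrame:
    path = resources.files("windsift") / "data" / name
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_ngp_goals_capacity() -> pd.DataFrame:
    """Per-jurisdiction development goals and low-impact capacity (GW)."""
    return _read("ngp_goals_capacity.csv")


def load_ngp_turbine_counts() -> pd.DataFrame:
    """Per-jurisdiction turbine counts by status, with low-impact counts."""
    return _read("ngp_turbine_counts.csv")
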