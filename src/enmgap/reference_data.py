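"""Packaged published tables for Sri Lankan Memecylon.

``habitat_extents`` holds the per-species suitable-habitat extents (km²)
under the current climate and 12 future scenarios (two GCMs, B =
BCC-CSM1-1 and M = MIROC5; RCPs 2.6/4.5/8.5; 2050 and 2070) together with
the published integer percent changes, kappa and niche-breadth scores.
``gap_table`` holds the category-level gap-analysis areas (richness area
and extents within protected/forest layers).  These are used as inputs to
the desk-reproducible arithmetic checks; empty cells mark categories with
total habitat loss (not applicable).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

SCENARIOS = tuple(
    f"{gcm}{rcp}_{year}"
    for year in ("2050", "2070")
    for gcm in ("B", "M")
    for rcp in ("26", "45", "85")
)


def _data_path(name: str):
    return resources.files("enmgap.data").joinpath(name)


def habitat_extents() -> pd.DataFrame:
    with resources.as_file(_data_path("memecylon_habitat_extents.csv")) as p:
        return pd.read_csv(p)


def gap_table() -> pd.DataFrame:
    with resources.as_file(_data_path("memecylon_gap_table.csv")) as p:
        return pd.read_csv(p)


def default_category_overrides() -> dict[str, str]:
    with resources.as_file(_data_path("category_overrides.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh) or {}
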