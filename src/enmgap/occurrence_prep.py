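"""Occurrence cleaning: dedupe, missing-environment drop, one-per-cell
thinning, and minimum-sample filters, with full attrition bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geodata_io import ClimateStack, OCCURRENCE_COLUMNS

__all__ = ["CleaningReport", "clean_occurrences"]

COORD_DECIMALS = 6  # GPS precision; exact-duplicate test applies after rounding


@dataclass
class CleaningReport:
    n_input: int = 0
    n_after_dedupe: int = 0
    n_missing_env_removed: int = 0
    n_same_cell_removed: int = 0
    species_dropped: list[dict] = field(default_factory=list)
    n_final: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def check(self) -> None:
        """Raise if the attrition arithmetic is inconsistent."""
        n_dropped_species_records = sum(d["n_records"] for d in self.species_dropped)
        expected_final = (
            self.n_after_dedupe
            - self.n_missing_env_removed
            - self.n_same_cell_removed
            - n_dropped_species_records
        )
        if expected_final != self.n_final:
            raise AssertionError(
                f"cleaning report inconsistent: expected n_final {expected_final}, got {self.n_final}"
            )


def clean_occurrences(
    occ: pd.DataFrame,
    stack: ClimateStack,
    min_count: int = 10,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Clean an occurrence table against a climate stack.

    Steps, in order, each reported: (1) collapse exact duplicates of
    (species, lon, lat) after rounding coordinates to 6 decimals; (2) drop
    records off-grid or on cells missing any climate layer; (3) keep at
    most one record per raster cell per species (first-seen wins); (4) drop
    whole species left with fewer than ``min_count`` distinct cells
    (reason ``min-count``) or with all records in one cell (reason
    ``single-location``).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    report = CleaningReport(n_input=len(occ))
    if len(occ) == 0:
        out = pd.DataFrame(columns=OCCURRENCE_COLUMNS)
        report.check()
        return out, report

    df = occ.copy().reset_index(drop=True)
    df["lon"] = df["lon"].round(COORD_DECIMALS)
    df["lat"] = df["lat"].round(COORD_DECIMALS)

    # 1. exact duplicates
    df = df.drop_duplicates(subset=["species", "lon", "lat"], keep="first")
    report.n_after_dedupe = len(df)

    # 2. records without environmental data
    valid = stack.valid_mask()
    rows, cols = stack.grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    on_grid = rows >= 0
    has_env = on_grid.copy()
    has_env[on_grid] = valid[rows[on_grid], cols[on_grid]]
    report.n_missing_env_removed = int((~has_env).sum())
    df = df.loc[has_env].copy()
    df["_cell"] = rows[has_env] * stack.grid.n_cols + cols[has_env]

    # 3. one record per cell per species (first-seen kept)
    before = len(df)
    df = df.drop_duplicates(subset=["species", "_cell"], keep="first")
    report.n_same_cell_removed = before - len(df)

    # 4. whole-species filters on distinct-cell counts
    keep_frames = []
    for species, grp in df.groupby("species", sort=False):
        n_cells = grp["_cell"].nunique()
        if n_cells == 1:
            report.species_dropped.append(
                {"species": species, "reason": "single-location", "n_records": len(grp)}
            )
        elif n_cells < min_count:
            report.species_dropped.append(
                {"species": species, "reason": "min-count", "n_records": len(grp)}
            )
        else:
            keep_frames.append(grp)
    if keep_frames:
        out = pd.concat(keep_frames).drop(columns="_cell").reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=OCCURRENCE_COLUMNS)
    report.n_final = len(out)
    report.check()
    return out, report
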