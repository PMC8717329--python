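"""Calibration areas (great-circle buffers) and collinearity filtering."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata_io import ClimateStack, RasterGrid, haversine_km

__all__ = [
    "CalibrationArea",
    "CorrelationMatrix",
    "RetainedVariables",
    "buffer_mask",
    "pearson_matrix",
    "filter_collinear",
]


@dataclass
class CalibrationArea:
    species: str
    mask: np.ndarray
    buffer_km: float


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray  # symmetric, diag 1; NaN marks undefined (zero variance)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variables)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")


@dataclass
class RetainedVariables:
    species: str
    kept: list[str]
    dropped: list[dict] = field(default_factory=list)  # name, trigger partner, |r|


def buffer_mask(
    occ: pd.DataFrame,
    grid: RasterGrid,
    buffer_km: float = 100.0,
    valid: np.ndarray | None = None,
    species: str = "",
) -> CalibrationArea:
    """Cells whose centers lie within ``buffer_km`` (haversine) of any
    occurrence.  ``valid`` (e.g. land/has-climate mask) excludes sea and
    nodata cells; occurrence cells themselves are always included."""
    if len(occ) == 0:
        raise ValueError("buffer_mask requires at least one occurrence")
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    lon2, lat2 = np.meshgrid(lon_c, lat_c)
    dmin = np.full(grid.shape, np.inf)
    for lon, lat in zip(occ["lon"].to_numpy(), occ["lat"].to_numpy()):
        d = haversine_km(lon, lat, lon2, lat2)
        np.minimum(dmin, d, out=dmin)
    mask = dmin <= buffer_km
    # the occurrence's own cell is inside even at buffer 0 (distance to its
    # center can exceed 0 for off-center points)
    rows, cols = grid.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    ok = rows >= 0
    mask[rows[ok], cols[ok]] = True
    if valid is not None:
        mask &= valid
    if not mask.any():
        raise ValueError("calibration mask is empty")
    return CalibrationArea(species=species, mask=mask, buffer_km=buffer_km)


def pearson_matrix(
    stack: ClimateStack,
    mask: np.ndarray,
    names: list[str] | None = None,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations over masked cells.

    Zero-variance layers yield NaN entries (treated as |r| = 1 by the
    collinearity filter, conservatively).
    """
    names = stack.names if names is None else names
    table = stack.env_table(mask, names)
    if len(table.dropna()) < 3:
        raise ValueError("need at least 3 valid cells to estimate correlations")
    r = table.corr(method="pearson", min_periods=2).to_numpy()
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables=list(names), r=r)


def filter_collinear(
    cm: CorrelationMatrix,
    threshold: float = 0.65,
    species: str = "",
) -> RetainedVariables:
    """Greedy elimination: while any surviving pair violates
    ``|r| > threshold``, drop — among variables in violating pairs — the
    one with the largest mean absolute correlation to the other survivors
    (ties broken by candidate order).  NaN correlations count as |r| = 1.
    """
    names = list(cm.variables)
    absr = np.abs(cm.r.copy())
    absr[np.isnan(absr)] = 1.0
    np.fill_diagonal(absr, 0.0)

    alive = list(range(len(names)))
    dropped: list[dict] = []
    while True:
        sub = absr[np.ix_(alive, alive)]
        np.fill_diagonal(sub, 0.0)
        if sub.size == 0 or sub.max() <= threshold:
            break
        violators = sorted({i for k, i in enumerate(alive) if (sub[k] > threshold).any()})
        mean_abs = {
            i: absr[i, [j for j in alive if j != i]].mean() if len(alive) > 1 else 0.0
            for i in violators
        }
        worst = max(violators, key=lambda i: (mean_abs[i], -i))
        # trigger partner: the surviving variable it correlates most with
        partners = [j for j in alive if j != worst]
        trig = max(partners, key=lambda j: absr[worst, j])
        dropped.append(
            {"name": names[worst], "partner": names[trig], "abs_r": float(absr[worst, trig])}
        )
        alive.remove(worst)
    return RetainedVariables(
        species=species, kept=[names[i] for i in alive], dropped=dropped
    )
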