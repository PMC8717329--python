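"""Protected-area / forest-cover gap analysis over category richness areas.

Reported one-decimal percentages are truncated, not rounded: published
gap-analysis tables in this domain print 46.38% as 46.3, and truncation
reproduces them consistently where half-up rounding does not.  The raw
ratio is always carried alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .endemism_richness import richness_area

__all__ = ["GapRow", "overlay_extent", "gap_percent", "gap_report", "recommendation_map"]


@dataclass
class GapRow:
    category: str
    period: str
    richness_area_km2: float
    extent_all_protected_km2: float | None
    extent_conservation_forest_km2: float | None
    extent_forest_km2: float | None  # current period only
    not_applicable: bool = False

    def percent(self, which: str) -> float | None:
        """Truncated one-decimal percent of an extent over the richness area."""
        extent = getattr(self, f"extent_{which}_km2")
        if self.not_applicable or extent is None or self.richness_area_km2 <= 0:
            return None
        return gap_percent(extent, self.richness_area_km2)

    def percent_raw(self, which: str) -> float | None:
        extent = getattr(self, f"extent_{which}_km2")
        if self.not_applicable or extent is None or self.richness_area_km2 <= 0:
            return None
        return 100.0 * extent / self.richness_area_km2


def gap_percent(extent_km2: float, richness_km2: float, decimals: int = 1) -> float:
    """Percent of richness area covered, truncated to ``decimals`` places."""
    if richness_km2 <= 0:
        raise ValueError("richness area must be positive")
    scale = 10.0**decimals
    return math.floor(100.0 * extent_km2 / richness_km2 * scale) / scale


def overlay_extent(richness_mask: np.ndarray, layer_mask: np.ndarray, areas: np.ndarray) -> float:
    """km² of richness cells intersecting the layer mask."""
    sel = np.asarray(richness_mask, dtype=bool) & np.asarray(layer_mask, dtype=bool)
    return float(np.sum(np.where(sel, areas, 0.0)))


def _richness_mask(counts: np.ndarray, level="max") -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    finite = np.isfinite(counts)
    if not finite.any():
        return np.zeros(counts.shape, dtype=bool)
    if level == "max":
        mx = np.nanmax(counts)
        return finite & (counts == mx) & (counts > 0)
    return finite & (counts >= float(level))


def gap_report(
    category_counts: dict[str, np.ndarray],
    protected_all: np.ndarray,
    protected_conservation_forest: np.ndarray,
    forest: np.ndarray | None,
    areas: np.ndarray,
    period: str = "current",
    level="max",
) -> list[GapRow]:
    """One row per category: richness area and extents inside the protected
    and forest layers.

    Future periods pass ``forest=None`` (forest change is not modeled) and
    reuse the current protected layers.  A category with no richness cells
    in the period is flagged not-applicable.
    """
    rows = []
    for category, counts in category_counts.items():
        mask = _richness_mask(counts, level)
        r_area = richness_area(counts, areas, level)
        if r_area <= 0 or not mask.any():
            rows.append(GapRow(category, period, 0.0, None, None, None, not_applicable=True))
            continue
        rows.append(
            GapRow(
                category=category,
                period=period,
                richness_area_km2=r_area,
                extent_all_protected_km2=overlay_extent(mask, protected_all, areas),
                extent_conservation_forest_km2=overlay_extent(
                    mask, protected_conservation_forest, areas
                ),
                extent_forest_km2=(
                    overlay_extent(mask, forest, areas) if forest is not None else None
                ),
            )
        )
    return rows


def recommendation_map(
    high_confidence_richness: list[np.ndarray],
    dry_zone_richness: np.ndarray | None,
    forest_mask: np.ndarray,
    protected_mask: np.ndarray,
) -> np.ndarray:
    """Unprotected forest worth conserving: cells in any category's
    high-confidence richness (or the dry-zone category's richness band)
    that are forested and not protected."""
    target = np.zeros(np.asarray(forest_mask).shape, dtype=bool)
    for m in high_confidence_richness:
        target |= np.asarray(m, dtype=bool)
    if dry_zone_richness is not None:
        target |= np.asarray(dry_zone_richness, dtype=bool)
    flag = target & np.asarray(forest_mask, dtype=bool) & ~np.asarray(protected_mask, dtype=bool)
    return flag.astype(np.uint8)
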