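"""Endemism categories, stacked richness, and tri-state uncertainty maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CATEGORIES",
    "SpeciesProfile",
    "CategoryLabel",
    "UnresolvedCategoryError",
    "classify",
    "stack_richness",
    "richness_area",
    "uncertainty",
    "UNCERTAINTY_CODES",
]

CATEGORIES = (
    "wide_endemic",
    "narrow_endemic_lowland",
    "narrow_endemic_montane",
    "nonendemic_dry",
    "nonendemic_wet",
)

# area (km^2) and niche-breadth cutoffs for the endemic split; the
# comparisons are inclusive so published borderline profiles (e.g. breadth
# exactly 0.5) classify as wide
AREA_CUTOFF_KM2 = 10_000.0
BREADTH_CUTOFF = 0.5
MONTANE_ELEVATION_M = 300.0

UNCERTAINTY_CODES = {"absent": 0, "mixed": 1, "always": 2}


class UnresolvedCategoryError(ValueError):
    """Profile does not satisfy any rule; an explicit override is needed."""


@dataclass(frozen=True)
class SpeciesProfile:
    species: str
    endemic: bool
    current_area_km2: float
    breadth: float
    occ_elevations_m: tuple[float, ...] = ()
    zone_overlap: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zone_overlap:
            total = sum(self.zone_overlap.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"zone overlaps must sum to 1, got {total}")


@dataclass(frozen=True)
class CategoryLabel:
    label: str
    rule_trace: str
    overridden: bool = False

    def __post_init__(self) -> None:
        if self.label not in CATEGORIES:
            raise ValueError(f"unknown category {self.label!r}")
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")


def classify(
    profile: SpeciesProfile,
    overrides: Mapping[str, str] | None = None,
) -> CategoryLabel:
    """Assign the five-way endemism/zone category.

    Rule order: explicit override; endemic wide (area >= 10,000 km² and
    breadth >= 0.5); endemic narrow (area < 10,000 and breadth < 0.5),
    montane iff the minimum occurrence elevation exceeds 300 m; endemics
    matching neither rule raise :class:`UnresolvedCategoryError`.
    Nonendemics go to the zone holding their largest suitable-area
    fraction (wet -> wet, dry or arid -> dry); intermediate-dominant or
    tied profiles raise for an override.
    """
    if overrides and profile.species in overrides:
        return CategoryLabel(
            label=overrides[profile.species],
            rule_trace=f"override({profile.species})",
            overridden=True,
        )
    a, b = profile.current_area_km2, profile.breadth
    if profile.endemic:
        if a >= AREA_CUTOFF_KM2 and b >= BREADTH_CUTOFF:
            return CategoryLabel("wide_endemic", f"endemic; area {a:.0f} >= 10000; breadth {b:.2f} >= 0.5")
        if a < AREA_CUTOFF_KM2 and b < BREADTH_CUTOFF:
            if not profile.occ_elevations_m:
                raise UnresolvedCategoryError(
                    f"{profile.species}: narrow endemic needs occurrence elevations"
                )
            min_elev = min(profile.occ_elevations_m)
            if min_elev > MONTANE_ELEVATION_M:
                return CategoryLabel(
                    "narrow_endemic_montane",
                    f"endemic; area {a:.0f} < 10000; breadth {b:.2f} < 0.5; min elev {min_elev:.0f} > 300",
                )
            return CategoryLabel(
                "narrow_endemic_lowland",
                f"endemic; area {a:.0f} < 10000; breadth {b:.2f} < 0.5; min elev {min_elev:.0f} <= 300",
            )
        raise UnresolvedCategoryError(
            f"{profile.species}: endemic profile (area {a:.0f}, breadth {b:.2f}) "
            "matches neither wide nor narrow rule; supply an override"
        )
    # nonendemic: dominant climate-zone overlap decides
    if not profile.zone_overlap:
        raise UnresolvedCategoryError(f"{profile.species}: nonendemic needs zone overlaps")
    wet = profile.zone_overlap.get("wet", 0.0)
    dry = profile.zone_overlap.get("dry", 0.0) + profile.zone_overlap.get("arid", 0.0)
    inter = profile.zone_overlap.get("intermediate", 0.0)
    if wet > dry and wet >= inter:
        return CategoryLabel("nonendemic_wet", f"nonendemic; wet overlap {wet:.2f} dominant")
    if dry > wet and dry >= inter:
        return CategoryLabel("nonendemic_dry", f"nonendemic; dry/arid overlap {dry:.2f} dominant")
    raise UnresolvedCategoryError(
        f"{profile.species}: zone overlaps tied or intermediate-dominant "
        f"(wet {wet:.2f}, dry {dry:.2f}, intermediate {inter:.2f}); supply an override"
    )


def stack_richness(member_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Cell-wise species count from member binary maps (NaN-aware: a cell
    is NaN only where every member is NaN)."""
    if not len(member_maps):
        raise ValueError("at least one member map required")
    stacked = np.stack([np.asarray(m, dtype=float) for m in member_maps])
    counts = np.nansum(np.where(stacked == 1.0, 1.0, 0.0), axis=0)
    all_nan = np.all(~np.isfinite(stacked), axis=0)
    counts[all_nan] = np.nan
    return counts


def richness_area(counts: np.ndarray, areas: np.ndarray, level="max") -> float:
    """km² of richness cells.

    ``level="max"`` (the reporting default) takes cells attaining the map's
    maximum count; an integer level takes cells with count >= level.
    """
    counts = np.asarray(counts, dtype=float)
    finite = np.isfinite(counts)
    if not finite.any():
        return 0.0
    if level == "max":
        max_count = np.nanmax(counts)
        if max_count <= 0:
            return 0.0
        sel = finite & (counts == max_count)
    else:
        sel = finite & (counts >= float(level))
    return float(np.sum(np.where(sel, areas, 0.0)))


def uncertainty(replicate_maps_per_member: Sequence[Sequence[np.ndarray]]) -> np.ndarray:
    """Tri-state agreement raster across members and replicates.

    ``always`` (2): every replicate of every member predicts presence;
    ``mixed`` (1): not always, but each member has at least one replicate
    predicting presence; ``absent`` (0): some member is never predicted
    present.  NaN where no member has data.
    """
    if not len(replicate_maps_per_member):
        raise ValueError("at least one member required")
    member_all = []
    member_any = []
    any_data = None
    for reps in replicate_maps_per_member:
        stacked = np.stack([np.asarray(r, dtype=float) for r in reps])
        pres = stacked == 1.0
        valid = np.isfinite(stacked)
        member_all.append(np.all(pres | ~valid, axis=0) & valid.any(axis=0))
        member_any.append(np.any(pres, axis=0))
        has = valid.any(axis=0)
        any_data = has if any_data is None else (any_data | has)
    all_always = np.logical_and.reduce(member_all)
    all_any = np.logical_and.reduce(member_any)
    out = np.zeros(all_always.shape, dtype=float)
    out[all_any] = UNCERTAINTY_CODES["mixed"]
    out[all_always] = UNCERTAINTY_CODES["always"]
    out[~any_data] = np.nan
    return out
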