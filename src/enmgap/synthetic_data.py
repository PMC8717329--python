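"""Synthetic island world: climate stack, virtual species, scenarios, layers.

Everything downstream of the pipeline is exercised against this generator,
so it is deterministic given a single integer seed and produces the same
formats the real-data path consumes (ASCII rasters, GeoJSON polygons,
occurrence CSVs).

Only a physically consistent subset of the 19 bioclim-style layers is
derived from elevation and the west-east rainfall gradient (bio1, bio4,
bio5, bio6, bio7 = bio5 - bio6, bio12, bio13); the remaining layers are
correlated noise fields so that the collinearity filter has structure to
chew on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Point

from .geodata_io import (
    ClimateStack,
    PolygonLayer,
    RasterGrid,
    cell_area_km2,
    make_occurrences,
    rasterize,
)

__all__ = [
    "IslandSpec",
    "VirtualSpecies",
    "ScenarioDelta",
    "TEMPERATURE_SHIFT_LAYERS",
    "PRECIPITATION_LAYERS",
    "make_island_climate",
    "apply_scenario",
    "true_suitability",
    "sample_occurrences",
    "make_conservation_layers",
    "zone_from_precip",
    "ZONE_CODES",
]

#: Absolute-temperature layers that shift additively under warming.
TEMPERATURE_SHIFT_LAYERS = ("bio1", "bio5", "bio6", "bio8", "bio9", "bio10", "bio11")
#: Precipitation layers that scale multiplicatively.
PRECIPITATION_LAYERS = tuple(f"bio{i}" for i in range(12, 20))

ZONE_CODES = {"wet": 1, "intermediate": 2, "dry": 3, "arid": 4}

LAPSE_C_PER_KM = 6.5


@dataclass(frozen=True)
class IslandSpec:
    n_rows: int = 120
    n_cols: int = 150
    resolution: float = 1 / 120.0
    seed: int = 0
    x_origin: float = 79.5
    y_origin: float = 7.5
    elevation_peaks: tuple[tuple[int, int, float, float], ...] = (
        (70, 60, 2400.0, 18.0),
        (45, 90, 1500.0, 14.0),
        (85, 95, 900.0, 16.0),
    )
    coast_threshold: float = 25.0
    arid_cutoff_mm: float = 1200.0

    def __post_init__(self) -> None:
        if not self.elevation_peaks:
            raise ValueError("at least one elevation peak required")
        if any(p[2] <= 0 for p in self.elevation_peaks):
            raise ValueError("peak heights must be positive")

    def grid(self) -> RasterGrid:
        return RasterGrid(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            resolution=self.resolution,
        )


@dataclass(frozen=True)
class VirtualSpecies:
    """Known logistic response on standardized climate layers."""

    name: str
    response: Mapping[str, tuple[float, float]]  # layer -> (linear, quadratic)
    intercept: float = 0.0
    prevalence_target: float = 0.15
    endemic: bool = True
    #: intended endemism category; exported as a pipeline override so the
    #: synthetic world classifies deterministically even when the emergent
    #: breadth of a fitted map sits on the rule boundary
    category: str | None = None

    def __post_init__(self) -> None:
        if not any(a != 0 or b != 0 for a, b in self.response.values()):
            raise ValueError("at least one nonzero response coefficient required")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must be in (0, 1)")


@dataclass(frozen=True)
class ScenarioDelta:
    """Additive temperature shift (°C) and multiplicative precipitation scale."""

    label: str
    temp_shift: float = 0.0
    precip_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.precip_scale <= 0:
            raise ValueError("precip_scale must be positive")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated Gaussian field."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _elevation(spec: IslandSpec, rng: np.random.Generator) -> np.ndarray:
    rows = np.arange(spec.n_rows)[:, None]
    cols = np.arange(spec.n_cols)[None, :]
    elev = np.zeros((spec.n_rows, spec.n_cols))
    for r0, c0, height, decay in spec.elevation_peaks:
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        elev += height * np.exp(-d2 / (2.0 * decay**2))
    # broad island platform so the coastline is not a disc around one peak
    cy, cx = (spec.n_rows - 1) / 2.0, (spec.n_cols - 1) / 2.0
    rad = np.sqrt(((rows - cy) / (0.55 * spec.n_rows)) ** 2 + ((cols - cx) / (0.55 * spec.n_cols)) ** 2)
    elev += 220.0 * np.clip(1.0 - rad, -1.0, 1.0)
    elev += 40.0 * _smooth_noise(rng, (spec.n_rows, spec.n_cols), sigma=4.0)
    return elev


def zone_from_precip(annual_precip: np.ndarray, arid_cutoff_mm: float = 1200.0) -> np.ndarray:
    """Climate zones from annual precipitation: wet > 2500 mm, intermediate
    1750-2500 mm, dry < 1750 mm, with an arid subdivision below the cutoff.

    Returns an integer raster using :data:`ZONE_CODES`; NaN precip -> 0.
    """
    zones = np.zeros(annual_precip.shape, dtype=np.uint8)
    valid = np.isfinite(annual_precip)
    p = annual_precip
    zones[valid & (p > 2500)] = ZONE_CODES["wet"]
    zones[valid & (p <= 2500) & (p >= 1750)] = ZONE_CODES["intermediate"]
    zones[valid & (p < 1750) & (p >= arid_cutoff_mm)] = ZONE_CODES["dry"]
    zones[valid & (p < arid_cutoff_mm)] = ZONE_CODES["arid"]
    return zones


def make_island_climate(spec: IslandSpec) -> tuple[ClimateStack, np.ndarray, np.ndarray]:
    """Generate the island's 19-layer climate stack.

    Returns ``(stack, elevation, zones)``.  Sea cells (elevation below the
    coast threshold) are NaN in every climate layer and in elevation; zones
    are 0 at sea.  Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    shape = grid.shape
    elev = _elevation(spec, rng)
    land = elev >= spec.coast_threshold

    lat = np.repeat(grid.lat_centers()[:, None], grid.n_cols, axis=1)
    lon = np.repeat(grid.lon_centers()[None, :], grid.n_rows, axis=0)

    # temperatures: tropical sea-level baseline minus lapse-rate cooling
    t_noise = _smooth_noise(rng, shape, 5.0)
    bio1 = 27.5 - 0.3 * (lat - lat.mean()) - LAPSE_C_PER_KM * elev / 1000.0 + 0.3 * t_noise
    amp = 6.0 + 1.5 * _smooth_noise(rng, shape, 6.0)  # warm/cold month spread
    bio5 = bio1 + amp / 2.0
    bio6 = bio1 - amp / 2.0
    bio7 = bio5 - bio6
    # seasonality proxy (std x 100 convention)
    bio4 = 100.0 * (0.25 * bio7 + 0.4 + 0.15 * np.abs(_smooth_noise(rng, shape, 6.0)))

    # precipitation: wet west coast, dry east, orographic bonus
    x01 = (lon - lon.min()) / (lon.max() - lon.min())
    p_noise = _smooth_noise(rng, shape, 5.0)
    bio12 = 3600.0 - 2800.0 * x01 + 0.55 * elev + 180.0 * p_noise
    bio12 = np.clip(bio12, 600.0, None)
    bio13 = bio12 * (0.28 + 0.03 * _smooth_noise(rng, shape, 5.0))

    layers: dict[str, np.ndarray] = {
        "bio1": bio1,
        "bio4": bio4,
        "bio5": bio5,
        "bio6": bio6,
        "bio7": bio7,
        "bio12": bio12,
        "bio13": bio13,
    }
    # bio3 (isothermality) kept consistent with its definition
    layers["bio2"] = 0.75 * amp + 0.5 * np.abs(_smooth_noise(rng, shape, 6.0))
    layers["bio3"] = layers["bio2"] / bio7 * 100.0

    # remaining temperature-type layers: bio1 plus correlated structure
    for name, w in (("bio8", 0.6), ("bio9", 0.8), ("bio10", 0.9), ("bio11", 0.7)):
        layers[name] = w * bio1 + (1 - w) * (25.0 + 2.0 * _smooth_noise(rng, shape, 5.0))
    # remaining precipitation-type layers: mixtures of bio12 and noise
    for name, w in (("bio14", 0.35), ("bio15", 0.4), ("bio16", 0.85), ("bio17", 0.5), ("bio18", 0.6), ("bio19", 0.65)):
        base = w * (bio12 / bio12[np.isfinite(bio12)].mean()) + (1 - w) * (1.0 + 0.4 * _smooth_noise(rng, shape, 5.0))
        scale = {"bio14": 60.0, "bio15": 55.0, "bio16": 1100.0, "bio17": 280.0, "bio18": 520.0, "bio19": 640.0}[name]
        layers[name] = np.clip(base, 0.05, None) * scale

    zones = zone_from_precip(np.where(land, bio12, np.nan), spec.arid_cutoff_mm)
    sea = ~land
    for name in list(layers):
        arr = np.asarray(layers[name], dtype=float).copy()
        arr[sea] = np.nan
        layers[name] = arr
    elev_out = np.where(land, elev, np.nan)

    ordered = {f"bio{i}": layers[f"bio{i}"] for i in range(1, 20)}
    stack = ClimateStack(grid=grid, layers=ordered, period_label="current")
    return stack, elev_out, zones


def apply_scenario(stack: ClimateStack, delta: ScenarioDelta) -> ClimateStack:
    """Shift temperatures, scale precipitation, recompute derived layers."""
    new: dict[str, np.ndarray] = {}
    for name, arr in stack.layers.items():
        if name in TEMPERATURE_SHIFT_LAYERS:
            new[name] = arr + delta.temp_shift
        elif name in PRECIPITATION_LAYERS:
            new[name] = arr * delta.precip_scale
        else:
            new[name] = arr.copy()
    # derived layers stay internally consistent
    if "bio5" in new and "bio6" in new and "bio7" in new:
        new["bio7"] = new["bio5"] - new["bio6"]
    if "bio2" in new and "bio7" in new and "bio3" in new:
        with np.errstate(divide="ignore", invalid="ignore"):
            new["bio3"] = new["bio2"] / new["bio7"] * 100.0
    return ClimateStack(grid=stack.grid, layers=new, period_label=delta.label)


class MissingLayerError(KeyError):
    pass


def _standardized(stack: ClimateStack, names: Sequence[str], land: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for name in names:
        if name not in stack:
            raise MissingLayerError(f"response layer {name!r} not in stack")
        vals = stack[name]
        mu = np.nanmean(vals[land])
        sd = np.nanstd(vals[land])
        out[name] = (vals - mu) / (sd if sd > 0 else 1.0)
    return out


def true_suitability(sp: VirtualSpecies, stack: ClimateStack) -> np.ndarray:
    """Logistic suitability with the intercept tuned so that mean land
    suitability hits ``prevalence_target`` (within 1e-3 via bisection)."""
    land = stack.valid_mask()
    z = _standardized(stack, list(sp.response), land)
    eta = np.zeros(stack.grid.shape)
    for name, (a, b) in sp.response.items():
        eta += a * z[name] + b * z[name] ** 2
    eta_land = eta[land]

    def mean_suit(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(eta_land + c)))))

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_suit(mid) < sp.prevalence_target:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    suit = np.full(stack.grid.shape, np.nan)
    suit[land] = 1.0 / (1.0 + np.exp(-(eta[land] + c)))
    return suit


class SamplingError(ValueError):
    pass


def sample_occurrences(
    truth: np.ndarray,
    grid: RasterGrid,
    n: int,
    seed: int,
    cluster_sd: float = 0.0,
    species: str = "virtual",
):
    """Draw presence records proportional to suitability.

    Cells are drawn (with replacement) with probability proportional to the
    truth raster; ``cluster_sd`` jitters each draw by a Gaussian number of
    cells and snaps back to the nearest valid cell, producing spatially
    clustered records.  Returns an occurrence table of cell-center lon/lat.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.where(np.isfinite(truth), truth, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise SamplingError("truth raster has no positive suitability")
    idx = rng.choice(weights.size, size=n, p=weights / total)
    rows, cols = np.unravel_index(idx, truth.shape)
    if cluster_sd > 0:
        rows = rows + np.round(rng.normal(0, cluster_sd, n)).astype(int)
        cols = cols + np.round(rng.normal(0, cluster_sd, n)).astype(int)
        rows = np.clip(rows, 0, grid.n_rows - 1)
        cols = np.clip(cols, 0, grid.n_cols - 1)
        # snap jittered draws that landed at sea back onto suitable cells
        bad = ~np.isfinite(truth[rows, cols])
        if bad.any():
            repl = rng.choice(weights.size, size=int(bad.sum()), p=weights / total)
            rows[bad], cols[bad] = np.unravel_index(repl, truth.shape)
    lon, lat = grid.cell_center(rows, cols)
    return make_occurrences(
        (species, float(lo), float(la), np.nan, "synthetic") for lo, la in zip(lon, lat)
    )


def default_virtual_species() -> list[VirtualSpecies]:
    """Three contrasting virtual species: a montane endemic (cold-adapted),
    a wet-lowland endemic, and a widespread dry-zone nonendemic."""
    return [
        VirtualSpecies(
            name="montane_endemic",
            response={"bio1": (-2.5, -0.8), "bio12": (0.6, 0.0)},
            prevalence_target=0.08,
            endemic=True,
            category="narrow_endemic_montane",
        ),
        VirtualSpecies(
            name="wet_lowland_endemic",
            response={"bio12": (2.0, -0.6), "bio1": (0.8, -0.4)},
            prevalence_target=0.15,
            endemic=True,
            category="narrow_endemic_lowland",
        ),
        VirtualSpecies(
            name="dry_nonendemic",
            response={"bio12": (-1.8, -0.5), "bio5": (0.7, 0.0)},
            prevalence_target=0.25,
            endemic=False,
            category="nonendemic_dry",
        ),
    ]


def write_world(
    out_dir,
    spec: IslandSpec | None = None,
    seed: int = 0,
    species: Sequence[VirtualSpecies] | None = None,
    n_occurrences: int = 60,
    scenarios: Sequence[ScenarioDelta] | None = None,
):
    """Write a complete synthetic study system to disk, in the formats the
    pipeline consumes: current and scenario raster stacks, elevation and
    zone rasters, protected/forest GeoJSON layers, an occurrence CSV, and a
    ready-to-run pipeline config (``config.yaml``).  Returns the config
    path."""
    from pathlib import Path

    import yaml

    from .geodata_io import write_ascii_grid, write_occurrences, write_polygon_layer
    from .geodata_io import write_raster_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else IslandSpec(seed=seed)
    species = list(species) if species is not None else default_virtual_species()
    scenarios = list(scenarios) if scenarios is not None else [
        ScenarioDelta("M26-2050", temp_shift=1.0, precip_scale=0.95),
        ScenarioDelta("M85-2070", temp_shift=3.0, precip_scale=0.85),
    ]

    stack, elev, zones = make_island_climate(spec)
    write_raster_stack(out / "climate" / "current", stack)
    write_ascii_grid(out / "elevation.asc", stack.grid, elev)
    write_ascii_grid(out / "zones.asc", stack.grid, zones.astype(float))
    for delta in scenarios:
        write_raster_stack(out / "climate" / delta.label, apply_scenario(stack, delta))

    import pandas as pd

    rng = np.random.default_rng(seed)
    tables = []
    for i, sp in enumerate(species):
        truth = true_suitability(sp, stack)
        write_ascii_grid(out / f"truth_{sp.name}.asc", stack.grid, truth)
        occ = sample_occurrences(truth, stack.grid, n_occurrences,
                                 seed=int(rng.integers(2**31)), cluster_sd=1.0,
                                 species=sp.name)
        # attach elevations from the DEM at the sampled cells
        rows, cols = stack.grid.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        occ["elevation"] = elev[rows, cols]
        tables.append(occ)
    write_occurrences(out / "occurrences.csv", pd.concat(tables, ignore_index=True))

    land = stack.valid_mask()
    protected, forest = make_conservation_layers(spec, seed=seed + 1, land=land)
    write_polygon_layer(out / "protected.geojson", protected)
    write_polygon_layer(out / "forest.geojson", forest)

    config = {
        "out_dir": str(out / "results"),
        "occurrences_csv": str(out / "occurrences.csv"),
        "current_stack_dir": str(out / "climate" / "current"),
        "scenario_stack_dirs": {d.label: str(out / "climate" / d.label) for d in scenarios},
        "elevation_raster": str(out / "elevation.asc"),
        "zone_raster": str(out / "zones.asc"),
        "protected_geojson": str(out / "protected.geojson"),
        "forest_geojson": str(out / "forest.geojson"),
        "endemic_species": [sp.name for sp in species if sp.endemic],
        "category_overrides": {
            sp.name: sp.category for sp in species if sp.category is not None
        },
        "seed": seed,
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh)
    return cfg_path


def _random_blobs(
    rng: np.random.Generator,
    grid: RasterGrid,
    land: np.ndarray,
    n_blobs: int,
    radius_range: tuple[float, float],
    label: str,
) -> list[tuple]:
    land_rows, land_cols = np.nonzero(land)
    feats = []
    for _ in range(n_blobs):
        i = rng.integers(land_rows.size)
        lon, lat = grid.cell_center(land_rows[i], land_cols[i])
        radius = rng.uniform(*radius_range)  # degrees
        feats.append((Point(float(lon), float(lat)).buffer(radius, quad_segs=12), label))
    return feats


def make_conservation_layers(
    spec: IslandSpec,
    seed: int,
    land: np.ndarray | None = None,
) -> tuple[PolygonLayer, PolygonLayer]:
    """Protected-area layer (classes ``conservation-forest`` and
    ``all-conserved``) and a forest-cover layer.

    Conservation-forest polygons are strict subsets of all-conserved ones
    (each is a shrunken copy), and forest polygons are grown until they
    cover 20-35% of land.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid()
    if land is None:
        _, elev, _ = make_island_climate(spec)
        land = np.isfinite(elev)

    conserved = _random_blobs(rng, grid, land, 6, (0.04, 0.10), "all-conserved")
    cons_forest = [
        (geom.buffer(-0.35 * np.sqrt(geom.area / np.pi)), "conservation-forest")
        for geom, _ in conserved[:4]
    ]
    cons_forest = [(g, lab) for g, lab in cons_forest if not g.is_empty]
    protected = PolygonLayer(features=conserved + cons_forest)

    areas = cell_area_km2(grid)
    land_area = areas[land].sum()
    forest_feats: list[tuple] = []
    frac = 0.0
    # grow forest cover until within the 20-35% band
    for _ in range(200):
        if frac >= 0.20:
            break
        forest_feats.extend(_random_blobs(rng, grid, land, 2, (0.05, 0.12), "forest"))
        mask = rasterize(PolygonLayer(features=forest_feats), grid).astype(bool) & land
        frac = areas[mask].sum() / land_area
    # trim overshoot by dropping blobs from the end
    while frac > 0.35 and len(forest_feats) > 1:
        forest_feats.pop()
        mask = rasterize(PolygonLayer(features=forest_feats), grid).astype(bool) & land
        frac = areas[mask].sum() / land_area
    forest = PolygonLayer(features=forest_feats)
    return protected, forest
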