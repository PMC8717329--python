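"""Config-driven orchestration: clean -> select variables -> tune -> fit
replicates -> project scenarios -> metrics -> classify -> richness -> gap.

Artifacts are plain text (ASCII rasters, CSV, JSON); every written file is
checksummed into the run manifest so a rerun with the same config and seed
can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import endemism_richness as er
from . import gap_analysis as ga
from . import suitability_metrics as sm
from .geodata_io import (
    ClimateStack,
    cell_area_km2,
    rasterize,
    read_ascii_grid,
    read_occurrences,
    read_polygon_layer,
    read_raster_stack,
    write_ascii_grid,
)
from .maxent_core import (
    FeatureSpec,
    ModelConfig,
    logistic_map,
    nanmean_maps,
    permutation_importance,
    replicate_fit,
    sample_background,
    tune,
)
from .occurrence_prep import clean_occurrences
from .synthetic_data import ZONE_CODES
from .variable_selection import buffer_mask, filter_collinear, pearson_matrix

__all__ = ["RunConfig", "RunManifest", "run_all", "ConfigError", "DataError"]


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    occurrences_csv: str
    current_stack_dir: str
    scenario_stack_dirs: dict[str, str] = field(default_factory=dict)
    elevation_raster: str | None = None
    zone_raster: str | None = None
    protected_geojson: str | None = None
    forest_geojson: str | None = None
    endemic_species: list[str] = field(default_factory=list)
    category_overrides: dict[str, str] = field(default_factory=dict)
    r_threshold: float = 0.65
    buffer_km: float = 100.0
    min_count: int = 10
    fc_grid: list[str] = field(default_factory=lambda: ["L", "Q", "H", "LQ", "LH", "QH", "LQH"])
    rm_min: float = 1.0
    rm_max: float = 5.0
    rm_step: float = 0.5
    hinge_knots: int = 20
    n_background: int = 10_000
    n_replicates: int = 20
    train_fraction: float = 0.70
    max_iterations: int = 5000
    richness_level: Any = "max"
    seed: int = 0

    @property
    def rm_grid(self) -> list[float]:
        return [round(x, 6) for x in np.arange(self.rm_min, self.rm_max + 1e-9, self.rm_step)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, p in [("occurrences_csv", self.occurrences_csv),
                         ("current_stack_dir", self.current_stack_dir)]:
            if not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")
        for scen, d in self.scenario_stack_dirs.items():
            if not Path(d).exists():
                raise ConfigError(f"scenario {scen!r} raster dir missing: {d}")
        for opt in (self.elevation_raster, self.zone_raster,
                    self.protected_geojson, self.forest_geojson):
            if opt is not None and not Path(opt).exists():
                raise ConfigError(f"configured path does not exist: {opt}")
        if len(set(self.scenario_stack_dirs)) != len(self.scenario_stack_dirs):
            raise ConfigError("scenario labels must be unique")


@dataclass
class RunManifest:
    config_hash: str
    stages: dict[str, float] = field(default_factory=dict)  # wall seconds
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    inputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_stack_dir(directory: str | Path, period: str) -> ClimateStack:
    directory = Path(directory)
    paths = sorted(directory.glob("bio*.asc"), key=lambda p: int(p.stem[3:]))
    if not paths:
        raise DataError(f"no bio*.asc rasters in {directory}")
    return read_raster_stack(paths, [p.stem for p in paths], period_label=period)


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest = RunManifest(config_hash=hashlib.sha256(cfg_text.encode()).hexdigest())

    def record(path: Path) -> None:
        manifest.outputs[str(path)] = _sha256(path)

    def stage(name: str):
        return _StageTimer(name, manifest)

    # ------------------------------------------------------------------ load
    with stage("load"):
        occ = read_occurrences(config.occurrences_csv)
        manifest.inputs[config.occurrences_csv] = _sha256(Path(config.occurrences_csv))
        current = _read_stack_dir(config.current_stack_dir, "current")
        scenarios = {
            label: _read_stack_dir(d, label)
            for label, d in config.scenario_stack_dirs.items()
        }
        elevation = zones = None
        if config.elevation_raster:
            _, elevation = read_ascii_grid(config.elevation_raster)
        if config.zone_raster:
            _, zraw = read_ascii_grid(config.zone_raster)
            zones = np.where(np.isfinite(zraw), zraw, 0).astype(int)
        grid = current.grid
        areas = cell_area_km2(grid)
        land = current.valid_mask()
        protected_all = protected_cf = forest_mask = None
        if config.protected_geojson:
            prot = read_polygon_layer(config.protected_geojson)
            protected_all = rasterize(prot, grid).astype(bool)
            cf = rasterize(prot, grid, class_label="conservation-forest").astype(bool)
            protected_cf = cf
        if config.forest_geojson:
            forest_mask = rasterize(read_polygon_layer(config.forest_geojson), grid).astype(bool) & land

    # ----------------------------------------------------------------- clean
    with stage("clean"):
        cleaned, report = clean_occurrences(occ, current, min_count=config.min_count)
        cleaned.to_csv(out / "occurrences_clean.csv", index=False)
        (out / "cleaning_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        record(out / "occurrences_clean.csv")
        record(out / "cleaning_report.json")
    if cleaned.empty:
        raise DataError("no species survived occurrence cleaning")

    species_list = list(cleaned["species"].unique())
    results: dict[str, dict] = {}
    metric_rows = []

    for species in species_list:
        sp_occ = cleaned[cleaned["species"] == species].reset_index(drop=True)
        try:
            with stage("fit"):
                res = _run_species(species, sp_occ, current, scenarios, config,
                                   land, areas, manifest, out)
        except Exception as exc:  # fail loudly, naming the species
            raise DataError(f"stage failure for species {species!r}: {exc}") from exc
        results[species] = res
        metric_rows.append(res["metrics"])

    with stage("metrics"):
        metrics = pd.DataFrame(metric_rows)
        metrics.to_csv(out / "species_metrics.csv", index=False)
        record(out / "species_metrics.csv")

    # -------------------------------------------------------------- classify
    with stage("classify"):
        cat_rows = []
        for species in species_list:
            res = results[species]
            elevs = _occurrence_elevations(
                cleaned[cleaned["species"] == species], grid, elevation
            )
            zone_overlap = _zone_overlap(res["binary_current"], zones, areas)
            profile = er.SpeciesProfile(
                species=species,
                endemic=species in config.endemic_species,
                current_area_km2=res["metrics"]["area_current_km2"],
                breadth=res["metrics"]["breadth"],
                occ_elevations_m=tuple(elevs),
                zone_overlap=zone_overlap,
            )
            label = er.classify(profile, overrides=config.category_overrides)
            cat_rows.append({
                "species": species, "label": label.label,
                "rule_trace": label.rule_trace, "overridden": label.overridden,
            })
        categories = pd.DataFrame(cat_rows)
        categories.to_csv(out / "categories.csv", index=False)
        record(out / "categories.csv")

    # -------------------------------------------------- richness + gap
    with stage("richness"):
        periods = ["current"] + list(scenarios)
        category_counts: dict[str, dict[str, np.ndarray]] = {p: {} for p in periods}
        uncertainty_maps: dict[str, np.ndarray] = {}
        for label in sorted(categories["label"].unique()):
            members = categories.loc[categories["label"] == label, "species"]
            for period in periods:
                key = "binary_current" if period == "current" else f"binary_{period}"
                counts = er.stack_richness([results[s][key] for s in members])
                category_counts[period][label] = counts
            write_ascii_grid(out / f"richness_{label}_current.asc", grid,
                             category_counts["current"][label])
            record(out / f"richness_{label}_current.asc")
            uncertainty_maps[label] = er.uncertainty(
                [results[s]["replicate_binaries"] for s in members]
            )

    with stage("gap"):
        if protected_all is None:
            protected_all = np.zeros(grid.shape, dtype=bool)
            protected_cf = np.zeros(grid.shape, dtype=bool)
            manifest.warnings.append("no protected layer configured; gap extents are zero")
        gap_rows = []
        for period in periods:
            rows = ga.gap_report(
                category_counts[period], protected_all, protected_cf,
                forest_mask if period == "current" else None,
                areas, period=period, level=config.richness_level,
            )
            gap_rows.extend(rows)
        gap_df = pd.DataFrame([asdict(r) for r in gap_rows])
        gap_df.to_csv(out / "gap_report.csv", index=False)
        record(out / "gap_report.csv")

        if forest_mask is not None:
            high_conf = [
                (m == er.UNCERTAINTY_CODES["always"]) for m in uncertainty_maps.values()
            ]
            dry = category_counts["current"].get("nonendemic_dry")
            rec = ga.recommendation_map(
                high_conf,
                ga._richness_mask(dry, config.richness_level) if dry is not None else None,
                forest_mask, protected_all,
            )
            write_ascii_grid(out / "recommendation.asc", grid, rec.astype(float))
            record(out / "recommendation.asc")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest


class _StageTimer:
    def __init__(self, name: str, manifest: RunManifest):
        self.name, self.manifest = name, manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.stages[self.name] = self.manifest.stages.get(self.name, 0.0) + (
            time.perf_counter() - self.t0
        )
        return False


def _occurrence_elevations(sp_occ: pd.DataFrame, grid, elevation: np.ndarray | None) -> list[float]:
    elevs = [float(e) for e in sp_occ["elevation"] if np.isfinite(e)]
    if elevs or elevation is None:
        return elevs
    rows, cols = grid.cell_index(sp_occ["lon"].to_numpy(), sp_occ["lat"].to_numpy())
    ok = rows >= 0
    vals = elevation[rows[ok], cols[ok]]
    return [float(v) for v in vals if np.isfinite(v)]


def _zone_overlap(binary: np.ndarray, zones: np.ndarray | None, areas: np.ndarray) -> dict[str, float]:
    if zones is None:
        return {}
    suitable = binary == 1.0
    total = areas[suitable].sum()
    if total <= 0:
        return {}
    out = {}
    for name, code in ZONE_CODES.items():
        a = areas[suitable & (zones == code)].sum()
        if a > 0:
            out[name] = float(a / total)
    norm = sum(out.values())
    return {k: v / norm for k, v in out.items()} if norm > 0 else {}


def _run_species(species, sp_occ, current, scenarios, config, land, areas, manifest, out):
    grid = current.grid
    calib = buffer_mask(sp_occ, grid, config.buffer_km, valid=land, species=species)
    cm = pearson_matrix(current, calib.mask)
    retained = filter_collinear(cm, threshold=config.r_threshold, species=species)
    variables = retained.kept
    vars_path = out / f"variables_{_slug(species)}.json"
    vars_path.write_text(json.dumps({
        "species": species, "kept": retained.kept, "dropped": retained.dropped,
    }, indent=2))
    manifest.outputs[str(vars_path)] = _sha256(vars_path)

    background = sample_background(current, calib.mask, n=config.n_background,
                                   seed=config.seed, names=variables)
    rows, cols = grid.cell_index(sp_occ["lon"].to_numpy(), sp_occ["lat"].to_numpy())
    presence_env = pd.DataFrame(
        {v: current[v][rows, cols] for v in variables}
    ).dropna().reset_index(drop=True)
    study_env = current.env_table(current.valid_mask(variables), variables)

    tuning = tune(presence_env, background, study_env,
                  fc_grid=config.fc_grid, rm_grid=config.rm_grid,
                  hinge_knots=config.hinge_knots,
                  max_iterations=config.max_iterations)
    tuning_path = out / f"tuning_{_slug(species)}.csv"
    tuning.to_csv(tuning_path, index=False)
    manifest.outputs[str(tuning_path)] = _sha256(tuning_path)
    sel = tuning[tuning["selected"]].iloc[0]
    model_config = ModelConfig(
        fc=FeatureSpec.from_label(sel["fc"], hinge_knots=config.hinge_knots),
        rm=float(sel["rm"]), n_background=config.n_background,
        n_replicates=config.n_replicates, train_fraction=config.train_fraction,
        max_iterations=config.max_iterations, seed=config.seed,
    )
    replicates, mean_map = replicate_fit(presence_env, background,
                                         current.subset(variables), model_config)
    suit_path = out / f"suitability_{_slug(species)}_current.asc"
    write_ascii_grid(suit_path, grid, mean_map)
    manifest.outputs[str(suit_path)] = _sha256(suit_path)

    presence_scores = mean_map[rows[rows >= 0], cols[rows >= 0]]
    presence_scores = presence_scores[np.isfinite(presence_scores)]
    bg_valid = current.valid_mask(variables)
    background_scores = mean_map[bg_valid]
    ts = sm.thresholds(presence_scores, background_scores)
    tau = ts.chosen_value
    if ts.degenerate:
        manifest.warnings.append(f"{species}: degenerate threshold scores")

    binary_current = sm.binary_map(mean_map, tau)
    tp = int(np.sum(presence_scores >= tau))
    fn = int(presence_scores.size - tp)
    fp = int(np.sum(background_scores >= tau))
    tn = int(background_scores.size - fp)
    ks = sm.kappa(tp, fp, fn, tn)
    breadth = sm.niche_breadth(mean_map)
    area_current = sm.suitable_area(binary_current, areas)

    perm = permutation_importance(replicates[0].fit, presence_env, background,
                                  seed=config.seed)

    metrics = {
        "species": species, "n_presences": len(presence_env),
        "fc": sel["fc"], "rm": float(sel["rm"]),
        "threshold_mtp": ts.mtp, "threshold_eq_ss": ts.eq_ss,
        "threshold_max_ss": ts.max_ss, "threshold_used": tau,
        "kappa": ks.kappa, "breadth": breadth,
        "area_current_km2": area_current,
        "top_variable": perm.idxmax(),
    }
    res = {
        "variables": variables,
        "mean_map": mean_map,
        "binary_current": binary_current,
        "replicate_binaries": [sm.binary_map(r.suitability, tau) for r in replicates],
        "metrics": metrics,
    }

    for label, scen_stack in scenarios.items():
        maps = [logistic_map(r.fit, scen_stack.subset(variables), clamp=True)
                for r in replicates]
        scen_mean = nanmean_maps(maps)
        scen_binary = sm.binary_map(scen_mean, tau)
        res[f"binary_{label}"] = scen_binary
        a_fut = sm.suitable_area(scen_binary, areas)
        metrics[f"area_{label}_km2"] = a_fut
        metrics[f"pct_{label}"] = (
            sm.pct_change(area_current, a_fut) if area_current > 0 else np.nan
        )
        mess_vals, _ = sm.mess_raster(scen_stack.subset(variables), background)
        metrics[f"mess_min_{label}"] = float(np.nanmin(mess_vals))
    return res


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_")
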