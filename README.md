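# enmgap

Presence–background ecological niche modeling with climate-change
projection and protected-area gap analysis, plus a synthetic-island data
generator so the entire pipeline runs offline with no external downloads.

The pipeline mirrors a standard conservation-biogeography workflow:

1. **Occurrence cleaning** — exact-duplicate removal, missing-environment
   drop, one-record-per-raster-cell thinning, minimum-sample filters, with
   a full attrition report.
2. **Variable selection** — per-species 100 km great-circle calibration
   buffers and greedy pairwise-Pearson collinearity filtering (|r| ≤ 0.65).
3. **Maximum-entropy modeling** (from scratch) — linear/quadratic/hinge
   features, L1-penalized Gibbs likelihood solved by FISTA, AICc selection
   over the feature-class × regularization grid (1–5, step 0.5), 20
   bootstrap replicates with 70/30 splits, 10,000 background points,
   logistic output, clamped transfer, jackknife and permutation variable
   importance.
4. **Suitability metrics** — three binarization thresholds (minimum
   training presence, sensitivity=specificity, max sensitivity+
   specificity), Cohen's kappa, Levins niche breadth, MESS extrapolation
   surfaces, suitable-area (km²) and percent-change accounting.
5. **Endemism categories and stacked richness** — five-way classification
   (wide endemic, lowland/montane narrow endemic, dry/wet-zone
   nonendemic), per-category richness maps and tri-state
   (always/mixed/absent) uncertainty maps.
6. **Gap analysis** — overlap of richness areas with protected-area and
   forest-cover layers, per-category extent tables and a conservation
   recommendation map.

Rasters are ESRI ASCII grids (text, lossless round-trip), polygon layers
are GeoJSON, occurrence tables are CSV (`species,lon,lat,elevation,source`).

## CLI

Generate a synthetic island world (climate stack, virtual species,
occurrences, future scenarios, protected/forest layers, and a ready
`config.yaml`), then run every stage:

```sh
enm-gap synth --out world/ --seed 1
enm-gap run --config world/config.yaml
```

Individual stages:

```sh
enm-gap clean --occurrences occ.csv --stack-dir climate/current --out cleaned/
enm-gap select-vars --occurrences occ.csv --stack-dir climate/current \
    --threshold 0.65 --buffer-km 100 --out vars/
enm-gap fit --config world/config.yaml --species montane_endemic
enm-gap gap --run-dir world/results --protected world/protected.geojson \
    --forest world/forest.geojson
```

Outputs land in the configured `out_dir`: cleaned occurrences, per-species
retained-variable and tuning tables, mean suitability rasters, a
species-level metric table (thresholds, kappa, breadth, current and
per-scenario areas and percent changes, MESS minima), category
assignments, richness rasters, the gap report, a recommendation raster,
and a `manifest.json` with checksums and stage timings. Exit codes: 0
success, 2 configuration error, 3 data error.

## Notes

- The no-signal model scores exactly 0.5 everywhere (logistic output with
  entropy normalizer), and the penalized objective is verified against
  brute-force maximization in the tests.
- Gap-analysis percentages are truncated (not rounded) to one decimal,
  matching the convention of the published tables they reproduce; raw
  ratios are also exposed.
- Cell areas use the spherical cosine approximation
  (111.320 km/degree), adequate below ~0.5% error at island scale.
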