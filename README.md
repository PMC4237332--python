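# psrb

A Pressure–State–Response–Benefit (PSRB) biodiversity indicator pipeline that
disaggregates gridded and polygon data to arbitrary regional/national analysis
units, plus a seeded synthetic-scenario generator so every stage is testable
end-to-end without external datasets.

Indicators:

- **Pressure — forest loss**: per-unit mean forest cover (2000) and the annual
  rate of gross forest cover loss 2000–2005, expressed as percent of the 2000
  baseline per year.
- **State — Red List Index (RLI)**: per-unit, per-taxon (mammals, birds,
  amphibians, pooled) index on [0, 1]; first-assessment categories are
  back-cast through genuine category changes counted only when the driving
  process operated inside the unit; annualized change uses each group's
  assessment span (combined: the mean span).
- **Response — KBA protection**: percent of each key biodiversity area covered
  by the union of protected areas, unit means, a 1950–2010 time series with
  95% bootstrap confidence bands over random imputation of missing
  establishment dates, and the 1980–2010 annual rate.
- **Benefit — freshwater provision**: quality-weighted runoff routed along a
  D8 drainage grid to strictly-downstream populations, max-normalized to a
  relative per-cell index, averaged per unit (single time step, no trend).
- **Survey — monitoring capacity**: questionnaire score `P1 + 0.5*P2`
  (fractions answering "Monitored" / "Limited Monitoring") and monitoring-scale
  preference tabulations.

## CLI

```bash
# generate a synthetic scenario (rasters, units, species, sites, survey + ground truth)
psrb simulate --config scenario.yaml --seed 1 --out scn/

# compute any subset of indicators
psrb compute --inputs scn/ --indicators forest,rli,kba,freshwater,survey \
             --n-boot 1000 --seed 0 --out results/

# assemble dashboard products (tidy CSV, GeoJSON choropleths, JSON feed, trend charts)
psrb export --results results/ --formats csv,geojson,json,png
```

`scenario.yaml` keys mirror `psrb.synth.ScenarioConfig` (seed, n_units,
grid_shape, forest_cover_mean, true_annual_loss_rate, n_species_per_taxon,
category_change_prob, n_kba, n_pa, missing_date_fraction, survey_n,
survey_probs).

## File formats

Everything is plain text: ESRI ASCII grids (`.asc`, nodata preserved
bit-exactly), GeoJSON feature collections for units/KBAs/PAs, CSV for species,
survey and all tabular outputs, JSON for the ground-truth sidecar and the
dashboard feed.

## Layout

| module | purpose |
| --- | --- |
| `psrb.spatial` | `RasterGrid`, `SpatialUnit`, cell-center rasterization, zonal means, `.asc`/GeoJSON I/O |
| `psrb.synth` | seeded scenario generator with ground-truth sidecars |
| `psrb.forest` | pressure indicator |
| `psrb.rli` | state indicator |
| `psrb.kba` | response indicator (imputation + bootstrap series) |
| `psrb.freshwater` | benefit indicator (D8 routing) |
| `psrb.survey` | monitoring-capacity scoring |
| `psrb.export` | indicator table assembly and product export |
| `psrb.cli` | `psrb simulate / compute / export` |
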