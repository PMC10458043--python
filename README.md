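# ecoshift

Presence-only habitat-suitability modeling and multitemporal
land-use/land-cover (LULC) change analysis on regular raster grids.

The package provides:

- **`ecoshift.grid`** — raster data model (`GridSpec`, `GridLayer`,
  `RasterStack`), GeoTIFF I/O, nearest/bilinear/block resampling, Horn
  slope/aspect derivation from a DEM, and per-layer summary statistics.
- **`ecoshift.occurrences`** — occurrence CSV ingestion, spatial thinning
  to one record per grid cell, and convex-hull occurrence-area polygons.
- **`ecoshift.varselect`** — pairwise Pearson correlation between layers
  and collinearity pruning at a cutoff (connected-component grouping,
  deterministic representative choice).
- **`ecoshift.maxent`** — a from-scratch presence-background maximum-entropy
  model: linear/quadratic/product/hinge/threshold/categorical feature
  expansion, L1-regularized fitting by cyclic coordinate descent with exact
  backtracking (the training gain is non-decreasing by construction),
  raw/logistic/cloglog outputs, training AUC, percent contribution,
  permutation importance, jackknife gains, response curves, and raster
  projection.
- **`ecoshift.suitability`** — percentile presence thresholds
  (nearest-rank), binary presence/absence maps, five-class equal-interval
  classification, and present-vs-future change reports.
- **`ecoshift.lulc`** — hierarchical legend reclassification, per-epoch
  class-share tables over a polygon mask, epoch deltas (also directly from
  typed-in published percentage tables), and cross-tabulated transition
  matrices with persistence and gain/loss decompositions.
- **`ecoshift.synthetic`** — seeded generators for correlated smooth
  environmental fields, categorical soil, a DEM, occurrences sampled from a
  known suitability surface, and Markov-kernel LULC epoch sequences.
- **`ecoshift.pipeline` / `ecoshift.cli`** — YAML-config-driven
  orchestration with per-stage seeds and a checksummed artifact manifest.

## CLI

Every subcommand takes a YAML config (`--config`), with optional `--seed`
and `--output-dir` overrides:

```bash
# full synthetic end-to-end run
ecoshift run-all --config config.yaml --seed 7

# difference published per-epoch class-share tables (no rasters needed)
ecoshift lulc-areas --config config.yaml
```

A minimal synthetic config:

```yaml
output_dir: out
seed: 7
synthetic:
  n_rows: 120
  n_cols: 120
  variables: [V1, V2, V3, V4]
  true_weights: {V1: 2.0}
  m_presence: 150
maxent:
  n_background: 1000
  hinge_knots: 10
```

For published-table mode set `lulc_published_table` to a wide CSV with a
`class` column and one percentage column per epoch (two such tables ship
with the package under `ecoshift/data/`).

Stages run in a fixed order (resample/simulate → thin → variable selection
→ fit → diagnostics → project → threshold → classify → change; LULC areas
and transitions alongside), and `manifest.json` records every artifact
with its SHA-256, so identical config + seed reproduces identical outputs.

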