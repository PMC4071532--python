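# megafauna

Macroecological analysis of late Quaternary megafauna extinction severity:
climate-change anomaly and velocity surfaces, hominin-palaeobiogeography
classes, per-region extinction proportions with extant-richness correction,
candidate-model enumeration with AIC selection, and spatially explicit
regression (SAR error models, Moran's I correlograms). The whole pipeline
runs on an internally generated synthetic world, so every stage is testable
offline; user-supplied tables and plain-text rasters in the same schemas are
accepted.

## Layout

| module | what it does |
|---|---|
| `megafauna.synthetic` | synthetic world: lattice regions grouped into continent blocks with hominin classes, autocorrelated climate fields, species tables, SAR-error extinction generator |
| `megafauna.climate` | anomaly, spatial gradient, velocity (m/yr), sqrt/max standardization, region aggregation, k-means climate categories, ASCII-grid raster I/O |
| `megafauna.ranges` | species acceptance filters (mass/dating/window), occurrence cleaning, coastal snapping, range-gap filling along least-cost environmental paths, extinction counts |
| `megafauna.richness` | per-continent quasi-binomial richness models; potential richness at minimal human impact; extinction proportions |
| `megafauna.models` | arcsine-sqrt least squares (documented AIC convention), quasi-binomial check, candidate enumeration with the anomaly/velocity exclusion rule, AIC selection, ordinal category lumping, nested F-tests |
| `megafauna.spatial` | 4-NN row-standardized weights, maximum-likelihood SAR error model (concentrated likelihood, sparse-LU log-determinants), Moran's I, 500-km correlograms, pseudo-R² |
| `megafauna.pipeline` / `megafauna.cli` | staged orchestration with cached plain-text artifacts, provenance headers and a run log |

## CLI

```sh
megafauna all --seed 1 --out out/run1          # full synthetic run
megafauna all --seed 1 --min-mass 44 --no-interpolation --out out/sens44
megafauna fit --seed 1 --out out/run1          # re-run one stage from cache
```

Subcommands `simulate | climate | ranges | richness | fit | spatial | all`;
flags `--config <yaml> --seed --min-mass {10,44} --epoch-pair
{lgm-present,lig-lgm} --no-interpolation --include-uncertain --k
--class-width-km --out`. Artifacts are CSV/ASCII-grid/GeoJSON files with a
provenance header (package version, config hash, seed); reruns with the same
configuration are byte-identical.

## Data conventions

- Rasters: ESRI ASCII grids (6-line header) in metres per cell; synthetic
  worlds use planar km geometry, real-mode distances are great-circle.
- Proportions are modelled on the arcsine-square-root scale; back-transform
  clamps to [0, pi/2] before sin².
- Mass thresholds are inclusive (>= 10 kg primary, >= 44 kg sensitivity);
  the study window is 132 000-1 000 years BP with inclusive bounds.
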