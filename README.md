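# canopyreg

Tract-level tree/greenspace landscape metrics and maximum-likelihood
spatial regression for ecological health-outcome studies.

Ecological analyses of urban greenness and respiratory health regress a
tract-level outcome rate — e.g. asthma emergency-department visits per
10,000 residents — on high-resolution measures of the tree canopy and of
greenspace stratified by land use, controlling for socio-demographic and
air-quality covariates. Because tract outcomes are spatially
autocorrelated, ordinary least squares is only a first step: Moran's I on
the OLS residuals gates the move to spatial autoregressive models.
`canopyreg` implements that whole pipeline, plus a synthetic-landscape
generator with recorded ground truth so every stage can be validated by
parameter recovery when the real rasters and health tables are
access-restricted.

## The models

With row-standardized contiguity weights `W` (queen contiguity by
default), the package estimates, by full maximum likelihood:

- **spatial lag (SAR)**: `y = ρWy + Xβ + ε`
- **spatial error (SEM)**: `y = Xβ + ε`, `ε = λWε + u`

where `ε` (resp. `u`) is i.i.d. Gaussian. β and σ² are profiled out of
the likelihood, leaving a bounded one-dimensional search over the spatial
parameter; the log-Jacobian `Σᵢ ln(1 − ρωᵢ)` uses the real eigenvalues
`ωᵢ` of `W`. Standard errors come from the numeric Hessian of the full
log-likelihood. Diagnostics include Moran's I (normal-approximation and
permutation inference) and variance-inflation factors.

The six landscape variables per tract are:

| Variable | Meaning |
|---|---|
| `TreeCov` | fraction of tract area under tree canopy |
| `TreeClus` | median area of connected canopy patches |
| `TreeAgr` | nearest-neighbour index of patch centroids (<1 clustered, >1 dispersed) |
| `PrvtGrn` | greenspace fraction on private land (residential/commercial/office/industrial) |
| `SemiGrn` | greenspace fraction on semi-public land (golf/education/cemetery/agriculture) |
| `GrnRec` | greenspace fraction on public parkland |

## Worked example

Run a fully synthetic study — a 16×16 lattice of tracts, clustered canopy,
per-tract land-use blocks, correlated covariates, and an outcome drawn
from a spatial-lag process with true ρ = 0.541:

```python
import canopyreg as cr

cfg = cr.PipelineConfig(seed=11, synthetic={"n_rows": 16, "n_cols": 16,
                                            "tract_cells": 20})
report = cr.run_study(cfg)
print(report.to_markdown())
```

Highlights of the output for this seed:

```
Tracts: 256 input, 254 retained, 2 excluded
Moran's I = 0.210, z = 6.434, p = 0.000        (OLS residuals: spatial models warranted)
max VIF = 2.531                                (below 5: no collinearity concern)
               SL model    SE model    OLS
Log likelihood  -1002.4     -1007.8    -1025.8
AIC              2036.8      2047.6     2081.6
spatial param    ρ = 0.563   λ = 0.575     —
```

The Moran z-score of 6.4 on the OLS residuals confirms the spatial
autocorrelation the outcome was generated with; the lag model (the true
specification) attains the lowest AIC; and ρ̂ = 0.563 recovers the true
ρ = 0.541 to within the sampling spread expected at 254 tracts. Tracts
generated without residential land, or whose tree metrics are undefined
(fewer than two canopy patches), are excluded by the filtering stage and
itemised in the report's exclusion log.

The same study runs from a shell:

```sh
canopyreg simulate --seed 11 --out data/          # write rasters + table + truth
canopyreg metrics  --canopy data/canopy.asc --green data/greenspace.asc \
                   --landuse data/landuse.asc --tracts data/tracts.geojson \
                   --out metrics.csv
canopyreg fit      --table data/table.csv --weights data/weights.gal --model lag
canopyreg run      --config config.json --out results/
```

Estimators follow the scikit-learn protocol, so
`SpatialLagRegressor(weights=W).fit(X, y)` exposes `rho_`, `coef_`,
`intercept_`, `predict`, and `get_params`/`set_params`, and composes with
sklearn tooling; `fit_spatial_lag` / `fit_spatial_error` / `fit_ols` are
thin functional wrappers returning a `ModelFit` record.

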