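# Methods

## The analysis the package implements

The target design is an ecological regression at census-tract scale: an
outcome rate (emergency-department visits for asthma per 10,000 people)
is regressed on six landscape variables — canopy cover, median canopy
patch size, patch-centroid clustering, and greenspace split by land-use
access class — together with five socio-demographic percentages (poverty
rate, low educational attainment, African American population share,
children ≤10, seniors ≥65) and two air-quality covariates (PM2.5, ozone).
Because tract-level outcomes are spatially dependent, estimation proceeds
OLS → Moran's I on residuals → maximum-likelihood spatial lag (SAR) and
spatial error (SEM) models, with VIF screening of the predictors and a
three-column report (SAR, SEM, OLS) carrying coefficients, standardized
coefficients, standard errors, z-values with significance stars at the
two-tailed 0.10/0.05/0.01 levels, log-likelihood, AIC, pseudo-R², and the
spatial parameter.

## Landscape metrics

A *patch* is a maximal connected component of canopy cells within one
tract. Conventions, each configurable where noted:

- **Connectivity**: 8-neighbour by default (crowns touching diagonally
  read as one canopy); 4-neighbour selectable.
- **Tract membership**: a cell belongs to the tract containing its
  centre; no area-weighted splitting. The error this introduces is
  bounded by the one-cell ring along tract boundaries.
- **Cross-boundary canopies** are split at tract boundaries: all six
  variables are defined *within* each tract.
- **Median** of an even patch count is the mean of the two central order
  statistics.
- **Nearest-neighbour index**: `NNI = D̄_obs / D̄_exp` with
  `D̄_exp = 0.5/√(n/A)`, the classical average-nearest-neighbour
  expectation under complete spatial randomness. No edge correction is
  applied; the index is biased upward for small `n` because
  nearest-neighbour distances are censored at tract boundaries. The CSR
  calibration check therefore accepts a mean in [0.95, 1.10] rather
  than exactly 1.
- **Undefined metrics** (no patches for `TreeClus`, fewer than two for
  `TreeAgr`) are flagged, never imputed; flagged tracts are removed by
  the pipeline's filtering stage.
- Areas stay in the raster's native units; fractions are used
  internally everywhere and formatted as percentages only in reports.

Greenspace is classified by overlaying the binary greenspace raster with
the land-use map: residential, commercial, office and industrial land
feeds `PrvtGrn`; golf, education, cemetery and agriculture feed
`SemiGrn`; parks and recreation feed `GrnRec`. Green cells on any other
category count toward none of the three (reported as unclassified), so
the three fractions never exceed the tract's total green fraction.

## Spatial weights

First-order queen contiguity on the tract partition, row-standardized —
the conventional default of the spatial-econometrics software family this
report layout comes from; rook and symmetrized k-nearest-neighbour
weights are available as alternatives. Islands (tracts without
neighbours) are flagged at construction, left as zero rows by
standardization, and rejected by the estimators; the pipeline never
produces them on regular lattices.

For `W = D⁻¹B` with symmetric binary adjacency `B` and degree matrix
`D`, the spectrum is computed from the similar symmetric matrix
`D^(−1/2) B D^(−1/2)`, so it is real, and `ln|I − ρW| = Σᵢ ln(1 − ρωᵢ)`
is exact. The admissible spatial-parameter interval is
`(1/ω_min, 1/ω_max)` = `(1/ω_min, 1)` for row-standardized island-free
weights.

## Maximum-likelihood estimation

Both spatial models are estimated by full ML via the concentrated
log-likelihood; with ~10²–10³ tracts (and ~2×10³ in the real studies this
mirrors) the dense eigendecomposition is cheap, so no Chebyshev or sparse
log-determinant approximations are used.

- **Lag**: `L_c(ρ) = const − (n/2)·ln(e(ρ)ᵀe(ρ)/n) + Σᵢ ln(1 − ρωᵢ)`
  with `e(ρ) = e₀ − ρe_L`, where `e₀` and `e_L` are the OLS residuals of
  `y` and `Wy` on `X`. Each evaluation is O(1) after one pair of
  regressions.
- **Error**: for each λ the spatially filtered regression of
  `(I − λW)y` on `(I − λW)X` profiles out β (GLS at λ); the concentrated
  likelihood adds the same Jacobian term in λ.
- **Optimizer**: bounded scalar minimization (Brent) on
  `(1/ω_min + δ, 1/ω_max − δ)`, `δ = 1e−5`, tolerance `1e−8`. A solution
  within 10 tolerances of a boundary is flagged non-converged.
- **Standard errors**: central-difference numeric Hessian of the full
  log-likelihood at the optimum, with per-parameter relative step `1e−5`,
  uniformly for both models. The Hessian is taken in `(β, ρ or λ,
  ln σ²)`; the log keeps the variance step well-scaled, and the `(β,
  spatial)` block of the inverse information — the only block reported —
  is invariant to how σ² is parametrized. If the Hessian is singular or
  non-finite (boundary optimum), standard errors are reported as NaN with
  a warning rather than aborting the fit.
- **At ρ = 0 (λ = 0)** the full log-likelihood reduces exactly to the
  Gaussian OLS log-likelihood; the OLS column uses the ML variance
  `σ̂² = RSS/n` so the three columns are directly comparable.
- **AIC** = `2K − 2·loglik` with `K` = number of β coefficients + 1 for
  σ² + 1 for the spatial parameter (lag/error only). This counting
  convention is fixed here by documentation; published tables are often
  ambiguous about it.
- **Pseudo-R²**: squared Pearson correlation of observed vs predicted,
  with the reduced-form prediction `(I − ρ̂W)⁻¹Xβ̂` for the lag model and
  `Xβ̂` for the error model; the OLS column reports the classical R²
  (identical to the squared correlation whenever the latter is defined).
  Note the SEM's `Xβ̂` prediction discards the spatial error structure,
  so its pseudo-R² can legitimately fall below the OLS R².
- **Standardized coefficients**: `β̂ⱼ·sd(xⱼ)/sd(y)`; undefined for the
  constant.

## Diagnostics

Moran's I on residuals is `(n/S₀)·(eᵀWe)/(eᵀe)`, computed on the
residuals exactly as given (OLS residuals already have zero mean; no
studentizing). Default inference uses the normality-assumption variance
with `E[I] = −1/(n−1)`; a permutation scheme (default 999 relabelings,
seeded, pseudo-p with the +1 correction) is available because published
analyses rarely state which variance they used. VIFs are
`1/(1 − R²ⱼ)` from auxiliary regressions with intercept; exact
collinearity is reported as infinite rather than as a numeric overflow.

## The synthetic-landscape generator

The generator emulates every input of the real design with a known
data-generating process:

- **Partition**: a regular grid of square tracts. Real tracts are
  irregular, but no formula under test depends on tract shape, and the
  regular lattice makes queen adjacency analytically known.
- **Canopy**: seed cells drawn uniformly per tract (expected
  `patch_intensity` seeds per unit area), canopy grown by selecting
  cells with the smallest noisy distance-to-nearest-seed until the
  tract's target cover is met. The noise field is spatially smoothed
  (Gaussian, σ = 2 cells), so growth produces ragged connected blobs
  rather than salt-and-pepper speckle. `patch_growth` divides the noise
  amplitude: large values give compact discs around few seeds. Realized
  cover matches the target to within one cell per tract. Note an honest
  property of any growth process of this kind: *aggregating* trees into
  fewer, larger patches spaces the surviving patch centroids apart
  (merging removes close pairs), which *raises* the patch-centroid NNI,
  while fragmented growth leaves many mutually close fragments and
  lowers it. Patch size and patch-location clustering are therefore
  controlled by different knobs (`patch_intensity`/`patch_growth` vs.
  seed placement), not by one.
- **Land use and greenspace**: each tract is split into contiguous
  vertical strips realising the configured class shares
  (largest-remainder rounding; order shuffled per tract), and each
  strip's first cells in raster order are marked green at the class's
  green share — exact to within one cell per block, which is what the
  round-trip tests assert. Optional Dirichlet/Beta jitter
  (concentrations 50 and 30 in the bundled dataset builder) makes
  tracts vary realistically around the configured composition instead
  of repeating it, which real tract data do and constant columns would
  break (zero-variance predictors have no VIF or coefficient).
- **Covariates**: Gaussian draws under a configurable correlation
  matrix, mapped to tract-level scales (e.g. poverty rate 18.82 ± 13.01
  percent, PM2.5 11.53 ± 1.28) and clipped to admissible ranges. The
  default correlation is a mild r = 0.3 within the socio-demographic
  block — a deliberate, realistic choice; no published correlation
  structure exists to calibrate against. Clipping shrinks realized
  correlations slightly; the generator's tests account for that.
- **Outcome**: directly as a rate, `y = (I − ρW)⁻¹(Xβ + ε)` (lag),
  `y = Xβ + (I − λW)⁻¹u` (error), or `Xβ + ε` (none), with the true
  `(process, ρ or λ, β, σ, seed)` recorded verbatim in a
  `SyntheticTruth` next to every dataset. Defaults: ρ = 0.541,
  λ = 0.797, and coefficient magnitudes of the scale a tract-level
  ER-visit-rate regression produces; σ = 13 rate units gives moderate
  signal-to-noise. No population layer is simulated because the models
  operate on the rate itself.
- Every generator is a pure function of (configuration, integer seed);
  datasets are bit-reproducible, and dataset-level seeds are spawned
  from one master seed via `SeedSequence`.

What passing tests on these landscapes do **not** show: robustness to
irregular tract geometry and area heterogeneity, to non-Gaussian or
heteroskedastic outcomes, to misregistered rasters, or to the
measurement error of real canopy classification. They do show that the
measurement, weighting, diagnostic and estimation machinery is correct
wherever its assumptions hold.

## Pipeline conventions

- Tract filtering, in order: tracts below a residential-land-share
  threshold (default 0.05 — the analogue of dropping park/forest tracts
  without residential households, applied first as in the real design),
  tracts with flagged undefined metrics, then complete-case deletion of
  rows with missing values. Every exclusion carries its rule and reason
  in the report.
- The Moran gate is advisory: its result is logged, but all three
  models are always fitted so the columns can be compared.
- The outcome rate enters untransformed.
- Reports are bit-reproducible from (config, seed); the config digest
  (SHA-256 prefix) embedded in each report identifies re-runs of an
  unchanged configuration, which are no-ops.

## Problem sizes used in validation

The bundled validation uses lattices from 4×4 to 30×30 tracts (up to
n = 900 observations) with 100-replicate Monte-Carlo batches for
parameter recovery and model selection, 500 replicates for the CSR
calibration of the NNI, and a 0.001-step exhaustive grid as the
optimizer's oracle — sizes chosen so the whole suite runs in a few
minutes on one CPU while keeping Monte-Carlo standard errors well inside
the asserted tolerances.

## Known limitations

- No Lagrange-multiplier specification tests, spatial Durbin, GMM/2SLS
  estimation, or heteroskedasticity-robust variants.
- No distance-band or kernel weights; no polygon-clipping zonal
  statistics (cell-centre membership only).
- NNI carries the documented small-sample edge bias.
- The error model's pseudo-R² definition (prediction = `Xβ̂`) makes it
  incomparable to the lag model's reduced-form pseudo-R² when the error
  dependence is strong; AIC is the model-selection criterion, not
  pseudo-R².
- Raster IO is ESRI ASCII grid (plus GeoJSON for partitions, GAL/JSON
  for weights); georeferenced GeoTIFF is out of scope.
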