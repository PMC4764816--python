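# Methods

## The depth function

SOC content in alpine meadow profiles does not decline monotonically from
the surface: where a mattic epipedon (a dense living/dead root mat) is
present, content stays high and nearly constant through the mat and only
then decays. A single exponential misrepresents such profiles, so the model
is piecewise:

    C_v(z) = C_a                          0 ≤ z ≤ d_mat
    C_v(z) = C_a · exp(−k (z − d_mat))    z > d_mat

* `C_a` (kg m⁻³, > 0): SOC content at the surface; within mattic-bearing
  profiles it equals the mattic-layer content.
* `d_mat` (m): mattic thickness, 0 when absent. A flagged mattic layer must
  exceed 0.05 m (the diagnostic thickness criterion).
* `k` (m⁻¹, > 0): decay rate below the plateau.

Anchoring the decay at `z = d_mat` (rather than z = 0) is what makes the
function continuous and identifies C_a with the mattic content; with an
unshifted exponential the two segments would disagree at the mat's base.

Stocks over [z₁, z₂] integrate in closed form:

    S = C_a·(min(z₂,d) − min(z₁,d))
        + (C_a/k)·(e^{−k(max(z₁,d)−d)} − e^{−k(max(z₂,d)−d)})

Mapped stocks always use this integral; the 1-cm discretization
(`discretize_profile`) exists only for vertical-section visualization.

## Unit handling

Mass-basis SOC (g kg⁻¹) converts to volume basis as
C_v = C_m · ρ_b · (1 − G), which is dimensionally exact
((g/kg)·(g/cm³) ≡ kg/m³). `G` is the >2 mm fragment volume *fraction*; the
reader of percent-reporting lab sheets must divide by 100 once. Where bulk
density was not measured it comes from the pedo-transfer function
ρ_b = a₀ + a₁·exp(−a₂·C_m), defaults a₀ = 0.5 g cm⁻³ (organic-soil
asymptote), a₁ = 0.9 g cm⁻³ (so carbon-free soil sits at 1.4 g cm⁻³),
a₂ = 0.008 per (g kg⁻¹). The coefficients are configuration, not code:
any monotone-decreasing PTF of this family can be swapped in. Measured
densities always take precedence.

## Fitting

`(C_a, k)` are fitted per pedon by bounded nonlinear least squares
(trust-region reflective; k ∈ (10⁻³, 50), C_a ∈ (10⁻³, 500)), with mattic
occurrence and d_mat fixed from the field record. Horizon observations are
placed at interval midpoints — the simplest unbiased depth support when the
survey reports genetic horizons; mass-preserving splines are out of scope.
Within-plateau observations are fitted by the constant C_a, coupling both
segments. Initialization is deterministic: the two-point closed form
k = ln(v₁/v₂)/(z₂ − z₁) through the shallowest and deepest sub-plateau
midpoints. R² = 1 − SSE/SST with SST about the observed mean. Profiles with
all observations inside the plateau (k undetermined) or fewer than two
distinct sub-plateau depths raise an identifiability error.

## Spatial models

Four random forests on the covariate stack (elevation, folded aspect,
slope, slope length, curvatures, catchment area, wetness index, MrVBF,
valley depth, MAT, MAP, Landsat-like B3/B4/B5, NDVI, Lat, Lon):

* occurrence classifier — 1000 trees, mtry 4, majority vote; exact 50/50
  ties resolve to "no mattic" (conservative and deterministic; with 1000
  trees ties are rare);
* regressors for log d_mat, log C_a, log k — 1000 trees, mtry 6. Natural
  logs guarantee positive back-transformed predictions (plain exp, no
  smearing correction); the d_mat regressor trains only on mattic-bearing
  sites, where the quantity is defined, and predictions are forced to 0
  where the classifier says no mattic.

Regression trees stop at 3 samples per leaf. Fully grown trees memorize
per-site noise and inflate the out-of-bag MSE of an uninformative model
~20% above the target variance; a small leaf restores the OOB-MSE ≈
variance behaviour expected of an honest error estimate while retaining
enough local detail for in-sample (internal-validation) accuracy. OOB error
(classification error rate; regression MSE on the log scale, matching the
log-named targets) is summarized over repeated runs re-seeded
seed+0…seed+n−1 by min, quartiles, mean, median, max and SD.

Variable importance is the mean decrease in prediction accuracy computed
the out-of-bag way: for each tree, each covariate is permuted among that
tree's OOB rows and the drop in OOB accuracy (or rise in squared error) is
averaged over trees and repeats. Evaluating permutation importance on the
training rows instead would credit memorized noise covariates; the per-tree
bootstrap is reconstructed from each tree's stored random state and is
cross-checked in the test suite against the forest's own OOB predictions.

## Validation protocols

* Internal: at each calibration site, "observed" stock integrates the
  site's fitted depth function over the layer; "predicted" stock applies
  the trained models to the site pixel's covariates (identical to reading
  the stock map there). In-sample, hence optimistic.
* Independent: pedons sampled contiguously at 5-cm increments; observed
  stock is the increment sum Σ C_v·Δz, which does not presume the
  functional form. Any coverage gap is an error, not a silent
  interpolation.
* Indices: ME = mean(P − O) (negative ⇒ under-prediction),
  RMSE = √mean((P − O)²), and Lin's concordance correlation coefficient
  with population (1/n) variances, LCCC = 2·cov / (σ_P² + σ_O² + (μ_P −
  μ_O)²). The identity RMSE² = ME² + Var(P − O) and the bound
  LCCC ≤ |r| are enforced in tests.
* The default validation layer is 0–100 cm; per-layer reporting is
  available.
* Residual spatial structure: classical Matheron semivariogram of
  prediction residuals over user-supplied lag bins. A flat variogram means
  regression kriging of residuals would add nothing.

Run-to-run spread of the indices is generated by re-seeding the forest
training — the pipeline's only stochastic stage — across runs.

## The synthetic landscape

The generator emulates the survey setting this pipeline targets: a
200×200-pixel grid at 90 m, 96 calibration pedons sampled by genetic
horizons, and 3 independent pedons at 5-cm increments, all drawn from one
seeded generator hierarchy (covariates, fields and pedons use separate
child streams of the master seed, so every product is bit-reproducible).

* Covariates are Gaussian-filtered white-noise fields (σ = 25 px) with
  physically linked structure: MAT follows a −6.5 K km⁻¹ lapse on
  elevation, MAP a positive elevation gradient, and B3/B4 are back-solved
  from the NDVI field so the NDVI computation is exactly consistent.
* Truth fields: mattic occurrence ~ Bernoulli(logistic(−0.5 + 3.0·NDVI_std
  − 1.5·MAT_std)) (≈ 40% prevalence, matching the roughly two-fifths of
  surveyed alpine pedons that carry the mat); log d_mat, log C_a and log k
  are linear in standardized NDVI/elevation/MAT with field noise SDs
  0.05/0.18/0.18 and clips to [0.06, 0.30] m, [5, 100] kg m⁻³ and
  [0.2, 10] m⁻¹ — magnitudes mirroring reported alpine-meadow values
  (mattic content ≈ 38, ordinary topsoil ≈ 22 kg m⁻³, mattic depth
  ≈ 0.15 m, k ≈ 2.3 m⁻¹).
* Calibration pedons: 4–6 horizons to ≥ 1 m (first boundary at d_mat where
  present). A horizon's value is the *depth average* of the true function
  over the horizon times multiplicative lognormal noise (CV = 0.10), not
  the midpoint value — so midpoint fitting faces a small, realistic model
  discrepancy (relative error up to ~sinh(kh/2)/(kh/2) − 1, ≈ 2% at
  k ≈ 3) rather than a tautology.
* Independent pedons are placed purposively, one random pixel per
  equal-count NDVI stratum. Real surveys of this kind locate their few
  validation profiles across contrasting landscape conditions by design;
  uniformly random placement of just three profiles frequently yields
  three near-identical stocks, for which a three-pair concordance
  coefficient is meaningless.
* Mattic flags are copied from truth (flag-error rate defaults to 0;
  occurrence determination is treated as ground truth, with an optional
  error rate for sensitivity work).

What the generator does *not* emulate: geostatistically calibrated
variograms of a real study area, Landsat radiometry, terrain-attribute
consistency (slope, curvature etc. are independent smooth fields, not
derivatives of the elevation field), bedrock shallower than 1 m, and
spatially correlated measurement error. Passing recovery tests therefore
demonstrates that the pipeline's estimators are consistent and unbiased
under a known generating process of realistic magnitudes — not that any
particular real-world accuracy will be achieved.

## Numerical choices and degenerate inputs

* Closed-form stocks agree with trapezoid quadrature (10⁻⁴ m step) to
  ≤ 10⁻⁸ relative for k ≤ 3; the residual difference at larger k is the
  quadrature's own O(h²k²) truncation, not integrator error.
* Stock additivity over adjacent intervals holds to 10⁻¹² relative.
* NDVI is NaN (nodata) where both bands are zero; nodata is one mask
  shared by all stack layers, and a pixel missing anywhere is excluded
  from training and prediction.
* Soil depth is assumed ≥ 1 m at every mapped pixel; a bedrock-depth
  raster, when available, should truncate the integration bottom.
* Resampling: bilinear for continuous layers, nearest-neighbour for
  categorical; climate layers arriving at coarser grids are assumed
  bilinear.
* Raster I/O uses plain-text ESRI ASCII grids plus a JSON manifest; grids
  are row-0-north with cell-center coordinate semantics.
* Problem sizes in the shipped tests and acceptance script (60×60 grids for
  unit tests, the full 200×200 scenario over ten seeds for end-to-end
  recovery) were chosen so the whole suite completes in a few minutes while
  keeping the end-to-end experiment at the standard study conditions.

## Known limitations

* The three-pedon independent validation makes LCCC an n = 3 statistic;
  its run-to-run distribution is intrinsically wide, and occasional low or
  near-perfect values under re-simulation are sampling behaviour, not
  pipeline regressions.
* Exactly tied classifier votes default to "no mattic"; with even tree
  counts this is a (rare) asymmetry.
* The log back-transforms carry no bias correction; predicted C_a, k are
  medians, not means, of the predictive distribution.
* Terrain covariates are consumed, never computed: the package expects a
  GIS-prepared stack.
* No uncertainty maps are produced; OOB statistics and validation indices
  quantify model quality globally, not per pixel.
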