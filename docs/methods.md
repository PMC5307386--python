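# Methods

This note records the statistical model behind `socmap`, the defaults that
matter, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer should know about.

## Model and pipeline

SOC stock per layer is treated as a regionalized variable z(x) on a
projected metric plane, decomposed as

    z(x) = t(x) + ε(x)

with t a deterministic second-degree polynomial trend and ε an intrinsically
stationary, isotropic random field described by its semivariogram γ(h).
Because plot stocks are right-skewed, a Shapiro–Wilk test (α = 0.05) gates
the whole analysis onto the natural-log scale; everything between the gate
and the final back-transform (trend fitting, variography, kriging) operates
on the working scale. The stage order is fixed: transform → detrend →
variogram/interpolate residuals → retrend → back-transform. Detrending
before variography matters because a trend inflates γ̂ quadratically at
long lags and destroys the sill.

Four variogram families are supported. On the internal scale parameter a:

* spherical: γ = C₀ + C(1.5 h/A₀ − 0.5 (h/A₀)³), flat beyond A₀
* exponential: γ = C₀ + C(1 − e^(−h/a)), reported range A₀ = 3a
* Gaussian: γ = C₀ + C(1 − e^(−(h/a)²)), reported range A₀ = √3·a
* linear-to-sill: constant slope to the fitted extent, flat beyond

For the exponential and Gaussian families the *effective* (95 %) range is
reported, following the GS+ convention common in soil geostatistics; this
changes the meaning of A₀ relative to packages that report the scale
parameter, and is deliberate.

γ(0) is defined as 0 (the exact-interpolation convention): kriging honours
observed values exactly even with a positive nugget, which is the behaviour
wanted when the nugget represents microscale variation rather than
measurement error. The alternative "nugget as measurement error" smoothing
is not the default and is not currently exposed.

Ordinary kriging uses the m = 16 nearest neighbours by default, mirroring
the IDW neighbourhood so that the two methods differ only in their weights;
`m=None` gives global kriging. Duplicate sample coordinates are averaged
before solving, guaranteeing a nonsingular system. The kriging variance
w·γ₀ + μ is clipped at zero with a warning if round-off drives it
marginally negative.

The back-transform from the log working scale defaults to the lognormal
bias correction exp(ŷ + σ²_OK/2) for kriging and plain exp(ŷ) for IDW
(which has no prediction variance). The correction uses the kriging
variance of the *residual* field only; the trend is treated as known. Both
modes are selectable because the exact back-transformation used by legacy
GS+ workflows is not documented precisely.

## Estimation defaults and why

* Empirical semivariogram: 12 uniform lag bins to half the maximum pairwise
  distance; bins report the mean pair separation. Empty bins are dropped.
* Model fitting: weighted least squares with weights = pair counts N(h)
  (uniform and Cressie N(h)/γ² schemes selectable), eight multi-starts over
  moment-based heuristics because the objective is non-convex in the range.
  Model selection ranks by weighted R², ties broken by smaller weighted
  RSS, then by family order (spherical, exponential, Gaussian, linear).
  The unweighted R² is reported alongside since legacy software does not
  state which it prints.
* Moran's I: row-standardised inverse-distance weights over the 8 nearest
  plots — robust for irregular networks; the weight matrix is a modelling
  choice, not part of the statistic, and is configurable. p-values come
  from a seeded permutation null (default 999 permutations, one-sided for
  positive autocorrelation) with the randomisation-variance normal
  approximation reported for reference.
* Trend surfaces are fitted on centred, standard-deviation-scaled
  coordinates to avoid the catastrophic conditioning of raw metre-scale
  quadratics; coefficients are mapped back to the raw scale for reporting.
  Degree is fixed at 2; degree 1 exists for diagnostics only.
* LOOCV refits nothing per fold by default: the trend and variogram are
  estimated once on all n plots and held fixed, matching the legacy
  software behaviour this emulates and costing ~100× less; per-fold
  refitting is available via `refit_per_fold`.
* Pseudo-R² is the Nash–Sutcliffe efficiency 1 − SSE/SST; the squared
  correlation between predicted and observed is reported alongside. ME is
  predicted − measured, so negative ME reads as underestimation.
* Pools: grid cells are converted at cell_size²/10⁴ ha per cell and summed
  into Tg. Differences versus CA use CA as the denominator (whole percent);
  the OK-vs-IDW difference uses the mean of the two (one decimal).
* The 90 m default grid cell matches the DEM resolution of the emulated
  survey; the bundled examples and tests use 1–4 km cells, which changes
  pool totals by well under a percent on smooth surfaces while keeping grid
  prediction cheap.

## The synthetic generator

The generator reproduces the statistical conditions of a subtropical
Moso-bamboo plot survey: 111 plots over a 40 × 70 km domain; three depth
layers with arithmetic means 50.9 / 42.6 / 33.3 Mg ha⁻¹ and CVs of
32–47 %; log-scale variograms with nuggets 0.043–0.095, sills 0.13–0.35 and
ranges 17.5–30.9 km (nugget-to-sill 27–42 %, i.e. moderate spatial
dependence); a quadratic trend calibrated so a refitted second-order
surface explains roughly a third of the log-scale variance; and clustered
sampling locations (Matérn-style parents/offspring, one `cluster_factor`
knob where 0 is complete spatial randomness).

Construction per layer: a zero-mean Gaussian random field with the layer's
variogram is drawn by exact Cholesky factorisation of the dense covariance
C(h) = sill − γ(h) (diagonal jitter 10⁻¹⁰ × sill), added to the trend,
standardised, exponentiated with the log-normal σ matching the target CV,
then affinely rescaled on the arithmetic scale to the exact target mean and
SD (falling back to multiplicative mean-matching if the affine shift would
break positivity). The 0–60 cm stock is the per-plot sum of the three
layers, multiplicatively rescaled to the 0–60 target mean — note that in
the emulated survey the 0–60 layer was interpolated independently and its
published pool is *not* the sum of the layer pools; the generator's
summation is a simplification chosen for internal consistency.

Cross-layer dependence is induced by correlating the fields' driving
innovations (default correlation 0.7). This is an assumption: the emulated
survey reports no cross-layer covariance. Elevation is constructed to track
the latent carbon field (rescaled into 580–1605 m), so stocks increase
with elevation as upland forest soils typically show; slope and aspect are
independent noise. Not emulated: concentration/bulk-density pairs beyond
what the stock formula needs, soil-type strata, anisotropy, measurement
error distinct from the nugget, and any real terrain model — so passing
tests demonstrate correctness of the estimators under the assumed model,
not robustness to the ways real soil data violate it.

## Known limitations and variance of the estimators

* Variogram parameters estimated from a single realization are noisy. At
  n = 500 on the default domain (only two to three ranges across), the
  fitted sill lands within ±25 % and the range within ±35 % of truth in
  roughly 70–80 % of realizations depending on the seed block and weight
  scheme; the range is the binding constraint. This is a property of the
  problem, not of the optimizer — users should treat fitted ranges as
  order-of-magnitude statements.
* On white noise the range is unidentified; only the fitted semivariance
  level within the observed lag window is meaningful.
* Aspect enters the topographic regression as raw degrees, as legacy survey
  analyses do; a circular variable treated linearly can mask north/south
  contrasts. Interactions are plain products.
* Moran's I significance depends on the weight specification; both the
  permutation and normal p-values are reported, the permutation value being
  primary.
* IDW predictions are convex combinations of neighbour values on the
  working scale; after log back-transform the mapped range is typically
  wider than kriging's, and neither method extrapolates beyond the data's
  convex hull structure.
* The pipeline assumes projected metric coordinates and rejects tables
  whose coordinates all look like lon/lat degrees; it does not reproject.
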