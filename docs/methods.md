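# Methods

## The model

`geofalter` analyses continuous anthropometric z-scores (height-for-age,
weight-for-age, weight-for-height against the WHO 2006 Child Growth
Standards) measured on children at GPS-located survey clusters.  Rather
than dichotomising children into malnourished / not at the conventional
z < −2 cutoff and modelling a binary outcome — which discards
information — the z-scores are modelled directly and prevalence is
derived afterwards from the fitted predictive distribution.

For child *j* at cluster location *x\_i*,

    Y_ij = α + βᵀ D(x_i) + S(x_i) + U_ij

* `α` — intercept, in z-score units;
* `D(x_i)` — standardized environmental covariates at the cluster
  (each coefficient β reads as the change in mean z-score per 1 SD of
  the covariate);
* `S(x)` — a zero-mean stationary, isotropic Gaussian process with
  variance σ² and exponential correlation ρ(u) = exp(−u/φ), u the
  Euclidean distance in km.  σ² is the *between-cluster* (spatial)
  variance, φ the correlation scale; the *practical range* — the
  distance at which correlation drops to 0.05 — is ≈ 3φ (the exact value
  −φ ln 0.05 is available as an option);
* `U_ij` — iid Gaussian nugget with variance ω², the individual-level
  residual variation.

All geometry lives in a projected planar system in km; rasters are
cell-center registered, row-major from the top-left, with half-open cell
intervals, so point extraction (nearest containing cell) is exactly
defined and testable.

## Estimation

The model is linear-Gaussian, so the marginal likelihood of the observed
vector is a closed-form multivariate normal with covariance
Σ = σ² Z K Zᵀ + ω² I (Z the child→cluster indicator, K the cluster
correlation matrix).  We maximise this *exact* likelihood.  (General
geostatistical software often uses Monte Carlo maximum likelihood because
it also covers non-Gaussian outcomes; for the Gaussian case simulation
adds noise with no benefit.)

The likelihood is evaluated through an exact orthogonal decomposition:
within-cluster contrasts are iid with variance ω², and cluster means have
covariance σ²K + ω² diag(1/m_i).  One c×c Cholesky per evaluation
replaces the n×n problem; unit tests require agreement with the dense
multivariate-normal density to 10⁻⁸.  The covariance is factorized
exactly; a relative diagonal jitter (10⁻⁸, escalating to 10⁻⁴) is applied
only if factorization fails, e.g. with near-duplicate locations and a
vanishing nugget.

Optimization runs over (log σ², log φ, log ω²) with (α, β) profiled out
in closed form by GLS, using Nelder–Mead restarted from dispersed
perturbations of variogram-based initial values (nugget ≈ short-distance
semivariance, sill ≈ plateau, φ ≈ distance at ~63% of the sill); the φ
likelihood surface can be flat or multimodal, hence the restarts
(default 5).

### Confidence intervals

* α and β: Wald intervals from the observed information (equivalently
  the GLS covariance — mean and covariance parameters are orthogonal in
  Gaussian models).  Two-sided Wald p-values at the 0.05 level are
  reported for β; no multiplicity correction is applied.
* σ², ω²: Wald on the log scale, back-transformed — this produces the
  asymmetric intervals typical of variance components.
* φ: profile-likelihood interval (inverting the LR test at
  χ²₁(0.95)/2 = 1.92).  A 100-replicate calibration study showed
  log-scale Wald intervals for φ covering ~100% — the Wald SE of a
  weakly identified range parameter inflates exactly when the estimate
  strays, a known pathology — while the profile interval restores
  near-nominal coverage (~97% in the same study).

### Non-identifiable φ and the non-spatial fallback

If the profile log-likelihood over φ varies by less than 0.01 across two
orders of magnitude around the optimum, φ is reported as non-identifiable
(no residual spatial variation, or variation at a scale the data cannot
resolve).  A non-spatial variant — S(x) degenerates to iid cluster
effects, i.e. a compound-symmetry covariance, K = I — is then fitted and
attached, and the two can be compared by AIC.  The empirical variogram of
cluster-mean residuals, with a permutation envelope under the
independence null, supports the same judgement graphically; the envelope
is Bonferroni-adjusted across distance bins so "any bin outside" is a
calibrated 5% global test.

## Lagged covariates and exposure-window selection

Time-varying covariates (rainfall-, SPEI-, vegetation-like monthly
series) enter the model lagged relative to each child's birth month: lag
*d* is the covariate value at the child's location in calendar month
(birth month − d), and candidate windows run from birth (lag 0) to 12
months before.  Because neighbouring lags are highly correlated, each
lag is tested *on its own*: the scan substitutes one lag's standardized
column into the design, refits the model, and selects the lag with the
lowest AIC (= 2k − 2ℓ); ties below 10⁻⁶ break toward the shorter lag.
Scan refits are warm-started from the previous lag's covariance
parameters with a single start — the covariance surface moves little
between lags — while the headline fit keeps the full restart policy.

The drought index is multiscalar (an n-month timescale accumulates the
climatic water balance over the previous n months).  The accumulation
timescale is chosen *before* lag scanning as the one whose series has the
highest Pearson correlation with a vegetation index, pooled over
location–month pairs (per-location averaging is available as an option);
ties break toward the shorter timescale.  Computing the index itself from
precipitation and evapotranspiration is out of scope — multiscalar series
are inputs.

## Prediction, prevalence, counts, aggregation

With MLEs plugged in (parameter uncertainty is not propagated — the
standard practice for these maps; a parametric-bootstrap option would be
the natural extension), the latent field at grid points is predicted by
the conditional-Gaussian (kriging) formulas on cluster-level sufficient
statistics: mean c(x)ᵀV⁻¹ r̄ and variance σ² − c(x)ᵀV⁻¹c(x) with
V = σ²K + ω² diag(1/m).  This equals the dense individual-level
conditional formula exactly (tested to 10⁻⁸), and the joint conditional
covariance is available for simulation.

Prevalence at a cell is P(Y_new < −2) for a new child there:

* closed form (default): Φ((−2 − m(x)) / √(v(x) + ω²)) — exact under the
  Gaussian model;
* simulation: average Φ((−2 − α − βᵀD − S⁽ˢ⁾)/ω) over ≥500 joint
  conditional draws of S — retained because district-level *nonlinear*
  functionals of jointly dependent cells need joint draws.  The two paths
  must agree within Monte Carlo error (tested cellwise at 3 MC SEs).

Grid covariates are transformed with the *training* standardization
record, never re-standardized on the grid (that would silently rescale
β).  Time-varying covariates enter grid predictions at their temporal
mean over the series: a map cell has no birth month, so the surface
describes a child with average seasonal exposure.

Expected cases per cell are prevalence × under-5 population.  District
summaries assign cells to the polygon containing their center: cases are
summed, prevalence is cases/population (population-weighted by
construction), so the national total is conserved exactly under any
partition; cells outside all polygons and zero-population polygons are
reported, never dropped silently.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design in miniature so the entire
pipeline is testable without restricted survey microdata:

* cluster locations uniform over a rectangular domain (real surveys use
  probability-proportional-to-size sampling, which needs a census frame;
  uniform is the neutral stand-in);
* 5–15 children per cluster by default, uniformly (per-cluster counts
  are not published; ~7.5 children per cluster matches the survey's
  5219 children across 696 clusters);
* constant covariate rasters and monthly series as Gaussian random
  fields with exponential spatial covariance; monthly series add a
  sinusoidal 12-month seasonal mean, with a fresh anomaly field each
  month.  The temporal independence of anomalies is what makes lagged
  copies of a series distinguishable — real drought indices carry some
  month-to-month autocorrelation, so real-data lag selection is, if
  anything, harder than the synthetic test;
* z-scores drawn from the exact model above, with default truth near the
  published height-for-age fit: α = −1.23, σ² = 0.15, φ = 18.28 km,
  ω² = 2.02, one SPEI-like covariate acting at lag 3 with β = 0.06;
* an under-5 population raster (log-Gaussian clustered or uniform)
  summing to 7.2 million by largest-remainder rounding.

Default simulation rasters use 10 km cells over a 500 km square —
1 km national grids are the operational target, but every algorithm here
is resolution-agnostic and the coarser grid keeps simulation studies
quick.  Passing tests on synthetic data show the estimator and mapping
machinery are correct and calibrated *under the model*; they cannot show
robustness to survey-weighting effects, GPS displacement, covariate
measurement error, or non-Gaussian tails in real anthropometry.

## Verification at a glance

* blocked likelihood ≡ dense MVN density (10⁻⁸, 100 random instances);
* kriging ≡ dense conditional MVN (10⁻⁸);
* 50-replicate recovery at 300 clusters × 10 children: bias within 2 MC
  SEs for every parameter; 95% CI coverage within [85%, 99%];
* lag-selection power at the survey's scale (696 clusters, 5–10 children
  per cluster): true lag 3 recovered in ≥80% of 25 replicates;
* prevalence closed form vs 10,000-draw simulation within 3 MC SEs;
  aggregation conserves totals exactly.

## Known limitations

* Exponential correlation only (Matérn κ = 0.5) — no anisotropy, no
  general Matérn, matching the model this package implements.
* Plug-in prediction understates map uncertainty where parameters are
  poorly identified (wide φ intervals are common).
* Cell-to-district assignment is by cell center; area-weighted splitting
  of boundary cells is out of scope.
* The SPEI timescale choice pools correlations over space and time; if
  vegetation–water-balance coupling varies regionally, per-location
  correlation (the provided option) may choose differently.
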