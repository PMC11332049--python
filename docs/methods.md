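# Methods

This note documents the statistical model behind `phenoshift`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not establish.

## The phenometric model

A presence-only observation is a record (species, lon, lat, date). Within a
grid cell and year, observation dates for a conspicuous flowering species are
treated as draws from a unimodal distribution whose median tracks peak
flowering. The package estimates that median — the **median observation date
(MOD)** — rather than an onset percentile, because central percentiles of an
observation-date distribution are far less sensitive to sampling intensity
than the extremes: the chance of recording an early outlier grows with the
number of observers, the median barely moves.

**Distribution and fit.** The observation-day distribution is modelled as a
two-parameter Weibull (location fixed at 0, working on the raw day-of-year
scale). The MLE is computed by the standard profile-likelihood reduction:
for shape k the scale is λ(k) = (mean xᵏ)^(1/k) and k solves
Σxᵏ ln x / Σxᵏ − 1/k − mean(ln x) = 0, a monotone one-dimensional root
problem solved by Brent's method (and, for bootstrap matrices, by a
vectorised 80-step bisection in log k, bracketed in [10⁻³, 64] with
automatic expansion). The profile form matters because one MOD estimate
requires hundreds of refits; it agrees with `scipy.stats.weibull_min.fit`
(floc=0) to ~10⁻⁵ relative error, which the test suite checks as an
independent oracle.

Integer dates are jittered uniformly within ±0.5 day before fitting whenever
ties are present; continuous MLE is otherwise degenerate on heavily tied
integer data. A sample with all values identical short-circuits to a
degenerate estimate (MOD = that value, zero-width CI).

**Bias correction and CI.** The naive estimate is the plug-in quantile
q̂ = λ̂(−ln(1−q))^(1/k̂). The parametric bootstrap draws `n_bootstrap`
(default 250, minimum 100) samples of the original size from the fitted
Weibull, recomputes the plug-in quantile on each, and subtracts the mean
bootstrap bias from the naive estimate (one-step mean-bias correction). The
95% CI is the 2.5/97.5 percentile interval of the bootstrap quantiles,
re-centred on the corrected estimate. Whether an iterative correction would
differ in detail is left open deliberately; both the naive and corrected
values are retained in every output row so the correction is always
auditable. At n = 25 draws from a skewed Weibull (shape 2) the correction
reduces the mean bias of the estimator by roughly an order of magnitude
(~0.64 d → ~0.06 d in the antithetic calibration study) while leaving the
per-sample error essentially unchanged — it is a calibration fix, not a
variance fix.

**Minimum counts.** MOD is estimated only for cells with ≥ 25 records
(configurable; 20 is a common alternative); sparser cells are candidates for
interpolation instead. The threshold trades per-cell precision against
spatial coverage.

## Gridding

Cells live on a square grid in an equal-area plane so that every cell
covers the same ground area. Because `pyproj` is not a dependency, the
projection is a self-contained spherical Lambert azimuthal equal-area
transform on the authalic sphere (R = 6 371 007.181 m) with the standard
European parameters (centre 10°E 52°N, false origin 4 321 000/3 210 000 m).
Equal area holds exactly on the sphere; positional departures from the
ellipsoidal version are a few hundred metres — irrelevant at 50 km cells.
Cells are half-open intervals [x, x+s) × [y, y+s) with a lower-left origin
and row-major ids, so boundary points belong to exactly one cell. Cell
covariates are the unweighted mean elevation of source pixels falling in the
cell and the geographic coordinates of the projected cell centroid.

## Interpolation and the area of applicability

Under-sampled cells are predicted by ε-SVR with an RBF kernel on
standardized (elev, lat, lon), trained per species × year on the observed
cells (minimum 10). Hyperparameters are picked by unshuffled 5-fold CV over
a small fixed grid (C ∈ {10, 10², 10³, 10⁴}, ε ∈ {0.1, 0.5},
γ ∈ {scale, 0.1, 0.01}); the small-γ options let the CV select an almost
linear kernel when the surface is linear, which is what makes noiseless
linear surfaces interpolate to within ~1 day.

Predictions are restricted to the **area of applicability**: a target cell's
dissimilarity index is its minimum standardized Euclidean distance to any
training cell divided by the mean pairwise training distance, and the cell
is inside iff the index does not exceed the upper whisker
(Q75 + 1.5·IQR) of the training cells' leave-one-out indices. Predictor
weighting inside the distance is deliberately not applied. The
monotonicity property "fewer training cells ⇒ no larger AOA" holds under a
fixed scaler/normalizer/threshold (and is tested in that form); when the
threshold is re-derived from the subset it can move either way.

Interpolated cells never feed the gradient regressions by default:
interpolated MODs are functions of the very covariates being regressed on,
and including them would bias coefficients toward the interpolator. A config
switch enables the inclusive variant for comparison.

## Thermal time

GDD(d) = Σ_{i≤d} max(0, (Tmin_i+Tmax_i)/2 − T_base), T_base = 5 °C,
accumulated from January 1 (the conventional start; no single-sine or cutoff
variant). GDD at a fractional MOD is linear interpolation between the
bracketing integer days, making GDD-at-MOD continuous in MOD. Years are
handled as 365 days; a leap day is folded into the DOY-59 temperature so
DOYs align across years. Shifts are reported as year₂ − year₁ for both MOD
and GDD-at-MOD, so a warm first year should give a positive MOD shift and a
negative GDD shift.

## Inference

Per species × year, OLS of cell MOD on elevation (m), latitude and longitude
(degrees), unweighted regardless of per-cell n; a condition-number guard
rejects rank-deficient designs naming the collinear pair. The elevation
coefficient is additionally reported per 1000 m. Holm's step-down adjustment
is applied across the three slope p-values of each model (the family scope
is configurable; the implementation is cross-checked against statsmodels).
The inter-annual test is the paired two-sided Wilcoxon signed-rank on
per-cell MOD differences — "paired" forces the signed-rank form; an unpaired
rank-sum would discard the cell pairing. All-zero differences return p = 1
with a degenerate flag. Species are spring-flowering iff their
reference-year median-of-cell-MODs is strictly before DOY 172. The seasonal
course of each gradient coefficient across species × years is summarised by
a quadratic OLS against median MOD (vertex and concavity reported), which
captures the hump-shaped pattern — gradients peak near the spring–summer
transition because late-season species face a shortening season at high
elevation/latitude.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:

* **True surface**: per-cell median DOY = β₀ + β_elev·elev/1000 +
  β_lat·(lat−mean) + β_lon·(lon−mean), plus a constant shift per year index;
  defaults 150 + 20 d/km + 4 d/° lat + 0.5 d/° lon and 7 d/year, matching
  the classical bioclimatic gradients (≈4 d per degree latitude, ≈20 d per
  km elevation at desk scale). Covariates are centred so β₀ is the
  domain-centre median; clipping to [1, 365] warns.
* **Effort**: per-cell expected counts are gamma-multiplied around
  `mean_obs_per_cell` (default 60) with a tenfold boost in a few hotspot
  cells, then realised as Poisson or negative-binomial — the simplest model
  of effort clustering in populated areas. Zero-count cells are legitimate.
* **Dates**: drawn in continuous time from a normal or Weibull family with
  the requested median and dispersion (Weibull shape solved numerically so
  the SD matches), rounded to integer DOY — app records carry calendar
  dates. The default landscape is 20 × 20 cells of 50 km with log-normal
  elevations clipped to [0, 2500] m.
* **Climate**: daily means follow a seasonal sine (amplitude 9 °C peaking at
  the configured DOY) minus a 6.5 °C/km lapse and a 0.7 °C/° latitude
  gradient, plus iid daily noise; tmin/tmax are mean ∓ half the diurnal
  range. The `phase_doy` parameter is the DOY of the temperature *peak* (the
  sine is phase-shifted accordingly).
* **GDD coupling**: a cell's threshold-crossing day is the first day
  cumulative GDD reaches the threshold. The true median is
  mean_crossing + tracking·(year_crossing − mean_crossing) with
  tracking ∈ (0, 1], default 0.5. Exact tracking (1.0) would make
  GDD-at-MOD identical across years by construction, leaving the GDD shift
  as pure estimation noise; real flowering records show *partial*
  compensation — a warm year advances flowering, but the thermal time
  accumulated by the flowering date is still higher — and tracking < 1
  reproduces exactly that complementary-sign pattern. Cells never reaching
  the threshold yield no observations and are flagged.

All generators are bit-reproducible under a fixed seed.

**What passing tests show — and don't.** Recovery on these synthetics
demonstrates that the estimation chain is unbiased and correctly calibrated
*under the generator's assumptions*: unimodal within-cell date
distributions, effort independent of phenology, a linear gradient surface,
and spatially independent cells. Real opportunistic data violate several of
these (weekend/holiday effort cycles, range edges truncating the
observation curve, spatially correlated residuals, taxonomic confusion);
passing tests say the machinery is sound, not that those biases are absent.

## Numerical choices and problem sizes

Bootstrap seeds for each cell are derived from the root seed plus a hash of
the cell's (sorted) data, so results are independent of processing order and
identical data give identical estimates. The validation studies use a
100-cell landscape with ~150 observations per cell for gradient recovery
(20 seeds; the OLS slope SE is then ≈0.08 d/°, well inside the ±0.3 d/°
recovery check), 500 antithetic replicates for the n = 25 calibration
(antithetic pairing cuts the Monte-Carlo SE of the mean bias ~5-fold, making
the naive-vs-corrected comparison a measurement rather than noise), 50
replicates for the complementary-sign experiment, and 1,000 simulations for
the Wilcoxon type-I calibration. Degenerate inputs (all-identical samples,
all-zero shift vectors, unreachable GDD thresholds, empty cell
intersections) are handled explicitly as documented per function.

## Known limitations

* The spherical LAEA projection is a very good but not exact stand-in for
  the ellipsoidal European standard; grids built here may shift cell
  membership near edges relative to other tools (grid origin alignment is
  unspecified in general, so this is inherent to the method, not just the
  projection).
* The Weibull bias correction is one-step; heavily skewed, very small
  samples may retain residual bias.
* Effort is assumed independent of phenology within a cell; observation
  biases that co-vary with date (weather-driven recording) are not modelled.
* NetCDF I/O uses the classic (NetCDF-3) format via scipy.
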