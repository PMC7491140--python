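# Methods

This note documents the statistical model the package implements, the
design choices made where more than one reasonable option existed, what
the synthetic-data generator does and does not emulate, and the known
limitations of the approach.

## The two-stage model

**Stage 1.** For each location, the daily YLL rate Y_t (years of life
lost per 10⁵ population) is modelled as Gaussian with identity link:

    E(Y_t) = α + cb(Tm_t, lag) + ns(time_t, 7 df/year) + ns(RH_t, 3 df) + β·DOW_t

The cross-basis cb is the tensor product of an exposure basis R
(quadratic B-spline of daily mean temperature; internal knots at the
location's 10th/50th/90th percentiles, clamped boundary knots at the
observed minimum and maximum, no intercept column — the model intercept
absorbs it) and a lag basis C (natural cubic spline over integer lags
0..21, with intercept, three internal knots at equally spaced points on
the log-lag scale, i.e. 21^{1/4, 1/2, 3/4} ≈ 2.14, 4.58, 9.81 days).
Its entry for day t and coefficient (j, k) is
Σ_l R_j(T_{t−l})·C_{l,k}; the first 21 rows use an incomplete exposure
history and are dropped from the fit rather than imputed. Days with a
missing outcome are dropped with their design rows; their temperatures
still feed the lag history of later days. The fit is ordinary least
squares with the classical covariance σ̂²(XᵀX)⁻¹ — under the Gaussian
identity model there is no overdispersion concept, and no population
weighting is applied across days.

The fitted surface is reduced to the *overall cumulative*
exposure–response by summing the lag dimension: with M = I_vx ⊗ (1ᵀC),
θ = M·β_cb and V = M·Σ_cb·Mᵀ. Predictions re-centre the exposure basis
at a reference temperature: excess(T) = [R(T) − R(ref)]·θ, so
excess(ref) = 0 exactly and changing ref shifts the curve by a constant.

**Stage 2.** Reduced coefficients are pooled within each development
stratum under the intercept-only multivariate random-effects model
θ_i ~ N(μ, Ψ + V_i). Ψ is estimated by REML; the restricted likelihood
is maximised over a Cholesky factor of Ψ (so PSD holds by construction)
with L-BFGS-B from a method-of-moments start — the same estimator as
iterative GLS formulations, implemented as a direct maximisation for
robustness. BLUPs are

    θ_blup,i = μ̂ + Ψ̂(Ψ̂ + V_i)⁻¹(θ_i − μ̂)

with covariance Ψ̂ − Ψ̂(Ψ̂ + V_i)⁻¹Ψ̂ + A_i·Var(μ̂)·A_iᵀ,
A_i = I − Ψ̂(Ψ̂ + V_i)⁻¹. The last term propagates the uncertainty of
the pooled mean; a variant without it would understate BLUP uncertainty
for well-pooled strata.

## Attribution

The minimum-YLL-rate temperature (MYT) is the argmin of the BLUP curve
over a 0.1 °C grid, searched within the 2nd–98th percentile window of
the location's observed temperatures: at the observed extremes the
curve's variance explodes with data sparsity, and an argmin there is an
artifact rather than an optimum (on short series with long lag windows
the unconstrained argmin routinely lands on a boundary and produces
absurd attributable fractions). Ties break toward the median
temperature. The MYP is the empirical percentile of the MYT.

Attribution is *forward* on the overall cumulative association: day t
contributes a_t = [R(T_t) − R(MYT)]·θ_blup attributable YLL rate, and
a_t × population / 10⁵ attributable YLLs. When MYT is the curve's
argmin over the searched range, a_t ≥ 0 up to grid discretisation;
negatives larger than −10⁻⁹ are clamped to zero with a logged count,
genuine negatives (possible when the MYT is constrained away from the
global argmin) are retained. AF is the ratio of summed attributable
YLLs to summed YLLs (×100); life loss per death divides by summed
deaths instead. Components split the day set at the 2.5th percentile,
the MYT and the 97.5th percentile; cold/heat are defined relative to
the MYT first, so the four components partition the days exactly and
extreme + moderate additivity holds to machine precision whatever the
MYT's position relative to the percentile cuts.

Empirical 95% CIs come from n_sim (default 1000) draws
θ* ~ MVN(θ_blup, Var_blup); every burden quantity is recomputed per
draw with the MYT held at its point estimate (re-estimating it per draw
is available as an option), and the eCI is the 2.5th/97.5th percentile
of the simulated values. Stratum-level results sum per-draw
attributable YLLs across locations *at a shared draw index using a
shared underlying random stream*: BLUP curves within a stratum are
strongly correlated through the pooled mean, and independent
per-location draws would understate the pooled sampling variance by
roughly the square root of the number of locations.

## Clustering

Locations are clustered on percent urban dwellers, average education
years, and GDP per capita, z-standardised first (sample SD, ddof = 1):
unstandardised, GDP's numeric range dominates the Euclidean metric.
K-means uses 25 random starts; the cluster count is selected over
k = 2..7 by majority vote of silhouette, Calinski–Harabasz and
Davies–Bouldin, ties toward smaller k — a three-index panel standing in
for larger index collections, and extensible. With k = 2, the cluster
with the higher mean percent-urban is labelled HDR.

## Life tables

Abridged tables use nqx = n·nmx/(1 + (n − nax)·nmx) with nax = n/2
except the infant group (a0 = 0.1 years by default, configurable), the
standard lx/nLx/Tx chain, and ex = Tx/lx; the open-ended terminal group
takes ex = 1/nmx. YLL lookup is by age-group ex (not interpolated to
exact age). Days with zero deaths contribute zeros, keeping regression
series dense. No discounting or age-weighting is applied to YLLs.

## The synthetic-data generator

The generator emulates the *structure* of a national daily panel, not
any real geography:

* Temperature: annual mean 16 °C, seasonal sinusoid of amplitude 10 °C,
  AR(1) anomalies (ρ = 0.8, innovation SD 2 °C). All locations share
  this climate regime by default (`temp_mean_spread = 0`); per-location
  mean offsets are available but shift each location's basis and make
  the pooled estimand differ from the planted curve, so they are off in
  recovery experiments.
* Humidity: mean 72%, −0.8 %/°C coupling to the temperature anomaly,
  Gaussian noise, clipped to [0, 100].
* Outcome: baseline YLL rate 22 per 10⁵ per day, small day-of-week
  offsets, Gaussian noise SD 4 — the same distributional family the
  stage-1 model assumes, so recovery tests run under correct
  specification.
* Planted effect: a V-shaped overall curve with geometric lag decay
  (ratio 0.7 over lags 0..21, weights normalised to 1, so the lag-summed
  curve equals the V itself). The vertex (true MYT 24 °C, ~80–90th
  percentile of the simulated climate) is *smoothly rounded*: each arm
  is a C2 smoothstep hinge of half-width 6 °C, linear beyond it (cold
  slope 0.35, heat slope 0.5 YLL-rate units per °C; about 12% expected
  AF, ~87% of it cold-side — the burden scale and cold dominance such
  analyses report). The rounding is deliberate: a hard kink lies outside
  every C1 quadratic-spline space, so recovery experiments with a hard
  V would measure spline-approximation error rather than implementation
  correctness. `smooth_delta = 0` restores the hard kink for degenerate
  tests.
* Death records: daily records are drawn age-by-age (a fixed decedent
  age distribution skewed to old ages, 55% male, causes CVD 40% /
  respiratory 12% / other non-accidental) until the record-implied
  life-table YLL sum is as close to the day's target YLL as one more
  death allows — so records reproduce daily YLLs to within one death's
  remaining life expectancy. The continuous (pre-discretisation) rate is
  kept as the regression outcome. Life tables use a schematic
  Gompertz-like schedule with an infant hump and a female advantage
  (e0 ≈ 70/73.5 years).
* Socio metadata: two clusters at (86.3%, 10.7 y, 55.2) and (41.2%,
  8.3 y, 24.8) for percent urban / education / GDP per capita
  (thousands), with per-feature SDs (14, 1, 14); a quarter of locations
  are in the high-development cluster.

What passing recovery tests on these data show: the cross-basis,
reduction, pooling, BLUP and attribution machinery is implemented
correctly and the uncertainty quantification is calibrated *under
correct specification and a shared climate*. What they do not show:
robustness to real-data features the generator omits — spatial climate
heterogeneity (which biases pooling of location-specific-knot
coefficients), outcome distributions with heavy tails or
overdispersion, measurement error in exposure, influenza epidemics and
other confounders not captured by a smooth time trend, or harvesting
dynamics.

## Numerical choices

* Temperature percentiles and knots use the type-7 empirical quantile
  convention throughout, so results are bit-reproducible.
* The natural cubic spline is built by projecting a cubic B-spline basis
  onto the null space of its boundary second derivatives (the classical
  ns() column space); evaluation beyond the boundary continues linearly.
  The quadratic exposure basis is evaluated by the B-spline recursion
  with clamped boundary knots (no linear extrapolation).
* Log-lag knots are exp of points equally spaced strictly between
  log 1 and log lag_max; lag 0 is part of the lag range, not a knot.
* REML convergence: L-BFGS-B with ftol 1e−10, 200 iterations; a Ψ with
  all entries below 1e−10 is snapped to exactly zero so the
  no-heterogeneity limit (every BLUP = μ̂) is exact.
* MYT grid step 0.1 °C; argmin ties break toward the median.
* Degenerate inputs are rejected with named errors: non-stationary AR
  coefficients, zero-variance clustering features, nqx outside (0, 1]
  (naming the offending age group), non-PSD covariance inputs,
  rank-deficient stage-1 designs (naming the collinear blocks).

## Problem sizes in validation runs

Recovery experiments use 20 locations × 10 years (stage-1 designs of
~3 650 × 105), eCI calibration 200 single-location 3-year replicates at
n_sim = 200, the null control 20 replicates; these sizes give Monte
Carlo errors comfortably below the effects being checked while the full
suite runs in seconds.

## Known limitations

* Pooling location-specific-percentile-knot coefficients treats curves
  on different temperature supports as exchangeable; with strong climate
  heterogeneity the pooled curve and stratum burdens attenuate (the
  generator can reproduce this with `temp_mean_spread > 0`).
* Referencing attribution at an *estimated* argmin MYT makes daily
  attributable values non-negative by construction, which under a flat
  (null) truth inflates AF; the package's null-control experiment
  therefore evaluates attribution at a fixed reference, and users
  comparing near-null strata should be aware of the argmin bias.
* The Gaussian identity model is appropriate for YLL *rates* in
  populations large enough for daily rates to be roughly continuous; it
  is not a count model and small populations violate it.
* eCIs condition on Ψ̂ and V̂_i; hyper-parameter uncertainty is not
  propagated.
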