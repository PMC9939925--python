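# Methods

## The problem

Disease maps drawn per local administrative area (LAA) are noisy wherever
populations are small: the variance of a crude log-rate is roughly the
reciprocal of the case count, so sparsely populated areas show spuriously
extreme rates. Empirical-Bayes (EB) shrinkage fixes the noise but keeps the
map tied to administrative polygons; ordinary kriging produces a smooth
boundary-free surface but assumes every observation has the same error
variance, which is untenable for rates. `stabkrig` implements a kriging
estimator that carries each area's sampling variance into the prediction
system, combining both advantages.

## Model

Each area i contributes a log-rate estimate θ̂ᵢ = log(dᵢ/pᵢ) with sampling
variance vᵢ. The true log-rates θᵢ are modelled as a second-order
stationary isotropic random field: mean μ, variance τ², covariance between
areas a monotone decreasing function C(D) of the distance between their
representative points, and θ̂ᵢ = θᵢ + εᵢ with E εᵢ = 0, Var εᵢ = vᵢ,
errors independent across areas. Under a Poisson count model with
error-free populations, the delta method gives vᵢ ≈ 1/dᵢ; with dᵢ = 0 the
log-rate is undefined and vᵢ = ∞, which the table represents explicitly
(rows are retained, never dropped).

The predictor at any locality x₀ is θ̂₀ = Σ wᵢ θ̂ᵢ with Σ wᵢ = 1; the
minimum-variance weights solve the bordered system whose off-diagonal
entries are C(Dᵢⱼ), right-hand side C(Dᵢ₀) and 1, and whose diagonal
distinguishes the flavors:

| flavor | diagonal | behaviour at a centroid |
|---|---|---|
| stabilized | τ² + vᵢ | shrinkage proportional to vᵢ |
| traditional | τ² | exact interpolation (no stabilization) |
| nugget-adjusted | τ² + c₀ | uniform smoothing for all areas |

The predicted rate is exp(θ̂₀). Weights may legitimately be negative; they
are never clamped.

**Infinite variance.** As vₖ → ∞ the weight wₖ → 0 exactly, so zero-case
areas are removed from the linear system (rows/columns deleted) rather
than approximated by a large finite variance. This is the exact limit and
avoids ill-conditioning; a test confirms that dropping a zero-case row
changes no prediction bit.

**Linear algebra.** The bordered matrix is symmetric indefinite; it is
LU-factorized once (partial pivoting) and reused for all targets, so a
whole mesh costs one factorization plus one multi-RHS triangular solve. If
the condition number exceeds 1e12 a single shot of diagonal jitter
(1e-10 × sill) is tried with a warning; a condition number near 1/machine-ε
(duplicate representative points with equal diagonals) raises immediately.

## Semivariogram

For the m areas with defined log-rates, the cloud holds m(m−1)/2 points
(Dᵢⱼ, (θ̂ᵢ−θ̂ⱼ)²/2). A spherical model γ(h) = c₀ + c(1.5h/a − 0.5(h/a)³)
for h ≤ a, flat at the sill c₀+c beyond, is fitted under box constraints
c₀, c ≥ 0, a > 0. The covariance function is C(h) = sill − γ(h).

**τ² at the origin.** A fitted spherical model is discontinuous at 0 when
c₀ > 0 (γ(0) = 0 by definition, γ(0⁺) = c₀). We evaluate γ(0) = 0 exactly,
so τ² = C(0) = c₀ + c: the nugget contributes to the between-area
variance, the stabilized diagonal τ²+vᵢ is at least the sill, and the
traditional flavor reproduces ordinary kriging exactly when c₀ = 0. The
alternative τ² = c is exposed as `tau2_mode="partial_sill"` for
sensitivity analysis.

**Fitting.** The range parameter is a notorious local-minimum trap, so the
fit profiles it: for each of 24 candidate ranges (log-spaced between the
smallest and largest nonzero distance) the nugget and partial sill solve a
2-parameter non-negative linear least-squares problem in closed form; the
best profile point seeds one bounded trust-region polish of all three
parameters. Ties break by residual sum of squares, then smaller range; the
procedure is deterministic and invariant to pair order. Two targets are
supported: `cloud` (unweighted fit to all pairs — used inside the
simulation harness) and `binned` (count-weighted fit to 15 equal-width bin
means up to half the maximum distance — the robust default for real
data). A flat all-zero cloud (all usable log-rates equal) returns the
degenerate model (0, 0, max distance) with a warning, and kriging then
returns the common value everywhere; all pairwise distances identical is
an error (range unidentifiable). No down-weighting of pairs involving
high-variance areas is applied.

## Empirical-Bayes comparators

1. **DerSimonian–Laird (distribution-free).** Moment estimator:
   μ_FE = Σθ̂ᵢ/vᵢ / Σ1/vᵢ, Q = Σ(θ̂ᵢ−μ_FE)²/vᵢ,
   τ̂² = max(0, (Q−(m−1)) / (S₁−S₂/S₁)) with S₁ = Σ1/vᵢ, S₂ = Σ1/vᵢ²,
   then μ̂ re-estimated with weights 1/(vᵢ+τ̂²). Posterior log-rate:
   precision-weighted average of θ̂ᵢ and μ̂. Zero-case areas are excluded
   from hyperparameter estimation and receive the fully shrunk value μ̂
   (the v → ∞ limit of the posterior). Agreement with the statsmodels
   meta-analysis implementation is tested to 1e-10.
2. **Poisson-gamma.** rᵢ ~ Gamma(shape α, rate ν), dᵢ ~ Poisson(pᵢrᵢ);
   the marginal is negative binomial and (α, ν) are fitted by L-BFGS-B on
   (log α, log ν) with the analytic gradient, started from moment
   estimates. Posterior mean rate: (dᵢ+α)/(pᵢ+ν) — zero-case areas get
   α/(pᵢ+ν) > 0 naturally. The prior is parameterized as (shape, rate) so
   the conjugate update is literal; the fitted prior mean α/ν is invariant
   to the scale-vs-rate choice. Underdispersed data (between-area variance
   below Poisson noise) degenerate the prior: the fit returns
   near-complete shrinkage with a warning.
3. / 4. **Local variants.** Hyperparameters for each area are re-estimated
   from the area plus its k = 15 nearest areas (representative-point
   distance, same metric as kriging; distance ties broken by table order);
   only the centre area's stabilized value is kept. A failed local fit
   falls back to the global fit for that area with a warning.

## Direct age standardization

DASIR = Σₐ wₐ dₐ/pₐ under a standard population with weights summing to 1
(the WHO 2000 World Standard ships in 5-year bands 0–4 … 85+; its printed
percentages sum to 100.03 and are renormalized). With Poisson stratum
counts, Var(DASIR) = Σₐ wₐ² dₐ/pₐ² and Var(log DASIR) = Var(DASIR)/DASIR²
by the delta method — the unique formula consistent with the v ≈ 1/d
derivation for crude rates, to which it reduces for a single stratum.
Zero total cases map to the infinite-variance marker, so standardized
tables feed stabilized kriging exactly like count tables.

## Synthetic study conditions

The Monte Carlo harness emulates a mid-size county split into LAAs:

- **Geometry.** 26 Voronoi cells of uniform random sites in a
  0.5° × 0.42° rectangle (the aspect of a Taiwanese county), representative
  points at cell centroids, and a 40 × 34 rectangular evaluation mesh
  (1360 points, all in-region since the boundary is the rectangle). The
  mesh size is a deliberate compromise: SMAPE is a mesh average, and its
  Monte Carlo mean stabilizes long before mesh refinement matters.
- **Surfaces.** Log-rate peaks at −6.725 (120 per 10⁵) decaying by a
  Gaussian in distance to a floor of −7.725 (44.16 per 10⁵). Bandwidths:
  σ = 0.25 × the bounding-box diagonal for the slow mode and 0.10 × for
  the rapid mode — chosen once so the slow surface spans most of the
  region while the rapid one is clearly sub-regional. The double mode
  averages two rapid single-centre surfaces (each anchored at the full
  θ range), so its realized peak is below −6.725 unless the centres
  coincide. Hotspot centres are drawn uniformly from the full mesh;
  a switch restricts them to in-region points.
- **Populations.** Log-normal, moment-matched to mean ∈ {100000, 50000,
  25000} and CV ∈ {0.1, 0.5, 1.0} (σ_L² = ln(1+cv²),
  μ_L = ln mean − σ_L²/2).
- **Counts.** Poisson with expectation population × rate at the LAA
  centroid.
- **Scoring.** SMAPE = 100 × mean over in-region mesh points of
  |r̂−r|/(r̂+r), bounded in [0, 100]. LAA-based methods (raw rate, EB)
  paint each mesh point with its area's value; for the Voronoi geometry
  the point-to-area map is a nearest-site lookup, computed once. Kriging
  methods predict each mesh point. All eight methods score the same
  replicate data; the per-replicate variogram is fitted in `cloud` mode
  with a `binned` fallback on failure. One master seed spawns independent
  per-replicate streams, so runs are pure functions of (seed, region).

What the generator does **not** emulate: irregular real administrative
polygons (concave shapes, enclaves, islands), spatially correlated
population sizes, age structure, covariate-driven risk, or barriers to
spatial continuity. Passing the Monte Carlo ordering tests therefore shows
the estimators behave as designed under the stated random-field + Poisson
conditions, not that stabilized kriging dominates on any particular real
map.

## Problem sizes and tolerances

Acceptance-grade checks run 500 replicates per scenario over the full
3 surfaces × 9 population scenarios on the 26-LAA region; the bundled
results script uses 300 replicates per scenario. Solver agreement with an
independent null-space quadratic-programming oracle is required to 1e-8;
exact-interpolation and sum-to-one identities to 1e-10; the
vanishing-variance limit (stabilized ≡ traditional) to 1e-12 in sup-norm.
Parameter-recovery checks (DL, Poisson-gamma, noiseless variogram
inversion) use the tolerances stated in their tests.

## Known limitations

- Only the spherical semivariance model is built in, though the covariance
  interface is pluggable; no automated ("empirical Bayesian kriging")
  variogram estimation.
- Global kriging only: every finite-variance area enters each prediction;
  no local neighbourhood search. Fine at n ≤ a few hundred areas.
- No kriging prediction-variance maps, no universal kriging with
  covariates, no CAR/SAR comparators, and no barrier-aware distances.
- Whether distances for a lon/lat dataset should be degrees (euclidean on
  coordinates) or kilometres (haversine) is the caller's choice and is
  recorded in output metadata; only relative distances enter the
  variogram, but the choice is never guessed.
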