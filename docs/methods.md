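# Methods

## The problem

Standard automated perimetry (SAP) measures differential light sensitivity
(DLS, in dB; 0 = blind, ~35 = healthy) at 52 analysed locations of the
24-2 grid.  Detecting true deterioration in a series of such fields is
hard for two reasons: the measurement error is *non-stationary* — roughly
±3 dB at healthy levels but tens of dB, skewed, bimodal and censored at
0 dB once a location is damaged — and the field is *spatially correlated*
along retinal nerve-fibre bundles, which never cross the horizontal raphe.
Ordinary least-squares trend tests ignore both.

## Measurement model: per-level Weibull mixtures

Test–retest pairs (repeat fields taken over a window too short for real
change; the canonical design is 30 eyes x 12 tests = 30·C(12,2) = 1,980
test pairs) estimate the retest density at each integer DLS level 0..35.
Each level's retest distribution is fitted as a K-component mixture of
Weibull densities

    f(y; α, β) = (α/β)(y/β)^(α−1) exp(−(y/β)^α),   shape α, scale β (dB)

by expectation–maximisation: responsibilities in the E-step, closed-form
mixing weights and a 1-D root-find for each shape (closed-form scale given
shape) in the M-step, iterated to a 1e−8 log-likelihood tolerance with 5
jittered restarts.  K is grown from 1 and accepted while the held-out
log-likelihood improves across cross-validation folds at p < 1%
(one-sided paired t-test, 5 folds); on the synthetic retest study two
components suffice at mid-range levels, matching the on-target +
attention-lapse structure of the generator.

Because log-Weibull densities are undefined at 0, observed values pass
through a C1 floor transform: identity above 1 dB, exp(y−1) below —
continuous with matching first derivative at the knot and strictly
positive.

Numerical choices worth knowing:

* **Shape cap at 50.**  DLS is recorded in whole dB; unbounded shapes let
  EM collapse a component onto one tied integer value and degenerate the
  density.  A cap at 50 (CV ≈ 2.5%) is narrower than any real retest
  scatter.
* **PCHIP parameter interpolation.**  The regression needs p(y | μ) for
  continuous predicted level μ, so log-weights, log-shapes and log-scales
  are interpolated across levels.  Shape-preserving piecewise cubics
  (PCHIP) are used instead of natural cubic splines: spline overshoot
  between knots created spurious local optima in the regression
  objective.  The density is C1 in μ, which is all the optimiser needs.

## Trend model and spatial prior

Each location j follows μ_ij = intercept_j + slope_j·t_i; an observation
y_ij is a draw from the fitted retest density at μ_ij, independent across
measurements given the trends.  Predicted levels are squeezed into the
modelled [0, 35] dB range by a softplus clamp (sharpness 10) so the
objective stays differentiable when trends leave the range.

Slopes and intercepts carry multivariate-normal priors N(0·1, aΨ) and
N(17.5·1, bΨ) with a = b = 100, i.e. weakly informative marginal SDs of
10 dB/year and 10 dB, and an intercept mean at the middle of the
measurement range.  The correlation Ψ is anatomical:

    Ψ_pq = exp(−d_pq²/(2σ_d²) − θ_pq²/(2σ_θ²))   same hemifield,
    Ψ_pq = 0                                      across the midline,

with d_pq the grid distance (σ_d = 6°, one grid step) and θ_pq the
absolute difference in nerve-fibre entry angles at the optic nerve head
(σ_θ = 15°).  The kernel form and σ_θ are package choices exposed in the
configuration; the packaged entry-angle table is a synthetic
approximation (straight path from each location to the nerve head at
(+15°, 0°), with a small arcuate correction around the fovea) and can be
replaced by a measured map file.  A 1e−8 diagonal jitter guards positive
definiteness.  Zeroing the off-diagonal of Ψ gives the no-spatial variant
(ANSWER vs the full ANSWERS).

## Fitting: MAP with a basin scan, Laplace uncertainty

The 2M-dimensional log posterior is maximised by L-BFGS with analytic
gradients (the density derivative flows through the PCHIP coefficients
and the clamp).  Two non-standard steps deal with the fact that the
retest density is *multimodal in μ* — at every damaged level a
"lapse-reversion" mode sits near healthy sensitivity:

* **Initialisation by per-location grid scan.**  Each location's (slope,
  intercept) plane is scanned on a coarse lattice (slopes −5..5 by 0.5
  dB/yr, intercepts 0..40 by 1 dB) under likelihood plus the diagonal
  prior, landing every location in its best basin.  Least-squares starts
  (with or without shrinkage toward the prior mean) routinely strand
  healthy locations between basins.
* **Conditional basin rescan.**  After convergence, each location is
  re-scanned under its conditional prior given the others' current
  values; locations whose basin choice is beaten jump there and the
  ascent re-runs (at most twice).  This recovers joint modes that the
  independent initialisation misses once spatial coupling matters, and
  brute-force lattice search on two-location problems no longer beats
  the optimiser.

Stationary points with a finite-difference negative-curvature direction
are probed along the offending eigenvector and re-optimised (saddle
escape).

The posterior covariance is the Laplace approximation: inverse negative
Hessian at the mode.  The prior precision is exact; the likelihood
Hessian comes from central differences (step 1e−4) of the analytic
gradient, exploiting the fact that measurements couple slope_j and
intercept_j only within a location, so four gradient evaluations recover
all per-location 2×2 blocks.  Because the density is only C1 at integer
levels and modes often sit exactly on those knots, a block can read a
spuriously convex direction; each 2×2 likelihood block is therefore
projected onto the concave cone before the prior precision is added,
which keeps every marginal variance bounded by its prior value and the
result positive definite.

**Known limitation:** with the full mixture density the exact posterior
has fatter tails (and sometimes secondary modes) than the local
curvature; the Laplace slope SDs are then anti-conservative.  This is
intrinsic to the Laplace approach; the evaluation protocol absorbs the
absolute scale by calibrating decision thresholds on null data.

## Indices

Per location, Pnd = P(slope ≥ 0) = Φ(slope/SD) under the Laplace
marginal, clamped to [1e−300, 1].  Per eye,

    S_d = −Σ_j log Pnd_j,     S_i = −Σ_j log(1 − Pnd_j),

non-negative, additive over locations, larger = more certain
deterioration (resp. improvement).

## Evaluation protocol

Null behaviour comes from pseudo-series: per-eye random reorderings of
the repeat tests, truncated to each length, one test per assumed year.
The full design (30 eyes × 300 reorderings × lengths 3–12 = 90,000
series) is represented lazily; MAP-based scoring runs on scaled-down
subsets.  Decision thresholds are the empirical (1 − FPR) quantiles of
the null S_d scores, calibrated *per series length* (ties not flagged);
MD regression is calibrated the same way on its null p-values.  Methods
are compared at matched empirical FPR via hit rate (the proportion of
series flagged; at matched FPR a surrogate for sensitivity), the
normalised partial AUC of the hit-rate-vs-FPR curve over FPR ∈ [0, 0.15]
(divided by 0.15 so a perfect detector scores 1; a hit-rate-equals-FPR
detector scores 0.075), and time-to-detect (earliest flagged prefix,
minimum length 3; the full span if never flagged).

Problem sizes used by the packaged benchmark (`benchmark_methods`) and
the acceptance script: 30 null eyes with 4–5 reorderings per length
(≥ 100 null scores per length and method), a labelled cohort of 50–80
eyes (30% progressing, −1 dB/year in a connected 6-location cluster,
7 annual tests), and time-to-detect on a 24–40 eye subset.  These sizes
give stable directional comparisons; the absolute hit rates carry
binomial noise of a few percentage points.

## Synthetic data generator

The generator emulates the statistical structure the model assumes:

* healthy fields ≈ 33 dB centrally with a 0.12 dB/degree eccentricity
  fall-off and 1 dB eye-to-eye spread;
* 70% of eyes carry a connected same-hemifield damage patch (3–12
  locations, depth uniform 5–40 dB, clipped at 0), so test-retest pools
  cover the full 0–35 dB range including truly blind points;
* observations are two-component draws: an on-target Weibull whose
  median sits at the true level and whose shape falls from ~31 (healthy)
  to ~1 (blind) — giving a 90% retest interval of 7 dB at 32 dB,
  widening to ~12–30 dB at damaged levels — plus a 2–12% attention-lapse
  component reading near the floor; values are rounded to whole dB and
  censored into [0, 40].  Conditioning on a *measured* low baseline then
  reproduces the bimodal retest histograms of real perimetry (a blind
  spike plus a lapse-reversion mode near healthy sensitivity);
* progressing eyes decline linearly at a connected cluster from t = 0.

What it does not emulate: learning effects (handled in real data by the
curation rule that drops the first test), age-related decline in stable
eyes, per-visit reliability variation, floor effects of the instrument's
staircase, and long-range correlation of damage across hemifields.
Passing tests therefore demonstrate correctness of the estimators and
the direction of the method comparison under the model's own
assumptions, not clinical performance.

## Degenerate inputs and edge policies

* Series need Q ≥ 3 tests; missing per-location values are rejected.
* Constant-response OLS fits report p = 1.
* An empty series contributes zero log-likelihood, making the prior the
  posterior (used by the pure-prior Laplace identity test).
* Pnd of exactly 0 or 1 is floored/capped at 1e−300 from either side
  before logs; a location can contribute at most ~690 to either index.
* Tie scores at a decision threshold are conservatively not flagged.
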