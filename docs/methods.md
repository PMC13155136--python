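# Methods

## Model

A limiting dilution assay records, for each expected seeding density `S`
(cells per well) in a geometric ladder, the number `Y` of `n` replicate
wells without clonogenic growth. Conditional on a per-well mean number of
clonogenically active cells `λ(S)`, the number of active cells in a well is
taken as Poisson, so the per-well failure probability is `μ(S) = e^{−λ(S)}`
and `Y ~ Binomial(n, μ(S))` independently across dilutions.

The package models the mean as a power law,

    λ = p · S^b,      α = ln p,      ln(−ln μ) = α + b · ln S,

a binomial GLM with log–log link on failures. `b = 1` is the classical
single-hit model (each cell founds a colony independently with probability
`p`); `b > 1` captures cooperative growth (per-capita clonogenicity rises
with density, the in-vitro analogue of an Allee effect); `0 < b < 1`
captures competition. Because `p` and `b` are coupled, the model reports no
"clonogenic frequency"; the primary readout is the clonogenic activity
`a = e^{−α/b}`, the seeding density at which `λ = 1` and hence `μ = 1/e`.

Assumptions worth stating: wells are exchangeable within a dilution;
dilutions are independent given the parameters; every well receives exactly
the expected cell number `S` (no Poisson seeding noise); no extra-binomial
dispersion. Overdispersed or mixed-effects extensions are out of scope.

## Estimation

`LimitingDilutionModel.fit` maximizes the exact binomial likelihood by
Fisher scoring (IRLS) with step halving, using the analytic score and
expected information of the log–log link. Boundary counts `Y ∈ {0, n}`
enter the likelihood as-is — no continuity correction — via
`log(−expm1(−λ))` for the growth term, which is accurate when `λ → 0`.
Starting values come from least squares on the link-transformed interior
points (`0 < Y < n`); the fixed-slope variant (`b = 1`) estimates `α` alone
with `ln S` as offset.

Numerical choices:

* convergence when the score infinity-norm falls below 1e-8, at most 100
  iterations; link values are clipped to ±30 during iteration so boundary
  ridges cannot overflow;
* the reported covariance is the inverse **expected** Fisher information at
  the optimum — the quantity standard GLM software reports through its final
  IRLS weights. (Observed and expected information differ for this
  non-canonical link; interval coverage under the expected choice is
  verified by simulation in the test suite.)
* degenerate data: if no well grows anywhere, estimation is refused outright
  (`EstimationRefusedError`) — under this model an all-negative condition
  carries no information to separate `p` from `b`, and any number would be
  arbitrary. Quasi-separated data (e.g. every well positive, or all-negative
  below some dilution and all-positive above it with at most one interior
  point) drive the likelihood toward a ridge at infinite parameters; the
  gradient underflows on the ridge, so convergence is additionally diagnosed
  through the fitted rates: a fit whose smallest fitted `λ` over the
  observed dilutions is numerically 0 (< 1e-8, certain failure claimed) or
  numerically certain growth everywhere (smallest `λ` > −ln 1e-8 ≈ 18.4) is
  flagged `converged=False` with a warning, and downstream estimators refuse
  it.

Deviance is twice the log-likelihood gap to the saturated model
(`μ_i = Y_i/n_i`), AIC is `−2ℓ + 2k`, and the nested comparison against the
fixed-slope model is a likelihood-ratio test on the deviance difference with
one degree of freedom, reported alongside ΔAIC.

## Confidence intervals

**Activity.** The default interval inverts the link-scale confidence band:
the band `α̂ + b̂x ± z·sd(x)` (with `x = ln S` and
`sd²(x) = Var(α) + 2x·Cov(α,b) + x²·Var(b)`) crosses zero — i.e. `μ = 1/e` —
at the roots of the quadratic

    (b̂² − z²Var(b))·x² + 2(α̂b̂ − z²Cov(α,b))·x + (α̂² − z²Var(α)) = 0,

a Fieller-type construction; the exponentiated root pair bracketing `ln a`
is the interval. When the leading coefficient is non-positive the slope is
not significantly distinct from zero and the band never re-crosses the 37%
line on one or both sides; the affected bound is reported as 0 or ∞ with a
warning rather than invented. A delta-method alternative propagates
`Var(ln a) = Var(α)/b² + α²Var(b)/b⁴ − 2αCov(α,b)/b³`; the two agree
closely once wells per dilution are large (the tests check < 2% relative
difference at n = 10⁴).

**Survival fractions.** `SF_t = a_0/a_t`. Its 95% interval combines the
83.5% activity intervals of numerator and denominator as
`(a0_lb/at_ub, a0_ub/at_lb)` — the standard combination level for a ratio
of approximately independent estimates; simulation in the test suite
confirms ~95% coverage. Both levels are named constants, not magic numbers.

**Replicates.** Two explicit modes, chosen by the user rather than
automatically: `pooled` sums well counts across biological replicates at
matched dilutions (S matched exactly after rounding to 6 decimals —
dilution series are specified values, not measurements) before fitting;
`per_replicate` computes activities and SFs within each replicate (each
against its own reference fit) and summarizes by mean, SEM and a Student-t
interval with `r − 1` degrees of freedom — appropriate for the small
replicate counts (3–4) typical of these assays. The helper
`binomial_expectation_range` (exact equal-tail binomial quantiles by CDF
summation) quantifies the intrinsic stochasticity of a well count so users
can judge whether inter-replicate spread exceeds it; a zero lower count maps
to −∞ on the ln μ scale.

## Synthetic data generator

`simulate_lda` draws `Y ~ Binomial(n, exp(−p_t·S^b))` with a fixed stream
order (treatment-major, then replicate, then dilution) from a seeded
generator, so counts are bit-reproducible. Treatments are parameterized by
their true survival fraction: `p_t = p · sf_true^b`, which makes the
generating SF exactly `sf_true` for any `b`. Defaults mirror the standard
assay plate: ladder `2⁰…2⁷` cells/well, 12 wells per dilution (one 96-well
plate per condition), `p = 0.1`, `b = 1`.

The generator reproduces exactly the structure the model assumes — which is
the point for oracle tests, coverage studies and design exploration, and
also the limitation: it has no seeding-count noise, no plate or edge
effects, no inter-replicate biological variability and no overdispersion.
Passing coverage and recovery tests therefore validate the estimator under
its own assumptions; they do not certify behaviour on real data that
violates them (notably strong replicate heterogeneity, for which the
per-replicate mode exists). The latent active-cell count is never
materialized since `μ` depends on `λ` alone.

`design_grid` simulates experiments over a grid of wells-per-dilution and
informative-dilution counts and reports mean activity- and SF-interval
widths; each grid cell reuses the same spawned seed list so comparisons
across designs are paired.

## Problem sizes and verification

Stochastic checks in the test suite and the acceptance script use assay-
scale simulations chosen to keep Monte-Carlo error well below the asserted
tolerances while remaining quick: 200 simulated assays for recovery and
coverage studies, 500 for interval-coverage rates, 1000 for the
likelihood-ratio-test size, with 8 dilutions and 12–96 wells per dilution.
The fit itself is cross-checked against two independent oracles: a
dense-grid plus Nelder–Mead maximization of the same likelihood, and the
algebraically equivalent complementary-log-log binomial regression on
success counts (statsmodels), which must reproduce `α, b`, the covariance
and the deviance. The Fieller interval is checked against a numeric scan of
the band for its zero crossings.

A known small-sample property, visible in the acceptance output: at 12
wells per dilution with a narrow informative range, the MLE of `b` is
biased upward (about +0.12 at `b = 1.5` on the default ladder). This is a
property of the estimator itself — the independent GLM oracle reproduces it
to four decimals — and it vanishes with replication (mean b̂ within 0.005
of truth at 96 wells per dilution), which the consistency test asserts.

## Known limitations

* No overdispersion or random-effect structure; strongly heterogeneous
  replicates should use `per_replicate` mode rather than pooling.
* The capacity readout `100/a` is frequency-interpretable only when
  `b ≈ 1`; under cooperation or competition it is a convenience number, not
  a cell frequency.
* All-negative conditions are refused by design, and quasi-separated data
  yield flagged, non-converged fits; both are surfaced in output tables
  (`refused_reason`) rather than dropped.
* The LRT against `b = 1` is slightly anticonservative at 12 wells per
  dilution (empirical size ≈ 6% at nominal 5% in the acceptance output), a
  consequence of the χ² approximation on small discrete samples.
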