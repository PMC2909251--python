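# Methods

## Problem and estimand

A two-arm trial records, per participant, binary indicators for each of two
components of a composite endpoint. Component outcomes within a participant
are positively correlated (a participant who has an MI is more likely also
to die of cardiovascular causes). Composite *heterogeneity* means the
treatment odds ratio differs between components. In the interaction model

logit P(y_ijk = 1) = β₀ + β₁x₁ + β₂x₂ + β₃x₃,  x₃ = x₁x₂,

β₃ = ln(OR₂/OR₁) and the two-sided Wald test of β₃ = 0 is the heterogeneity
test; the main treatment effect on the composite is tested on the collapsed
participant-level indicator max(y₁, y₂).

## Scenario design arithmetic

A scenario is (n, allocation, R, ρ, OR₁, OR₂, r, α) with defaults
n = 2000, 1:1 allocation, control composite rate R = 0.50, within-participant
correlation ρ = 0.10 (a value typical of major cardiovascular component
pairs), α = 0.05, and balanced components r = p₁:p₂ = 1. These defaults are
the conditions of the simulation study the package reproduces.

Control-arm component marginals solve p₁ = r·p₂ subject to the exact union
constraint p₁ + p₂ − p₁₁ = R, where the joint probability follows from the
Pearson correlation of two Bernoullis, p₁₁ = p₁p₂ + ρ√(p₁q₁p₂q₂). The
solver bisects on p₂ (tolerance 1e−10, ≤200 iterations) inside the
Fréchet-feasible interval and raises a named error when ρ or R is
unattainable at the requested ratio. For r = 1 the solution has the closed
form of a quadratic root, which the tests use as an oracle. Treatment-arm
marginals apply OR₁, OR₂ to the control marginal odds; ρ is held at the same
value in both arms.

Analytic design power uses the continuity-corrected two-proportion normal
approximation with the *pooled* variance of the chi-square statistic,

z = (|p_c − p_t| − (1/n_c + 1/n_t)/2) / √(p̄q̄(1/n_c + 1/n_t)),
power = Φ(z − z_{1−α/2}).

The pooled form is what a chi-square test of equal proportions actually
inverts, and it reproduces the 88% / 97% design powers of the reference
2000-participant design at their printed rounding (the unpooled variant
gives 88.6 / 97.6, which rounds wrong).

## Correlated-binary generator

Binary pairs come from shared Poisson sums: draw independent A₁ ~ Poi(λ₁),
A₂ ~ Poi(λ₂), A₁₂ ~ Poi(α₁₂); set Z_k = A_k + A₁₂ and Y_k = 1{Z_k = 0}.
Then P(Y_k = 1) = e^{−(λ_k+α₁₂)} and choosing total rates −ln p_k with
α₁₂ = ln(1 + ρ√(p₁q₁p₂q₂)/(p₁p₂)) matches the target marginals, joint
probability, and correlation exactly. Mapping the event to the *zero* count
gives these closed-form rates; the opposite coding reproduces the same
moments, so downstream results are insensitive to the choice. The
construction only reaches ρ ≥ 0, which covers the composite-outcome use
case. Per-replicate RNG streams are spawned from a master `SeedSequence`, so
runs are reproducible and replicates independent; an inverse-CDF mode draws
the three Poisson counts from common uniforms so that scenarios can share
random numbers (used for monotonicity checks).

What the generator does *not* emulate about real trials: covariates,
censoring/follow-up asymmetry, more than two components, negative component
correlation, or between-participant heterogeneity beyond the exchangeable
pair correlation. Passing tests therefore show the estimators' operating
characteristics under exchangeable correlated Bernoulli pairs, not
robustness to those richer features.

## Estimation details

**Logistic (IRLS).** Newton iterations on the (optionally weighted)
Bernoulli likelihood to gradient norm < 1e−8, ≤100 iterations; covariance is
the inverse observed information with weights treated as frequency weights.
Separation or divergence is reported as `converged = False` rather than an
exception, and such replicates are excluded from that model's Monte-Carlo
denominator (counting them as non-rejections would bias power; in practice
non-convergence is absent at the study's sample sizes).

**ANOVA ICC and weighted fits.** With clusters of size m = 2,
ρ̂ = (MSB − MSW)/(MSB + MSW), kept in [−1, 1]. Negative estimates are
deliberately retained: the estimator pools the two component means, so
strong component imbalance inflates MSW and drives ρ̂ below zero even when
the true pair correlation is +0.10. The Donald–Donner fit weights every row
by 1/(1 + ρ̂) (guarded at ρ̂ ≥ −0.9); the Rao–Scott fit weights each arm by
the reciprocal of its design effect — the ratio of the empirical variance of
participant event totals to binomial variance, floored at 0.1. Keeping
weights > 1 when ρ̂ < 0 (or the design effect < 1) is what lets the weighted
models *beat* independent logistic under 1:5 imbalance, the documented
exception in the power ordering; truncating at the null value would collapse
them onto the independent fit there.

**GEE.** Fisher scoring on the estimating equations over participant
clusters, logit link, cluster size 2. The unstructured working correlation
(one off-diagonal parameter) is re-estimated each iteration as
Σᵢ eᵢ₁eᵢ₂/(N − p) from Pearson residuals (N clusters, p = 4). Convergence at
coefficient change < 1e−8; covariance is the robust sandwich. With the
independence working structure the estimating equations coincide with the
logistic score, so coefficients match IRLS exactly while the sandwich SE
differs — a property the tests assert, alongside agreement with an
independent GEE implementation to ~1e−8.

**Random-intercept logistic.** The marginal likelihood integrates
γᵢ ~ N(0, σ²) out of each cluster by adaptive Gauss–Hermite quadrature
(default 15 nodes; nodes recentred at the per-cluster mode found by Newton
and rescaled by the curvature there). Because the design matrix depends only
on the arm, clusters collapse to ≤8 (arm, y₁, y₂) types, making the
likelihood cheap at any n. Optimization is L-BFGS-B over (β, σ) with
σ ≥ 1e−8; the covariance is the β-block of the inverse observed information
(central differences, step 1e−4·max(1, |θ|)); when σ̂ sits at the boundary
the information is taken over β alone and σ² is reported as 0. The quadrature
agrees with dense trapezoid integration to <1e−6 in log-likelihood on toy
data.

**Main-effect test.** Default `collapsed_chisq`: participants collapse to
the composite indicator and the arms are compared by the continuity-corrected
chi-square test — the test the design power refers to, and the variant whose
simulated power (~70% at the (0.65, 1.00) scenario) tracks the analytic
design arithmetic. The alternative `gee_no_interaction` Wald-tests β₁ in a
GEE without the interaction term; it pools component-level information and
is systematically more powerful (~80% at the same scenario) because it tests
a different null vehicle, not because it is a better composite test. Both
are exposed.

## Monte-Carlo study

`run_scenario` simulates replicates, fits the requested models, and tallies
Wald rejections; `table1_grid`/`table2_grid`/`table3_grid` return the
published scenario sweeps (OR₂ from 0.65 to 1.20 at OR₁ ∈ {0.65, 0.70,
0.75}; balance ratios 1:1, 1:3, 1:5, 3:1, 5:1). Default replication is 2000
per cell (5000 for type-I-error estimation, 1000 for the random-effects
model in the reproduction suite) — a desk-scale choice relative to the
original 10,000; every tally carries its Monte-Carlo standard error
√(p(1−p)/n) so comparisons are made at multiples of it.

## Known limitations

- Two components only in the shipped grids; the model code accepts the
  long-format layout but the design solver and generator are pairwise.
- No negative within-participant correlation (generator constraint).
- Under strong component imbalance the simulated powers run ~3–4 points
  above the reference values for all models at 1:5; the offset disappears if
  the component marginals are instead recovered from the independence union
  formula p₁ + p₂ − p₁p₂ = R, suggesting that approximation underlies the
  reference numbers. The package keeps the exact solver — it is the only
  reading under which the control composite rate equals its stated 50% — and
  the reproduction suite documents the two affected checks as expected
  failures of this parameterization difference, while the qualitative
  finding (weighted models overtake the GEE at 1:5) reproduces.
- The random-intercept model reports the conditional (subject-specific)
  coefficient scale; its β₃ is attenuated toward the marginal scale only as
  σ² → 0. Comparisons across models are of test decisions, not estimates.
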