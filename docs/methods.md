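# Methods

## Problem and estimand

Two randomized trials form an anchored network: the IPD trial compares
active treatment A with a common comparator C; the ALD trial compares
active treatment B with C but is observed only through published
summaries (pooled covariate means and SDs, per-arm sample sizes and event
counts). The estimand is the **marginal** A-vs-B log odds ratio in the ALD
trial population. Because the odds ratio is non-collapsible, the marginal
effect differs from any conditional (covariate-adjusted) coefficient even
under randomization, so every estimator here produces a population-average
contrast: the B-vs-C log odds ratio is computed directly from the ALD 2×2
counts, and the A-vs-C contrast is transported to the ALD population
before anchoring.

## Estimators

**Bucher.** `d_AC − d_BC` from the two crude 2×2 tables; variances add.
No adjustment — biased when effect modifiers are imbalanced, but a useful
stability floor.

**MAIC.** Trial-assignment odds are modeled log-linear in the covariates,
`w_i = exp(α'x_i)`; combined with the mean-balancing constraint this is
the unique minimum of the convex objective `Q(α) = Σᵢ exp(α'(xᵢ − x̄_ALD))`.
We minimize `Q` by damped Newton iteration with analytic gradient and
Hessian (covariates centered at the target and standardized; gradient
tolerance 1e-10, balance tolerance 1e-6 on the standardized scale; a
quasi-Newton line-search fallback handles degenerate Hessians). An
infeasible target — outside the convex hull of the IPD — is reported as
`converged=False`, never an exception, since bootstrap resampling
routinely produces such datasets. The point estimate is the weighted
logistic regression of outcome on treatment (closed form via the weighted
2×2 table), anchored by the ALD contrast; the SE is the SD of
nonparametric bootstrap replicates (resample rows, re-estimate weights
against the fixed ALD means, re-estimate). Failed replicates are dropped
and counted; if more than half fail the SE is flagged unreliable.
Matching is on first moments only; the Kish ESS `(Σw)²/Σw²` and its
reduction are reported as the overlap diagnostic.

**Bayesian outcome regression.** Logistic model with treatment, main
covariate effects, and treatment-covariate interactions; independent
Normal(0, 10²) priors. Covariates are *not* internally centered or scaled:
the coefficients must stay on the data scale because marginalization
evaluates the model on covariate profiles of the target population. Two
backends: an affine-invariant ensemble MCMC sampler (differential-
evolution moves, walkers initialized around the posterior mode, burn-in
1500 steps, thinning 8; the fit aborts if any parameter's split-chain
scale reduction exceeds 1.05) and a Laplace approximation (penalized-ML
mode with inverse-Hessian covariance) used by the simulation harness,
where ~12-parameter logistic posteriors at n ≥ 100 are close to normal.
Large-sample equivalence of the two backends is tested.

**Parametric G-computation.** One fixed population of `n_star = 1000`
profiles is simulated from a parametric family moment-matched to the ALD
summaries — multivariate normal, or a Gaussian copula with Gamma
marginals ("mvgamma"); the correlation matrix is borrowed from the IPD
sample correlation since publications rarely report one. Per posterior
draw, marginal event probabilities under each treatment are averages of
model predictions over that population and the draw's contrast is the
difference of marginal logits. Draws whose marginal probability is exactly
0 or 1 (infinite logit, possible when extreme coefficients meet an
extrapolated population) are dropped and counted; the estimate is invalid
if fewer than two draws survive. The mis-specified variant deliberately
swaps families (Gamma population under the normal truth and vice versa).
For binary covariates the mvn family treats the column as continuous with
SD `sqrt(p(1−p))` when none is reported, while the mvgamma family draws
them as copula-thresholded Bernoulli variables.

**G-MAIC.** Same outcome model and full-sample MAIC weights, but the ALD
population is represented by the reweighted IPD itself. The Bayesian
bootstrap supplies the uncertainty of that representation: with
pseudo-frequency concentration `a = n·w̃` (total concentration n, reducing
to the standard Bayesian bootstrap under uniform weights), each posterior
draw is paired with a fresh `π ~ Dirichlet(a)` and the marginal means are
`μ_t = Σᵢ πᵢ p_t(xᵢ)`. Point and SE are the mean and SD of the per-draw
anchored contrasts. An optional tempering exponent `γ ∈ (0,1]` replaces
`w̃` with `w̃^γ` (re-normalized), strictly increasing the ESS of the
concentration vector when weights are non-uniform. We note that the effect
of tempering on the SD of the contrast draws is *data-dependent*: the two
marginal means share each Dirichlet draw, so much of the weight
fluctuation cancels in the logit contrast, and in our experiments
tempering does not uniformly widen the posterior spread. It is exposed as
an analyst option, default off.

For both Bayesian methods the anchored point estimate is
`mean(Δ) − d_BC` and the reported variance is `SD(Δ)² + se(d_BC)²`: the
ALD trial's sampling error enters additively since the ALD event counts
are not modeled jointly. Intervals are Wald, mean ± 1.96·SE, for
comparability with the frequentist methods.

## Data-generating process

Each replicate simulates both trials from a shared logistic outcome model
with five covariates that are simultaneously prognostic (log-OR 0.5 each)
and effect-modifying (interaction log-OR 1.0 each, identical for both
active treatments). The conditional treatment effect is `log(0.25)` — a
75% reduction in baseline odds — for both A and B, so the marginal A-vs-B
effect in any population is exactly zero; this design-implied truth is
verified by `true_marginal_effect` on a 10⁶ cohort. The intercept is
solved numerically so the BC-population comparator arm has a 35% marginal
event rate (a mid-range rate avoiding boundary degeneracy; configurable).
Arms are allocated 1:1 by exact block assignment to remove arm-size noise.
The ALD trial size is fixed at 600 (a typical phase-III scale); IPD sizes
are 100, 200, 600.

Covariate structures:

* **normal** — multivariate normal, means 0.6, SDs 0.2, exchangeable
  correlation 0.2. Under this structure the log-linear assignment model
  implicit in MAIC is correctly specified.
* **nonnormal** — three skewed continuous covariates (Gaussian copula,
  Gamma marginals with shape 2 and scale matched to the target mean, so
  the SD is mean/√2) plus two binary covariates defined by thresholding a
  noisy quadratic of the first covariate (`±4(x₁−0.6)² + N(0,0.5²)`
  against a quadrature-solved threshold hitting a 50% marginal rate).
  The quadratic dependence cannot be represented by any log-linear
  weighting model, which is precisely what destabilizes MAIC.

**Overlap calibration.** Population overlap is governed by shifting the
AC-trial covariate locations (means, and binary probabilities in the
nonnormal structure) downward by a single offset per overlap level. The
operative definition of overlap is the mean ESS reduction of the
mean-matching weights at n = 600, targeted at 82.7% / 55% / 31% for
poor / moderate / high. For the normal structure exponential-tilt theory
gives the closed-form fraction `exp(−δ'Σ⁻¹δ)`; the shipped constants are
finite-sample refinements obtained by bisecting the simulated mean
reduction (200 replicates), and the same simulation-based calibration
produced the nonnormal offsets (the calibration routine ships as
`calibrate_overlap_shift`). The realized reductions are within ~1
percentage point of target; a property test enforces ±10.

## Performance measures

Per scenario and method over `n_sim` replicates: bias, empirical SE
(SD of estimates), model-average SE (arithmetic mean of reported SEs),
and 95% Wald coverage of the true effect 0, each with its standard Monte
Carlo SE (`EmpSE/√n`, binomial, `EmpSE/√(2(n−1))`). Replicates whose
estimate is invalid — weight estimation failed, weighted separation, or
all posterior draws degenerate — are excluded complete-case within method
and counted, with bootstrap-level failures reported separately.
Replicates are seeded by spawned child streams of one integer seed, so
results are reproducible and order-independent.

## Problem sizes used in shipped checks

The package's own verification runs are scaled for a single CPU: 500
replications per examined scenario (Monte Carlo SE on coverage ≈ 1
percentage point), L = 500–1000 posterior draws via the Laplace backend,
bootstrap size 200 in the stress scenario, and full 1000-draw MCMC only in
unit tests. The full-scale study (2000+ replications, MCMC posterior,
1000 bootstrap replicates) is available through `gmaic simstudy`.

## What the synthetic benchmark does and does not show

The generator reproduces the qualitative mechanisms that matter for these
estimators — non-collapsibility, mean-imbalanced effect modifiers,
calibrated overlap, a dependence structure that breaks log-linear
weighting — under a known zero truth. It does not emulate measurement
error, missing data, reporting heterogeneity in published baselines
(e.g., medians instead of means), multi-arm trials, or survival outcomes;
conclusions about those settings cannot be drawn from passing tests.
Known limitations inherited from the methods themselves: G-MAIC never
extrapolates beyond the IPD covariate space, so under very poor overlap
its intervals can undercover; parametric G-computation extrapolates but
depends on the assumed covariate family and the borrowed correlation; the
ALD-side variance treatment (sum of variances) is an approximation rather
than a joint model.
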