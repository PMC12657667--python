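# gmaic — population-adjusted anchored indirect treatment comparisons

Health technology assessments must often compare two active treatments, A
and B, that were never tested head-to-head: each was compared with a common
comparator C in its own randomized trial. The sponsor typically holds
individual participant data (IPD) for its own A-vs-C trial but only the
published aggregate summaries (ALD: covariate means/SDs, arm sizes, event
counts) of the B-vs-C trial. When effect modifiers are distributed
differently across the two trial populations, the naive anchored contrast
is biased, and a population adjustment is needed.

This package implements, for binary outcomes on the (marginal) log
odds-ratio scale, the main estimators in that setting and the simulation
machinery to benchmark them:

* **Bucher's method** — the unadjusted anchored contrast
  `d_AB = d_AC − d_BC` with summed variances.
* **MAIC** (matching-adjusted indirect comparison) — weights
  `w_i = exp(α'x_i)` solved from the mean-balancing constraint
  `Σ w_i x_i / Σ w_i = x̄_ALD`, a weighted logistic regression of outcome
  on treatment, and a nonparametric bootstrap SE.
* **Bayesian parametric G-computation** — a logistic outcome model
  `logit P(y=1|x,t) = β₀ + β_t t + x'β₁ + t·x'β₂` fitted on the IPD,
  marginalized over a parametric covariate population simulated from the
  ALD moments; per posterior draw `Δ⁽ˡ⁾ = logit(μ₁⁽ˡ⁾) − logit(μ₀⁽ˡ⁾)`.
* **G-MAIC** — the same outcome model, but marginalized over the
  *reweighted IPD* instead of a parametric population: per posterior draw,
  Bayesian-bootstrap weights `π⁽ˡ⁾ ~ Dirichlet(n·w̃)` (pseudo-frequencies
  from the normalized MAIC weights) are attached to the observed covariate
  profiles, propagating the uncertainty of the population approximation
  without parametrizing the ALD covariate distribution.

A synthetic data-generating process (five jointly prognostic and
effect-modifying covariates, normal and skewed/binary structures, three
calibrated population-overlap levels) and an ADEMP-style harness (bias,
empirical/model SE, coverage, with Monte Carlo SEs) reproduce the
benchmark conditions under which MAIC destabilizes and G-MAIC does not.

## Worked example

Simulate a two-trial network (n_ipd = 200, moderate overlap, normal
covariates — the true A-vs-B effect is 0 by design), write the IPD CSV and
ALD YAML, and run every estimator:

```python
import numpy as np
from gmaic import ScenarioConfig, aggregate_ipd, write_ald, write_ipd
from gmaic import dgp_scenarios as dgp

rng = np.random.default_rng(4)
cfg = ScenarioConfig(n_ipd=200, overlap="moderate", structure="normal")
write_ipd(dgp.simulate_trial(cfg, "AC", rng), "demo_ipd.csv")
write_ald(aggregate_ipd(dgp.simulate_trial(cfg, "BC", rng)), "demo_ald.yaml")
```

```bash
gmaic maic  demo_ipd.csv demo_ald.yaml --n-boot 200 --seed 1
gmaic gmaic demo_ipd.csv demo_ald.yaml --posterior laplace --seed 1
```

The `maic` call prints (abridged):

```json
{"method": "maic", "estimate": 0.1449, "se": 0.4140,
 "ci": [-0.6665, 0.9564], "ess": 83.44, "ess_reduction": 0.583,
 "boot_failures": 0, "weights_converged": true}
```

and `gmaic`:

```json
{"method": "gmaic", "estimate": 0.4154, "se": 0.4162,
 "ci": [-0.4004, 1.2312], "n_draws": 1000, "degenerate_draws": 0,
 "ess": 83.44}
```

Reading the output: the ESS of 83 out of 200 (a 58% reduction) quantifies
the moderate population overlap; both adjusted estimates carry SEs of
about 0.41 on the log odds-ratio scale and both 95% intervals cover the
design-implied truth of zero. `bucher` and `gcomp` subcommands emit the
same JSON schema, and `gmaic simstudy` runs the full 18-scenario benchmark
(`--reps`, `--methods`, `--posterior laplace` for speed).

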