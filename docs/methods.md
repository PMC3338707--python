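# Methods

## Empirical power by simulation

Statistical power is estimated by its definition: generate `n_sim`
independent datasets from a fully specified alternative, analyze each one
with the model the real trial will use, and report the fraction of analyses
that reject the null hypothesis of no treatment effect. The rejection rule
throughout is whether the two-sided (1 − alpha) confidence interval for the
treatment effect excludes zero; an endpoint exactly at zero counts as
covering (fail to reject), a measure-zero convention fixed for determinism.
With 1000 replicates the Monte-Carlo standard error of a power near 0.5 is
about 0.016 and near 0.9 about 0.009; every `PowerResult` carries a Wilson
95% interval for this uncertainty, which has better small-count coverage
than the Wald interval.

## Data-generating model

All outcomes come from a cluster-level GLMM with linear predictor
`eta_ijk = pi_j + theta X_jk + b_k` and `b_k ~ N(0, sigma_b^2)`. No
individual-level covariates enter the model: at the design stage a
cluster-randomized study is conventionally powered on cluster-level
variables only, which also makes cluster-period aggregation loss-free.

Family-specific pieces:

* **Gaussian** (identity link): `Y = eta + e`, `e ~ N(0, sigma_w^2)`.
  The user supplies any two of `(sigma_b^2, sigma_w^2, ICC)`; the identity
  `ICC = sigma_b^2/(sigma_b^2 + sigma_w^2)` completes the triple (enforced
  to 1e-12; an inconsistent fully specified triple is an error, not a
  silent override).
* **Binomial** (logit link): `Y ~ Bernoulli(expit(eta))`. Period and
  treatment effects are on the log-odds scale — the natural scale of the
  logistic model — even when a scenario is described on the probability
  scale (e.g. "a 50% control-arm rate" means `pi = logit(0.5) = 0`).
* **Poisson** (log link): `Y ~ Poisson(T exp(eta))` with per-participant
  at-risk time `T`. `T` is either a fixed constant or negative-binomial
  with mean `mu` and size `s` (variance `mu + mu^2/s`). Negative-binomial
  draws of zero are replaced by 1, the smallest positive support value: a
  participant with no at-risk time contributes no information and a zero
  exposure breaks the log offset. The replacement rate is logged; at
  realistic exposure parameters it is negligible, and the moment checks in
  the test suite confirm the stated mean/variance are preserved to within
  sampling error.

Period effects are drawn once per simulated trial from
`N(period_effect, period_var)` — with `period_var = 0` they are the stated
centers verbatim. `period_effect` accepts a scalar (every period shares one
center) or a length-J vector (distinct per-period baselines, e.g. a
declining background rate); with a vector and `period_var > 0` the noise is
added around each element.

Individual outcomes are generated and then aggregated to cluster-period
summaries, rather than simulating the aggregates directly; for the count
family the two are distributionally identical (a sum of independent
Poissons is Poisson with summed exposure), and the individual-level path
keeps future extensions with participant-level heterogeneity possible.

## Designs

`make_design` builds balanced allocations: for one period, ⌈K/2⌉ treated
clusters; for two periods, half the clusters on sequence (1,0) and half on
(0,1) — an odd K is rejected rather than silently unbalanced, since the
balanced split is the standard crossover allocation. For J > 2 the two
alternating sequences (1,0,1,…) and (0,1,0,…) are tiled; multi-period
sequence design is genuinely open and this convention at least guarantees
every cluster experiences both conditions in every adjacent period pair.
The canonical allocation is deterministic; `randomize_assignment` permutes
cluster labels under a seeded generator, preserving the sequence counts.
Power runs use the canonical allocation directly — clusters are
exchangeable under the model, so the permutation cannot change power.

## Estimators

**Crossover (J ≥ 2), `cluster_fixed` / `cluster_fixed_period`.** A GLM on
the K×J cluster-period aggregates with one fixed effect per cluster, the
treatment indicator, optionally J−1 period indicators, and (counts) the log
total at-risk time as offset. Cluster fixed effects absorb `b_k` entirely,
so the treatment effect is identified from within-cluster contrasts without
distributional assumptions on the random intercepts. With equal exposures
in both periods of every cluster and no period adjustment, the Poisson MLE
has the closed form `theta_hat = log(treated events / control events)`,
which the test suite uses as an oracle alongside brute-force likelihood
maximization. Wald intervals use z quantiles for the Poisson and logistic
GLMs; the Gaussian version is a weighted (by cell size) linear model on
cluster-period means and uses t quantiles on its residual degrees of
freedom, `KJ − K − 1 − (J−1 if period-adjusted)`, without which its type-I
error would be visibly inflated at small K.

A fit is declared failed (`converged=False`, never an exception) when the
maximum-likelihood estimate does not exist at a finite point: a zero-event
cluster (count family), an all-success/all-failure cluster (binary), a
zero-event period under period adjustment, or a degenerate arm total —
plus any IRLS non-convergence. Failed replicates are excluded from the
power denominator and reported as a failure rate: a failed fit yields no
test decision, and counting failures as non-rejections would bias power
downward. A rate above 1% triggers a warning. Under heavy between-cluster
variance (sigma_b^2 = 0.5 with ~8 expected events per cluster-period) a
1–3% failure rate is an honest property of the scenario: those are
realizations in which a whole cluster records no events.

**Parallel (J = 1), `single_period`.** Binary outcomes: pooled
fixed-effects logistic regression of outcome on treatment — the pooled log
odds ratio with a Wald z interval. This model ignores clustering by
construction and is intended for settings with very small between-cluster
variation; with material `sigma_b^2` and large clusters it is
anti-conservative, which is a property of the analysis model, not of the
simulator. Continuous and count outcomes use cluster-summary comparisons
that do respect clustering: ordinary regression of cluster means on
treatment (continuous) or exposure-weighted regression of cluster log
incidence rates (count), both with t intervals on K − 2 degrees of
freedom. A cluster fixed-effects model is deliberately unavailable at
J = 1: with one observation per cluster the treatment indicator is a linear
combination of the cluster dummies and the effect is not identifiable.

Custom analyses register under a string label via `register_estimator`;
they receive the simulated trial and alpha and must return an
`EffectEstimate`, returning `converged=False` on degenerate data.

## Power engine

Replicate `i` of a run with master seed `s` uses
`SeedSequence(entropy=s, spawn_key=(i,))`, so results are bit-identical
given the seed, replicates are independent, and execution order is
irrelevant. Sweep grid point `i` derives seed `(s + 1000003·i) mod 2^31`;
point 0 reuses the master seed, so a length-1 sweep reproduces a plain
power call exactly.

Simulated power curves over cluster count or cluster size are smoothed by
isotonic regression (pool-adjacent-violators, weighted by converged
replicates) before any threshold search: true power is monotone in these
parameters, and PAV is the deterministic, assumption-light way to impose
exactly that and nothing more. `min_clusters_for_power` returns the
smallest grid value whose smoothed power reaches the target, or an explicit
grid-exhausted result — never an extrapolation. Because the threshold is
read off a stochastic curve, the resolved minimum is reproducible to about
one grid step across seeds.

## What the simulations do and do not show

The generator emulates the features that drive power in cluster designs:
within-cluster correlation, secular trends, exposure-time variation and
small-sample cluster counts. It does not emulate individual-level risk
factors, overdispersed counts (only exposure times are negative-binomial),
informative cluster sizes, carryover between periods (crossover periods
are assumed washout-separated), or missing data. A power estimate from this
package is therefore a design-stage quantity under an idealized model, and
passing tests demonstrate correctness of the machinery under that model —
not robustness of any real trial to violations of it.

## Numerical choices and problem sizes

Default alpha 0.05 and n_sim 1000 (Monte-Carlo SE ≤ 0.016). The end-to-end
checks use 1000 replicates per configuration and grids of 11–12 cluster
counts — about 100 seconds per minimum-cluster search on one CPU, which is
the scale at which the minimum is stable to one grid step. Type-I
calibration checks use 2000 replicates (3 MC SE ≈ 0.015 around 0.05).
GLM fits run to the statsmodels IRLS defaults with `maxiter=200`; the
cluster fixed-effects likelihoods are concave, so non-convergence in
practice only reflects the degenerate-data cases screened beforehand.
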