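# Methods

## Model

Responses to a J-item instrument with M ordered categories follow the Partial
Credit Model (PCM), the polytomous Rasch model. For person *i* and item *j*,

```
P(X_ij = k | theta_i, delta_j) = exp(k*theta_i - sum_{l<=k} delta_jl) /
                                 sum_{r=0}^{M-1} exp(r*theta_i - sum_{l<=r} delta_jl)
```

with the empty sum at k = 0. The category thresholds `delta_jl` are the trait
levels at which adjacent categories are equally probable; an item's location
`delta_j` is its threshold mean. Person traits are a normal random effect,

```
theta_i = mu0 + g_i * gamma + theta_res_i,   theta_res_i ~ N(0, sigma^2),
```

so in a two-arm trial `gamma` is the latent-scale treatment effect (a
standardized mean difference, since within-arm variance is 1 in the simulated
designs) and `mu0` the placebo-arm mean — equivalently, the (mis)targeting of
the sample relative to the instrument, whose thresholds are centered at 0.

Assumptions: unidimensionality, local independence given theta, equal
discrimination (Rasch), normal latent distribution, no differential item
functioning, cross-sectional data, complete responses. All of these are
satisfied exactly by the simulator, by construction.

## Item-bank archetypes

Two bank constructors reproduce patterns met in practice:

* **Archetype 1** ("parallel items", typical of classical-test-theory
  instruments): locations evenly spaced on [−0.25, 0.25]; within-item
  thresholds at normal percentiles with SD 2.5.
* **Archetype 2** ("item hierarchy", typical of Rasch-built instruments):
  locations evenly spaced on [−1, 1]; threshold SD 1.5.

Thresholds sit at the tercile points (M = 3) or quintile points (M = 5) of a
normal centered on each location. Terciles are taken as exact thirds rather
than the rounded 33rd/66th percentiles — consistent with the exact fifths used
for M = 5 (difference below the 0.01-quantile level; the rounded variant is
available via `literal_percentiles=True`). The whole bank is then shifted so
that the grand mean of all thresholds is 0, putting the latent origin at the
instrument's centre; with exact terciles/quintiles the offsets are symmetric
and this shift is a no-op, but it matters for the rounded-percentile variant.

## Estimation

The marginal likelihood integrates the person residual out with Gauss–Hermite
(GH) quadrature and is maximized by L-BFGS-B using analytic gradients, via the
PCM score identities `d log P / d theta = k − E[K|theta]` and
`d log P / d delta_jl = −1[k ≥ l] + P(K ≥ l | theta)`. Response patterns are
collapsed to unique (group, pattern) rows, which makes short instruments
(3^4 patterns) very cheap. `sigma` is optimized on the log scale;
`SE(gamma_hat)` comes from the inverse observed information over all free
parameters (central differences of the analytic gradient). This estimates the
same quantities as the generalized-SEM implementations common in commercial
software, without claiming algorithmic equivalence.

**Identification.** Adding a constant to all thresholds is equivalent to
shifting the latent location, so exactly one location constraint is active:
calibration-sample fits fix the latent mean at 0 (matching the calibration
population), free-item trial fits report grand-mean-centered thresholds with
`mu0` estimated, and anchored fits inherit the scale from the anchor.
Internally, free-item fits always run with `mu0 = 0` and are re-expressed
afterwards (`delta − mean(delta)`, `mu0 = −mean(delta)`), an exact
reparameterization that avoids a flat optimizer direction; `gamma` and its SE
are invariant to it.

**Numerical choices.**

* Fit quadrature: 21 fixed (non-adaptive) GH nodes. At the reported-scenario
  conditions (archetype 2, variance 1, |mu| ≤ 2) the 21- vs 41-node
  log-likelihood difference is ≤ ~1e-7 per subject for the short instrument.
  For long instruments (J = 10, M = 5), strong mistargeting or variance 2 the
  integrand is narrow relative to the node spacing and fixed GH converges more
  slowly (~1e-4 per subject at 21 nodes; 81 vs 161 nodes agree to 5e-5
  grid-wide). This has no visible effect on the operating characteristics,
  and `FitOptions.n_quadrature_nodes` raises the rule when higher accuracy is
  needed; per-person adaptive quadrature is deliberately out of scope.
* EAP scoring uses a denser default rule (121 nodes): person posteriors are
  much narrower than the prior when J·M is large, and 21 nodes can err by
  ~4e-2 there while 121 nodes match a 2001-point grid oracle to better than
  1e-6. The cost is negligible (computed once per unique response pattern).
* Thresholds are bounded at |delta| ≤ 15 so fits with unobserved categories
  (possible under strong mistargeting) stay finite; such fits are flagged and
  counted, and excluded from criteria only if they fail to converge.
* Starting values: thresholds 0 (or the anchor), mu0 = gamma = 0, sigma = 1.
  Convergence: L-BFGS-B success, or a final gradient max-norm ≤ 1e-3 (the
  line search can abort at machine precision essentially at the optimum);
  one restart is attempted otherwise, and failures are reported, never
  silently accepted.

**EAP prior.** The t-test pathway fits the no-covariate (pooled) model and
scores with the fitted marginal prior `N(mu0_hat, sigma2_hat)`. A pooled
prior shrinks both arms toward a common mean, which attenuates the group
contrast — the source of the systematic underestimation this pathway shows,
strongest for short instruments. A group-conditional prior (no attenuation of
the contrast) is available via `eap_latent(..., group_conditional=True)` but
is not the study default, since the pooled prior is what reproduces the
reported bias pattern and is the natural choice when scoring precedes any
group analysis.

## Study design and criteria

One replication: simulate a calibration sample (trait ~ N(0, variance)) and a
trial sample; fit the calibration model and anchor the trial fits at its
thresholds (calibrated approach) or re-estimate thresholds on the trial
(non-calibrated); apply both comparison methods to each. Per
(approach × method) cell over replications: rejection rate at alpha = 0.05
(type-I error when gamma = 0, power otherwise), position bias
(mean of effect − gamma; reported signed with the absolute value alongside,
and the t-test pathway's "effect" is the EAP group difference), and the SD of
the effect estimates. Non-converged cells are excluded with counts disclosed
(`n_used`, `n_flagged`).

Default generator conditions mirror the studied design: archetype-2 bank,
N_calibration = 250 with variance 1, equal arms of 200 or 500,
mu ∈ {0, 0.5, 2}, gamma ∈ {0, 0.2}; the full configurable grid spans
J ∈ {4, 7, 10}, M ∈ {3, 5}, both archetypes, N_calibration ∈ {100, 250, 500},
calibration variance ∈ {1, 2}, N_trial ∈ {50, 100, 200, 500} and
gamma ∈ {0, 0.2, 0.5}.

Seeding is hierarchical — `SeedSequence([scenario_seed, replication_index])`
split into calibration and trial streams — so replications are independent,
reproducible, and identical under any execution order or parallel schedule;
the bundled runner executes sequentially. The acceptance script uses 200
replications per scenario (the reference results used 500), with Monte-Carlo
tolerances scaled accordingly: 2·sqrt(p(1−p)/R) for rates, 2·SD/sqrt(R) for
bias and SD criteria.

## What the simulator does and does not emulate

It emulates polytomous Likert-type PRO responses under an exactly-true PCM:
normal traits, perfect model fit, complete data, no DIF, equal arms,
cross-sectional measurement. Real PRO data violate several of these (skewed
traits, misfit, missingness, DIF between calibration and trial populations),
so passing tests demonstrate the statistical behaviour of calibration under
ideal Rasch conditions — not robustness of calibration to miscalibrated or
DIF-affected item banks. Floor/ceiling effects under mistargeting *are*
reproduced (mu = 2 pushes responses into the top categories), which is what
drives the observed power loss there.

## Known limitations

* Fixed-node GH quadrature (see above); no adaptive or MCMC estimation.
* No conditional/pairwise-conditional ML (fixed-effect PCM), no weighted
  likelihood person estimates, no non-Rasch IRT discrimination parameters.
* Unbalanced arms, missing responses and longitudinal designs are out of
  scope.
* The Wald test uses the standard-normal reference and the t-test the pooled
  Student variant; these conventions are declared rather than empirically
  compared (Welch is available behind a flag).
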