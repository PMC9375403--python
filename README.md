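# pcmcal

Simulation toolkit for a question that matters whenever a patient-reported
outcome (PRO) instrument built with Rasch measurement theory is used as a
randomized-trial endpoint: **does calibrating the instrument — fixing its item
parameters at values estimated from a prior reference sample — cost anything
in the trial's ability to detect a treatment effect?** Calibration is what
makes scores traceable (the same number means the same thing across studies),
but an anchored analysis cannot adapt the item parameters to the trial sample.

`pcmcal` implements the full machinery needed to answer this by Monte Carlo:

* **Model.** The Partial Credit Model (polytomous Rasch model) with a normal
  random effect for the person trait. For person *i* and item *j* with
  ordered categories *k = 0..M−1*,

  P(X<sub>ij</sub> = k | θ<sub>i</sub>, δ<sub>j</sub>) =
  exp(kθ<sub>i</sub> − Σ<sub>l≤k</sub> δ<sub>jl</sub>) /
  Σ<sub>r</sub> exp(rθ<sub>i</sub> − Σ<sub>l≤r</sub> δ<sub>jl</sub>),

  with θ<sub>i</sub> = μ<sub>0</sub> + g<sub>i</sub>γ + θ<sub>res,i</sub>,
  θ<sub>res,i</sub> ~ N(0, σ²), g<sub>i</sub> the 0/1 treatment indicator and
  γ the latent-scale treatment effect (a standardized mean difference, the
  within-arm SD being 1).
* **Estimation.** Marginal maximum likelihood (latent trait integrated out by
  Gauss–Hermite quadrature, analytic score equations, L-BFGS-B), with item
  thresholds either free or anchored at a calibration fit; EAP
  (expected-a-posteriori) person scores.
* **Comparison methods.** Wald test on the group coefficient γ̂, and Student
  t-test on EAP scores between arms.
* **Study runner.** Scenario grids over instrument length (J = 4/7/10 items),
  response categories (M = 3/5), item-bank archetype, calibration-sample size
  and variance, trial size, targeting (μ) and effect size (γ), aggregating
  type-I error / power, position bias and SD of the effect estimate per
  (calibrated vs non-calibrated) × (Wald vs t-test) cell.

## Worked example

Calibrate on a reference sample, then analyse a simulated trial both ways
(`examples/03_calibration_anchoring.py`):

```text
threshold recovery (max abs error): 0.345
     calibrated: gamma_hat=0.267, SE=0.122, p=0.028
 non-calibrated: gamma_hat=0.251, SE=0.114, p=0.028
```

The calibration fit recovers the generating thresholds to within sampling
error at N = 250, and the anchored (calibrated) trial analysis estimates the
true γ = 0.2 with essentially the same precision and the same inference as
re-estimating the items on the trial itself — the toolkit's headline finding
when repeated over many replications.

A miniature operating-characteristics study (`examples/05_small_study.py`,
50 replications of one scenario) prints:

```text
      approach     method criterion  rejection_rate  position_bias  sd_estimates  n_used
non_calibrated wald_gamma     power            36.0       0.026461      0.121107      50
non_calibrated  ttest_eap     power            36.0      -0.062496      0.076094      50
    calibrated wald_gamma     power            36.0       0.025269      0.120166      50
    calibrated  ttest_eap     power            36.0      -0.063594      0.075062      50
```

Read: power (%) is identical for calibrated and non-calibrated analyses; the
Wald pathway is nearly unbiased for γ while the EAP t-test pathway
underestimates the group difference (pooled-prior shrinkage) yet has smaller
dispersion. The other examples cover item-bank construction, single fits and
EAP scoring.

A thin CLI mirrors the library: `pcmcal simulate`, `pcmcal fit` (with
`--anchor` for calibrated analyses) and `pcmcal run-study --config grid.yaml`.

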