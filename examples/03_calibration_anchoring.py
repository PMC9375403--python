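"""Calibrate an instrument on a reference sample, then analyse a trial with
the item parameters anchored (the 'calibrated' approach).

Anchoring guarantees the trial's measurements are in the same unit as every
other application of the instrument (metrological traceability).
"""

import numpy as np

from pcmcal import (
    PopulationSpec,
    TrialSpec,
    draw_latent,
    fit_random_pcm,
    make_archetype_bank,
    simulate_responses,
    simulate_trial,
    wald_group_test,
)

bank = make_archetype_bank(J=4, M=3, archetype=2)
rng = np.random.default_rng(11)

# 1. calibration study: N=250, trait ~ N(0, 1); latent mean fixed at 0
cal = simulate_responses(bank, draw_latent(PopulationSpec(0.0, 1.0, 250), rng), rng)
cal_fit = fit_random_pcm(cal, fix_latent_mean=True)
print("threshold recovery (max abs error):",
      f"{np.max(np.abs(cal_fit.thresholds_hat - bank.thresholds)):.3f}")

# 2. trial analysed with thresholds fixed at the calibration estimates
trial = simulate_trial(bank, TrialSpec(200, mu0=0.0, gamma=0.2), rng)
anchored = fit_random_pcm(trial, include_group=True, fixed_items=cal_fit.bank)
free = fit_random_pcm(trial, include_group=True)

for name, fit in [("calibrated", anchored), ("non-calibrated", free)]:
    t = wald_group_test(fit)
    print(f"{name:>15}: gamma_hat={fit.gamma_hat:.3f}, SE={fit.se_gamma:.3f}, p={t.p_value:.3f}")
# reading: anchoring the items at the calibration estimates gives essentially
# the same treatment-effect estimate and inference as re-estimating them.
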