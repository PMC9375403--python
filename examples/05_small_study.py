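"""Run a miniature version of the full simulation study (one scenario,
50 replications) and print the operating-characteristics table.

Each replication simulates a calibration sample and a trial, analyses the
trial with calibrated (anchored) and non-calibrated item parameters, and
applies both comparison methods; rejection rate, position bias and SD of the
effect estimate are aggregated over replications.
"""

from pcmcal import ScenarioSpec, compute_criteria, criteria_frame, run_scenario

scenario = ScenarioSpec(
    J=4, M=3, archetype=2,
    n_calibration=250, calibration_variance=1.0,
    n_trial=200, mu=0.0, gamma=0.2,
    n_replications=50, seed=2022,
)
records = run_scenario(scenario)
table = criteria_frame(compute_criteria(records, scenario.gamma))
print(table[["approach", "method", "criterion", "rejection_rate",
             "position_bias", "sd_estimates", "n_used"]].to_string(index=False))
# reading: 'rejection_rate' is power (%) since gamma = 0.2 here; calibrated
# and non-calibrated rows agree to Monte-Carlo noise, the t-test rows show
# the negative EAP shrinkage bias, and the Wald rows are nearly unbiased.
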