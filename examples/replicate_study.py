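"""Small replicate study: bias, coverage and the Fisher-variance pitfall.

Runs 30 replicates of the null scenario (no biomarker-event association)
and contrasts the sandwich-variance weighted estimator with its naive
Fisher-information variant. Expect near-0.95 coverage for the sandwich
and visibly lower coverage for the naive variant at m=1.
"""

from jmncc import aggregate_metrics, run_replicates, study1_scenario, true_parameter_values

scenario = study1_scenario(m=1)
raw = run_replicates(
    scenario, methods=("wjmncc", "wjmncc-fisher"), n_reps=30, seed=99
)
metrics = aggregate_metrics(raw, true_parameter_values(scenario.sim))

cols = ["method", "parameter", "bias", "se_mean", "ese", "ecp", "reject_rate"]
sub = metrics[metrics.parameter.isin(["beta_1", "beta_2"])]
print(sub[cols].to_string(index=False, float_format=lambda v: f"{v: .3f}"))
print("\nse_mean ~ ese and ecp ~ 0.95 indicate calibrated uncertainty;")
print("the Fisher variant's smaller SEs undercover and over-reject.")
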