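"""Score every estimator against both true estimands in one scenario.

Runs a small replicated simulation (all four estimators, full population
overlap) and prints each estimator's bias against the population-average
conditional truth d_BC and the marginal truth Delta_BC. Because the truths
differ under the logit link, an estimator can only be unbiased for the
estimand it actually targets — the table makes the targeting visible.
"""

import popadjust as pa

pop = pa.PopulationSpec(("x1",), (pa.Normal(0.0, 1.0),), label="shared")
params = pa.OutcomeModelParams(
    link="logit", baselines={"AB": 0.0, "AC": 0.2}, beta1=[0.8],
    beta2={"B": [0.0], "C": [0.0]}, gamma={"B": -0.4, "C": -0.9},
)
scenario = pa.Scenario(
    pop_ab=pop, pop_ac=pop, params=params,
    model=pa.ModelConfig(prognostic_set=("x1",), link="logit"),
    n_ab=500, n_ac=500, n_reps=50, base_seed=40,
)
result = pa.run_simulation_study(scenario)

print(f"true d_BC     = {result.truth.conditional:+.4f}")
print(f"true Delta_BC = {result.truth.marginal:+.4f}")
print()
cols = ["estimator", "kind", "bias_vs_d", "bias_vs_delta", "mc_se_bias", "n_fail"]
print(result.table[cols].to_string(index=False, float_format=lambda v: f"{v:+.4f}"))
print()
print("Read each row against the estimand its estimator targets: ML-NMR's")
print("conditional row should be unbiased for d_BC, its marginal row and")
print("MAIC/Bucher for Delta_BC (biases within ~2 mc_se_bias of zero).")
print("The bias columns differ by exactly Delta_BC - d_BC for every row.")
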