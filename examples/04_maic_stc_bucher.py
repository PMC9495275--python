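"""The comparator estimators on one anchored dataset, with estimand labels.

MAIC reweights the AB subjects to the AC covariate moments and compares
crude contrasts (a marginal estimand in the AC population). Typical STC
subtracts a conditional regression coefficient from a marginal crude
contrast — a mixed quantity, flagged as such. Bucher compares the two crude
contrasts with no adjustment at all.
"""

import popadjust as pa

spec = pa.PopulationSpec(("x1",), (pa.Normal(0.0, 1.0),), label="shared")
params = pa.OutcomeModelParams(
    link="logit", baselines={"AB": 0.0, "AC": 0.2}, beta1=[0.5],
    beta2={"B": [0.3], "C": [0.3]}, gamma={"B": -0.5, "C": -1.0},
)
ipd_ab = pa.simulate_ipd_trial(spec, params, "AB", ("A", "B"), 1000, seed=31)
agd_ac = pa.aggregate_trial(
    pa.simulate_ipd_trial(spec, params, "AC", ("A", "C"), 1000, seed=32)
)

weights = pa.maic_weights(ipd_ab, agd_ac, ["x1"], moment_order=2)
print(f"MAIC weights: ESS = {weights.ess:.1f} of {ipd_ab.n}, "
      f"largest moment gap = {weights.max_moment_gap:.2e}")

model = pa.ModelConfig(prognostic_set=("x1",), effect_modifiers=("x1",), link="logit")
estimates = [
    pa.maic_anchored(ipd_ab, agd_ac, weights),
    pa.stc_typical(ipd_ab, agd_ac, model),
    pa.bucher(pa.aggregate_trial(ipd_ab), agd_ac),
]
for est in estimates:
    print(f"{est.method:55s} {est.estimate:+.3f} (SE {est.se:.3f})")
    print(f"    estimand: {est.kind} on the {est.scale} scale")
print()
print("With full population overlap the weights are near-uniform and MAIC")
print("barely differs from Bucher; both target the marginal estimand")
print("(true Delta_BC ~ -0.440). STC's output is neither marginal nor")
print("conditional — the 'mixed' label makes the estimand mismatch explicit.")
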