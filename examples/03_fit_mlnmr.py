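"""Fit ML-NMR jointly to IPD and aggregate data, then predict both estimands.

The outcome model is fitted by maximum likelihood to the AB subject-level
data (Bernoulli likelihood) and the AC aggregate counts (Binomial likelihood
with the arm probability integrated over the reconstructed AC covariate
distribution). One fit then yields either estimand in any target population:
the conditional estimand by plugging in that population's mean covariates,
the marginal estimand by integrating event probabilities over it.
"""

import popadjust as pa

spec = pa.PopulationSpec(("x1",), (pa.Normal(0.0, 1.0),), label="shared")
params = pa.OutcomeModelParams(
    link="logit", baselines={"AB": 0.0, "AC": 0.2}, beta1=[0.5],
    beta2={"B": [0.3], "C": [0.3]}, gamma={"B": -0.5, "C": -1.0},
)
ipd_ab = pa.simulate_ipd_trial(spec, params, "AB", ("A", "B"), 1000, seed=21)
agd_ac = pa.aggregate_trial(
    pa.simulate_ipd_trial(spec, params, "AC", ("A", "C"), 1000, seed=22)
)

model = pa.ModelConfig(prognostic_set=("x1",), effect_modifiers=("x1",), link="logit")
fit = pa.fit_mlnmr(ipd_ab, agd_ac, model, pa.IntegrationConfig(n_points=2048, seed=0))

print(f"converged: {fit.converged} ({fit.n_iterations} iterations, "
      f"log-likelihood {fit.loglik:.2f})")
for name, est, se in zip(fit.param_names, fit.theta, fit.se):
    print(f"  {name:12s} = {est:+.3f} (SE {se:.3f})")

target = fit.agd_population  # the AC population, rebuilt from the summaries
for kind in ("conditional_population_average", "marginal_population_average"):
    est = pa.predict_estimands(fit, target, ("B", "C"), kind)
    print(f"{kind:34s}: {est.estimate:+.3f} (SE {est.se:.3f}) [{est.scale}]")
print()
print("True values under the generating model: d_BC = -0.500 and")
print("Delta_BC ~ -0.440; the conditional estimate sits further from the")
print("null than the marginal one, as noncollapsibility of the odds ratio")
print("requires. Both come from the same fit — the estimand is chosen at")
print("prediction time, not baked into the estimator.")
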