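"""Conditional, marginal and absolute population-average estimands."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate as sint
from scipy.special import expit
from scipy.stats import norm

import popadjust as pa
from conftest import random_params, random_population, rescale_for_identity

QMC = pa.IntegrationConfig(method="qmc", n_points=8192, seed=0)


class TestConditionalPopulationAverage:
    def test_self_contrast_is_zero(self, logit_params, std_normal_pop):
        est = pa.conditional_population_average(logit_params, std_normal_pop, "B", "B")
        assert est.estimate == 0.0

    def test_equal_interactions_cancel(self, logit_params, std_normal_pop):
        # beta2[B] == beta2[C], so only the gamma difference survives
        est = pa.conditional_population_average(logit_params, std_normal_pop, "B", "C")
        assert est.estimate == pytest.approx(-0.5)

    def test_plug_in_arithmetic(self):
        spec = pa.PopulationSpec(("x1",), (pa.Bernoulli(0.6),))
        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.0}, beta1=[0.3],
            beta2={"B": [0.0], "C": [0.5]}, gamma={"B": 0.0, "C": 1.0},
        )
        est = pa.conditional_population_average(params, spec, "B", "C")
        assert est.estimate == pytest.approx(0.6 * 0.5 + 1.0)

    def test_dimension_mismatch_rejected(self, logit_params, mixed_pop):
        with pytest.raises(pa.ValidationError):
            pa.conditional_population_average(logit_params, mixed_pop, "A", "B")


class TestAverageOutcome:
    def test_identity_link_closed_form(self, mixed_pop):
        params = pa.OutcomeModelParams(
            link="identity", baselines={"S": 0.3}, beta1=[0.05, 0.1],
            beta2={"B": [0.02, 0.0]}, gamma={"B": 0.1},
        )
        pbar, err = pa.average_outcome(params, mixed_pop, "B", "S", QMC)
        expected = 0.3 + mixed_pop.mean @ np.array([0.07, 0.1]) + 0.1
        assert pbar == pytest.approx(expected, abs=max(3 * err, 1e-9))

    def test_logit_symmetry_gives_half(self, std_normal_pop):
        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.0}, beta1=[1.0],
            beta2={"B": [0.0]}, gamma={"B": 0.0},
        )
        pbar, err = pa.average_outcome(params, std_normal_pop, "B", "S", QMC)
        assert pbar == pytest.approx(0.5, abs=max(3 * err, 1e-6))

    def test_against_adaptive_quadrature_oracle(self, std_normal_pop):
        # independent oracle: adaptive 1-d quadrature of expit(1 + x) phi(x)
        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 1.0}, beta1=[1.0],
            beta2={"B": [0.0]}, gamma={"B": 0.0},
        )
        oracle, _ = sint.quad(lambda x: expit(1.0 + x) * norm.pdf(x), -8, 8)
        pbar, _ = pa.average_outcome(params, std_normal_pop, "B", "S", QMC)
        assert pbar == pytest.approx(oracle, abs=1e-4)


class TestMarginalPopulationAverage:
    def test_identity_link_matches_conditional(self, mixed_pop):
        params = pa.OutcomeModelParams(
            link="identity", baselines={"S": 0.4}, beta1=[0.03, 0.05],
            beta2={"B": [0.02, -0.01], "C": [0.0, 0.0]}, gamma={"B": 0.1, "C": -0.05},
        )
        marg = pa.marginal_population_average(params, mixed_pop, "B", "C", "S", QMC)
        cond = pa.conditional_population_average(params, mixed_pop, "B", "C")
        assert marg.estimate == pytest.approx(
            cond.estimate, abs=max(3 * marg.metadata["error_bound"], 1e-9)
        )

    def test_constant_integrand_returns_gamma_difference(self, std_normal_pop):
        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.0}, beta1=[0.0],
            beta2={"B": [0.0], "C": [0.0]}, gamma={"B": 0.3, "C": 1.0},
        )
        marg = pa.marginal_population_average(params, std_normal_pop, "B", "C", "S", QMC)
        assert marg.estimate == pytest.approx(0.7, abs=1e-6)

    def test_attenuation_against_brute_force_oracle(self, std_normal_pop):
        from scipy.special import logit

        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.0}, beta1=[1.5],
            beta2={"B": [0.0]}, gamma={"B": 1.0},
        )
        marg = pa.marginal_population_average(params, std_normal_pop, "A", "B", "S", QMC)
        assert 0.0 < marg.estimate < 1.0  # strictly attenuated
        rng = np.random.default_rng(55)
        x = rng.standard_normal(10**7)
        oracle = logit(expit(1.5 * x + 1.0).mean()) - logit(expit(1.5 * x).mean())
        assert marg.estimate == pytest.approx(oracle, abs=3e-4)


class TestMarginalSummary:
    def test_null_contrast_on_every_scale(self):
        for scale in ("risk-difference", "log-relative-risk", "log-odds"):
            assert pa.marginal_summary(0.3, 0.3, scale).estimate == 0.0

    def test_risk_difference(self):
        assert pa.marginal_summary(0.2, 0.3, "risk-difference").estimate == pytest.approx(0.1)

    def test_log_odds_arithmetic(self):
        est = pa.marginal_summary(0.2, 0.3, "log-odds")
        assert est.estimate == pytest.approx(np.log((0.3 / 0.7) / (0.2 / 0.8)))

    def test_zero_probability_ratio_scale_rejected(self):
        with pytest.raises(pa.ValidationError):
            pa.marginal_summary(0.0, 0.3, "log-relative-risk")


class TestCondMargRatio:
    def test_identity_link_ratio_is_one(self, std_normal_pop):
        params = pa.OutcomeModelParams(
            link="identity", baselines={"S": 0.5}, beta1=[0.05],
            beta2={"B": [0.0]}, gamma={"B": 0.2},
        )
        assert pa.cond_marg_ratio(params, std_normal_pop, "A", "B", "S", QMC) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_no_prognostic_variation_ratio_is_one(self, std_normal_pop):
        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.2}, beta1=[0.0],
            beta2={"B": [0.0]}, gamma={"B": 0.8},
        )
        assert pa.cond_marg_ratio(params, std_normal_pop, "A", "B", "S", QMC) == pytest.approx(
            1.0, abs=1e-5
        )

    def test_ratio_exceeds_one_and_matches_oracle(self, std_normal_pop):
        from scipy.special import logit

        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.0}, beta1=[1.0],
            beta2={"B": [0.0]}, gamma={"B": 0.5},
        )
        ratio = pa.cond_marg_ratio(params, std_normal_pop, "A", "B", "S", QMC)
        assert ratio > 1.0
        rng = np.random.default_rng(77)
        x = rng.standard_normal(10**7)
        pb, pa_ = expit(x + 0.5), expit(x)
        oracle = 0.5 / (logit(pb.mean()) - logit(pa_.mean()))
        # 3 MC SEs of the oracle denominator, propagated through the ratio
        assert ratio == pytest.approx(oracle, rel=1e-3)

    def test_null_effect_degenerate_ratio(self, std_normal_pop):
        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.0}, beta1=[1.0],
            beta2={"B": [0.0]}, gamma={"B": 0.0},
        )
        # both effects are null: ratio defined as 1 by continuity
        assert pa.cond_marg_ratio(params, std_normal_pop, "A", "B", "S", QMC) == 1.0

    def test_attenuation_approximation_is_close_but_advisory(self, std_normal_pop):
        params = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.0}, beta1=[1.0],
            beta2={"B": [0.0]}, gamma={"B": 0.5},
        )
        exact = pa.cond_marg_ratio(params, std_normal_pop, "A", "B", "S", QMC)
        approx = pa.attenuation_approximation(params, std_normal_pop, "A", "B")
        assert approx > 1.0
        assert approx == pytest.approx(exact, rel=0.05)


class TestLabellingAndInvariance:
    @given(st.integers(0, 10_000))
    def test_every_estimate_is_labelled(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_population(rng, int(rng.integers(1, 3)))
        params = random_params(rng, spec.n_covariates)
        cond = pa.conditional_population_average(params, spec, "B", "C")
        marg = pa.marginal_population_average(
            params, spec, "B", "C", "AB",
            pa.IntegrationConfig(n_points=256, seed=0),
        )
        from popadjust.estimands import KINDS, SCALES

        for est in (cond, marg):
            assert est.kind in KINDS and est.scale in SCALES  # no naked numbers
            assert est.population == spec.label

    def test_unlabelled_estimate_cannot_be_constructed(self):
        with pytest.raises(pa.ValidationError):
            pa.EstimandEstimate(
                kind="", scale="log-odds", contrast=("A", "B"),
                population="P", estimate=0.1,
            )
        with pytest.raises(pa.ValidationError):
            pa.EstimandEstimate(
                kind="marginal_population_average", scale="", contrast=("A", "B"),
                population="P", estimate=0.1,
            )

    def test_invariant_to_covariate_reordering(self):
        # d and Delta average over the whole population: permuting the
        # covariate labels (with matching parameters) must not change them
        spec1 = pa.PopulationSpec(
            ("u", "v"), (pa.Normal(0.3, 0.9), pa.Bernoulli(0.35)),
            correlation=np.array([[1.0, 0.2], [0.2, 1.0]]),
        )
        spec2 = pa.PopulationSpec(
            ("v", "u"), (pa.Bernoulli(0.35), pa.Normal(0.3, 0.9)),
            correlation=np.array([[1.0, 0.2], [0.2, 1.0]]),
        )
        p1 = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.1}, beta1=[0.6, -0.4],
            beta2={"B": [0.25, 0.1]}, gamma={"B": 0.7},
        )
        p2 = pa.OutcomeModelParams(
            link="logit", baselines={"S": 0.1}, beta1=[-0.4, 0.6],
            beta2={"B": [0.1, 0.25]}, gamma={"B": 0.7},
        )
        c1 = pa.conditional_population_average(p1, spec1, "A", "B").estimate
        c2 = pa.conditional_population_average(p2, spec2, "A", "B").estimate
        assert c1 == pytest.approx(c2, abs=1e-12)
        gh = pa.IntegrationConfig(method="qmc", n_points=1 << 14, seed=3)
        m1 = pa.marginal_population_average(p1, spec1, "A", "B", "S", gh)
        m2 = pa.marginal_population_average(p2, spec2, "A", "B", "S", gh)
        tol = 3 * (m1.metadata["error_bound"] + m2.metadata["error_bound"]) + 1e-6
        assert m1.estimate == pytest.approx(m2.estimate, abs=tol)


class TestCollapsibilityProperties:
    def test_identity_link_collapsible_over_random_grid(self):
        rng = np.random.default_rng(4242)
        for _ in range(30):
            spec = random_population(rng, int(rng.integers(1, 3)))
            params = rescale_for_identity(random_params(rng, spec.n_covariates), spec)
            marg = pa.marginal_population_average(params, spec, "B", "C", "AB", QMC)
            cond = pa.conditional_population_average(params, spec, "B", "C")
            # integral-identity tolerance: max(1e-4, 3 * error bound)
            assert marg.estimate == pytest.approx(
                cond.estimate, abs=max(3 * marg.metadata["error_bound"], 1e-4)
            )
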