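"""MAIC weighting, anchored comparisons, typical STC and Bucher."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import popadjust as pa


def _ipd_from_values(values, y=None, trt=None, study="AB"):
    n = len(values)
    data = pd.DataFrame(
        {
            "trt": trt if trt is not None else ["A", "B"] * (n // 2) + ["A"] * (n % 2),
            "x1": np.asarray(values, dtype=float),
            "y": y if y is not None else [0, 1] * (n // 2) + [0] * (n % 2),
        }
    )
    return pa.IPDTrial(study=study, data=data, covariate_names=("x1",))


def _agd(mean=0.5, sd=None, proportion=None, study="AC", arms=None):
    if arms is None:
        arms = {"A": pa.ArmCounts(100, 10), "C": pa.ArmCounts(100, 30)}
    if proportion is not None:
        summ = {"x1": {"type": "binary", "proportion": proportion}}
    else:
        summ = {"x1": {"type": "continuous", "mean": mean, "sd": sd if sd is not None else 1.0}}
    return pa.AgDTrial(study=study, arms=arms, covariate_summaries=summ)


class TestMAICWeights:
    def test_already_balanced_gives_uniform_weights(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.3, 1.1, 400)
        ipd = _ipd_from_values(x)
        agd = _agd(mean=float(x.mean()), sd=float(np.sqrt(((x - x.mean()) ** 2).mean())))
        w = pa.maic_weights(ipd, agd, ["x1"], moment_order=2)
        np.testing.assert_allclose(w.alpha, 0.0, atol=1e-6)
        np.testing.assert_allclose(w.weights, 1.0 / 400, atol=1e-8)
        assert w.ess == pytest.approx(400, rel=1e-6)

    def test_four_subject_worked_instance(self):
        # one binary covariate, values (0,0,1,1), target mean 0.75:
        # the moment equation gives e^alpha = 3, hence normalised weights
        # (0.125, 0.125, 0.375, 0.375)
        ipd = _ipd_from_values([0.0, 0.0, 1.0, 1.0])
        agd = _agd(proportion=0.75)
        w = pa.maic_weights(ipd, agd, ["x1"], moment_order=1)
        np.testing.assert_allclose(w.weights, [0.125, 0.125, 0.375, 0.375], atol=1e-9)
        assert math.exp(w.alpha[0]) == pytest.approx(3.0, rel=1e-8)
        assert w.max_moment_gap < 1e-8

    def test_hull_violation_constant_covariate(self):
        ipd = _ipd_from_values([0.0, 0.0, 0.0, 0.0])
        agd = _agd(proportion=0.5)
        with pytest.raises(pa.OverlapError):
            pa.maic_weights(ipd, agd, ["x1"], moment_order=1)

    def test_hull_violation_target_outside_range(self):
        ipd = _ipd_from_values([0.1, 0.4, 0.2, 0.3])
        agd = _agd(mean=2.0, sd=0.5)
        with pytest.raises(pa.OverlapError, match="extrapolate"):
            pa.maic_weights(ipd, agd, ["x1"], moment_order=1)

    def test_moment_match_tolerance_on_solvable_instances(self):
        rng = np.random.default_rng(11)
        for i in range(10):
            x = rng.normal(0, 1, 300)
            ipd = _ipd_from_values(x)
            target_mean = float(np.quantile(x, rng.uniform(0.35, 0.65)))
            target_sd = float(x.std() * rng.uniform(0.7, 1.0))
            agd = _agd(mean=target_mean, sd=target_sd)
            w = pa.maic_weights(ipd, agd, ["x1"], moment_order=2)
            assert w.converged
            assert w.max_moment_gap < 1e-8
            got_mean = float(w.weights @ x)
            got_m2 = float(w.weights @ x**2)
            assert got_mean == pytest.approx(target_mean, abs=1e-8)
            assert got_m2 == pytest.approx(target_mean**2 + target_sd**2, abs=1e-8)

    def test_ess_decreases_as_target_moves_away(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0.0, 1.0, 500)
        ipd = _ipd_from_values(x)
        ess = []
        for shift in (0.0, 0.3, 0.6, 0.9, 1.2):
            agd = _agd(mean=float(x.mean() + shift), sd=1.0)
            ess.append(pa.maic_weights(ipd, agd, ["x1"], moment_order=1).ess)
        assert all(a > b for a, b in zip(ess, ess[1:]))

    def test_second_moment_constraint_reduces_ess(self):
        """Matching the variance on top of the mean is a stricter requirement
        and costs effective sample size. This holds in aggregate and nearly
        per-instance; it is not an exact per-instance monotonicity (the tilt
        on the mean can relax slightly when the variance term joins), so a
        small per-instance slack is allowed."""
        rng = np.random.default_rng(17)
        e1s, e2s = [], []
        for i in range(8):
            x = rng.normal(0, 1, 400)
            ipd = _ipd_from_values(x)
            agd = _agd(
                mean=float(np.quantile(x, rng.uniform(0.4, 0.6))),
                sd=float(x.std() * rng.uniform(0.75, 0.95)),
            )
            e1s.append(pa.maic_weights(ipd, agd, ["x1"], moment_order=1).ess)
            e2s.append(pa.maic_weights(ipd, agd, ["x1"], moment_order=2).ess)
            assert e2s[-1] <= e1s[-1] * 1.01
        assert np.mean(e2s) < np.mean(e1s)


class TestEffectiveSampleSize:
    def test_uniform_weights(self):
        assert pa.effective_sample_size(np.ones(100)) == pytest.approx(100.0)

    def test_single_positive_weight(self):
        assert pa.effective_sample_size(np.array([1.0, 0, 0, 0])) == pytest.approx(1.0)

    def test_direct_formula(self):
        assert pa.effective_sample_size(np.array([2.0, 1.0, 1.0])) == pytest.approx(16 / 6)

    def test_all_zero_rejected(self):
        with pytest.raises(pa.ValidationError):
            pa.effective_sample_size(np.zeros(3))


class TestMAICAnchored:
    def test_identical_crude_contrasts_cancel(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 200)
        trt = ["A"] * 100 + ["B"] * 100
        y = [1] * 10 + [0] * 90 + [1] * 30 + [0] * 70
        ipd = _ipd_from_values(x, y=y, trt=trt)
        agd = _agd(
            mean=float(x.mean()), sd=float(x.std()),
            arms={"A": pa.ArmCounts(100, 10), "C": pa.ArmCounts(100, 30)},
        )
        w = pa.maic_weights(ipd, agd, ["x1"], moment_order=1)
        est = pa.maic_anchored(ipd, agd, w)
        assert est.estimate == pytest.approx(0.0, abs=1e-6)

    def test_toy_counts_closed_form(self):
        x = np.zeros(200) + 0.5  # constant covariate: weights stay uniform
        trt = ["A"] * 100 + ["B"] * 100
        y = [1] * 10 + [0] * 90 + [1] * 20 + [0] * 80
        ipd = _ipd_from_values(x, y=y, trt=trt)
        agd = _agd(
            mean=0.5, sd=0.0,
            arms={"A": pa.ArmCounts(100, 10), "C": pa.ArmCounts(100, 30)},
        )
        w = pa.maic_weights(ipd, agd, ["x1"], moment_order=1)
        est = pa.maic_anchored(ipd, agd, w)
        expected = math.log((30 / 70) / (10 / 90)) - math.log((20 / 80) / (10 / 90))
        assert est.estimate == pytest.approx(expected, abs=1e-9)
        assert est.kind == "marginal_population_average"
        assert est.population == "AC"

    def test_bootstrap_variance_agrees_with_analytic(self):
        rng = np.random.default_rng(23)
        n = 400
        x = rng.normal(0, 1, n)
        trt = ["A"] * (n // 2) + ["B"] * (n // 2)
        y = (rng.random(n) < 0.3).astype(int)
        ipd = _ipd_from_values(x, y=list(y), trt=trt)
        agd = _agd(mean=float(x.mean() + 0.2), sd=float(x.std()))
        w = pa.maic_weights(ipd, agd, ["x1"], moment_order=2)
        analytic = pa.maic_anchored(ipd, agd, w)
        boot = pa.maic_anchored(ipd, agd, w, variance="bootstrap", n_boot=300, boot_seed=1)
        assert boot.estimate == analytic.estimate  # point estimate unchanged
        assert boot.se == pytest.approx(analytic.se, rel=0.25)

    def test_zero_cell_continuity_correction_warns(self):
        x = np.linspace(-1, 1, 40)
        trt = ["A"] * 20 + ["B"] * 20
        y = [0] * 20 + [1] * 5 + [0] * 15  # no events in arm A
        ipd = _ipd_from_values(x, y=y, trt=trt)
        agd = _agd(mean=0.0, sd=0.5)
        w = pa.maic_weights(ipd, agd, ["x1"], moment_order=1)
        with pytest.warns(UserWarning, match="continuity"):
            est = pa.maic_anchored(ipd, agd, w)
        assert np.isfinite(est.estimate)


class TestBucher:
    def test_identical_contrasts_give_zero(self):
        arms_ab = {"A": pa.ArmCounts(100, 10), "B": pa.ArmCounts(100, 30)}
        arms_ac = {"A": pa.ArmCounts(100, 10), "C": pa.ArmCounts(100, 30)}
        assert pa.bucher(arms_ab, arms_ac).estimate == pytest.approx(0.0)

    def test_closed_form_log_odds(self):
        arms_ab = {"A": pa.ArmCounts(100, 10), "B": pa.ArmCounts(100, 20)}
        arms_ac = {"A": pa.ArmCounts(100, 10), "C": pa.ArmCounts(100, 30)}
        est = pa.bucher(arms_ab, arms_ac)
        assert est.estimate == pytest.approx(math.log(27 / 7) - math.log(9 / 4))
        # variance: sum of 1/cell over both 2x2 tables
        var = (1 / 10 + 1 / 90 + 1 / 20 + 1 / 80) + (1 / 10 + 1 / 90 + 1 / 30 + 1 / 70)
        assert est.se == pytest.approx(math.sqrt(var))

    def test_estimand_labels(self):
        arms_ab = {"A": pa.ArmCounts(50, 10), "B": pa.ArmCounts(50, 20)}
        arms_ac = {"A": pa.ArmCounts(50, 10), "C": pa.ArmCounts(50, 5)}
        est = pa.bucher(arms_ab, arms_ac, scale="risk-difference")
        assert est.kind == "marginal_population_average"
        assert est.scale == "risk-difference"
        assert est.contrast == ("B", "C")


class TestSTCTypical:
    def test_mixed_kind_label_and_warning(self, std_normal_pop, logit_params):
        ipd = pa.simulate_ipd_trial(std_normal_pop, logit_params, "AB", ("A", "B"), 500, seed=1)
        agd = pa.aggregate_trial(
            pa.simulate_ipd_trial(std_normal_pop, logit_params, "AC", ("A", "C"), 500, seed=2)
        )
        cfg = pa.ModelConfig(prognostic_set=("x1",), link="logit")
        est = pa.stc_typical(ipd, agd, cfg)
        assert est.kind == "mixed (typical STC)"
        assert "warning" in est.metadata
        assert est.se is not None and est.se > 0

    def test_separation_raises(self):
        # outcome perfectly determined by the covariate -> separated regression
        x = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)])
        trt = (["A"] * 10 + ["B"] * 10) * 2
        y = [0] * 20 + [1] * 20
        ipd = _ipd_from_values(x, y=y, trt=trt)
        agd = _agd(mean=0.0, sd=1.0)
        cfg = pa.ModelConfig(prognostic_set=("x1",), link="logit")
        with pytest.raises(pa.SingularFitError):
            pa.stc_typical(ipd, agd, cfg)
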