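"""Simulation-study runner scoring every estimator against both estimands.

A :class:`Scenario` fixes the data-generating mechanism: the AB and AC trial
populations, the outcome-model parameters, sample sizes, the estimators to
run and the number of replicates. Each replicate simulates an AB IPD trial
and an AC trial (collapsed to aggregate form), runs the requested estimators,
and records their B-vs-C estimates. Summaries report bias, empirical SE, MSE
and CI coverage against *both* true estimands — the population-average
conditional effect d_BC and the marginal effect Delta_BC in the AC
population — because the estimators do not all target the same one.

Failed replicates (eg MAIC overlap failures) are logged and counted, never
silently dropped; a cell with more than 50% failures is flagged invalid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparators import bucher, maic_anchored, maic_weights, stc_typical
from .estimands import IntegrationConfig
from .exceptions import PopAdjustError, ValidationError
from .mlnmr import ModelConfig, fit_mlnmr, predict_estimands
from .popmodel import (
    OutcomeModelParams,
    PopulationSpec,
    TrueEstimandPair,
    aggregate_trial,
    link_scale,
    simulate_ipd_trial,
    true_estimands,
)

__all__ = ["Scenario", "SimStudyResult", "run_simulation_study"]

logger = logging.getLogger("popadjust.simstudy")

_ESTIMATORS = ("mlnmr", "maic", "stc", "bucher")


@dataclass(frozen=True)
class Scenario:
    """A complete simulation-study cell."""

    pop_ab: PopulationSpec
    pop_ac: PopulationSpec
    params: OutcomeModelParams
    model: ModelConfig
    n_ab: int = 1000  # subjects per arm in the AB trial
    n_ac: int = 1000  # subjects per arm in the AC trial
    study_ab: str = "AB"
    study_ac: str = "AC"
    arms_ab: tuple[str, str] = ("A", "B")
    arms_ac: tuple[str, str] = ("A", "C")
    estimators: tuple[str, ...] = _ESTIMATORS
    maic_moment_order: int = 2
    n_reps: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        unknown = set(self.estimators) - set(_ESTIMATORS)
        if unknown:
            raise ValidationError(f"unknown estimators {sorted(unknown)}")
        for arm in (*self.arms_ab, *self.arms_ac):
            self.params.require_treatment(arm)
        for study in (self.study_ab, self.study_ac):
            if study not in self.params.baselines:
                raise ValidationError(f"study {study!r} has no baseline in params")
        if set(self.arms_ab) & set(self.arms_ac) == set():
            raise ValidationError("the AB and AC trials must share an anchor arm")

    @property
    def contrast(self) -> tuple[str, str]:
        """(B, C): the non-anchor arms of the two trials."""
        anchor = set(self.arms_ab) & set(self.arms_ac)
        b = next(a for a in self.arms_ab if a not in anchor)
        c = next(a for a in self.arms_ac if a not in anchor)
        return (b, c)


@dataclass
class SimStudyResult:
    """Per-estimator performance against both true estimands."""

    truth: TrueEstimandPair
    table: pd.DataFrame
    n_reps: int
    scenario: Scenario = field(repr=False)

    def row(self, estimator: str, kind: str | None = None) -> pd.Series:
        t = self.table[self.table["estimator"] == estimator]
        if kind is not None:
            t = t[t["kind"] == kind]
        if len(t) != 1:
            raise KeyError(f"no unique row for ({estimator}, {kind})")
        return t.iloc[0]


def _replicate_seeds(base_seed: int, r: int) -> tuple[int, int]:
    state = np.random.SeedSequence(base_seed + r).generate_state(2)
    return int(state[0]), int(state[1])


def _run_estimators(scenario: Scenario, r: int, intcfg: IntegrationConfig) -> list[dict]:
    seed_ab, seed_ac = _replicate_seeds(scenario.base_seed, r)
    ipd_ab = simulate_ipd_trial(
        scenario.pop_ab, scenario.params, scenario.study_ab,
        scenario.arms_ab, scenario.n_ab, seed_ab,
    )
    ipd_ac = simulate_ipd_trial(
        scenario.pop_ac, scenario.params, scenario.study_ac,
        scenario.arms_ac, scenario.n_ac, seed_ac,
    )
    agd_ac = aggregate_trial(ipd_ac)
    agd_ab = aggregate_trial(ipd_ab)
    scale = link_scale(scenario.params.link)

    rows: list[dict] = []

    def record(estimator: str, est) -> None:
        rows.append(
            {
                "rep": r,
                "estimator": estimator,
                "kind": est.kind,
                "scale": est.scale,
                "estimate": est.estimate,
                "se": est.se,
                "ess": est.metadata.get("ess", np.nan),
                "ok": True,
            }
        )

    for name in scenario.estimators:
        try:
            if name == "bucher":
                record(name, bucher(agd_ab, agd_ac, scale=scale, population=scenario.study_ac))
            elif name == "maic":
                w = maic_weights(
                    ipd_ab, agd_ac, scenario.model.prognostic_set,
                    moment_order=scenario.maic_moment_order,
                )
                record(name, maic_anchored(ipd_ab, agd_ac, w, scale=scale))
            elif name == "stc":
                record(name, stc_typical(ipd_ab, agd_ac, scenario.model))
            elif name == "mlnmr":
                fit = fit_mlnmr(ipd_ab, agd_ac, scenario.model, intcfg)
                target = fit.agd_population
                for kind in (
                    "conditional_population_average",
                    "marginal_population_average",
                ):
                    record(name, predict_estimands(fit, target, scenario.contrast, kind))
        except PopAdjustError as exc:
            logger.warning("replicate %d: estimator %s failed: %s", r, name, exc)
            rows.append(
                {
                    "rep": r,
                    "estimator": name,
                    "kind": "failed",
                    "scale": scale,
                    "estimate": np.nan,
                    "se": np.nan,
                    "ess": np.nan,
                    "ok": False,
                }
            )
    return rows


def run_simulation_study(
    scenario: Scenario,
    intcfg: IntegrationConfig | None = None,
    truth_intcfg: IntegrationConfig | None = None,
) -> SimStudyResult:
    """Run the scenario and score all estimators against d_BC and Delta_BC.

    Replicate r uses seed ``base_seed + r``. The true estimands are computed
    once with high-precision integration over the AC population (the common
    target population of the anchored comparison).
    """
    if intcfg is None:
        intcfg = IntegrationConfig(method="qmc", n_points=1024, seed=scenario.base_seed)
    if truth_intcfg is None:
        truth_intcfg = IntegrationConfig(method="qmc", n_points=1 << 16, seed=0)
    truth = true_estimands(
        scenario.params, scenario.pop_ac, scenario.contrast,
        intcfg=truth_intcfg, study=scenario.study_ac,
    )

    all_rows: list[dict] = []
    for r in range(scenario.n_reps):
        all_rows.extend(_run_estimators(scenario, r, intcfg))
    raw = pd.DataFrame(all_rows)

    d_true, m_true = truth.conditional, truth.marginal
    summaries = []
    for name in scenario.estimators:
        sub = raw[raw["estimator"] == name]
        n_fail = int((~sub["ok"]).sum())
        for kind in sorted(sub.loc[sub["ok"], "kind"].unique()):
            cell = sub[(sub["kind"] == kind) & sub["ok"]]
            est = cell["estimate"].to_numpy()
            se = cell["se"].to_numpy(dtype=float)
            n_ok = len(est)
            mean = float(est.mean()) if n_ok else np.nan
            emp_se = float(est.std(ddof=1)) if n_ok > 1 else np.nan
            with np.errstate(invalid="ignore"):
                cover_d = float(np.mean(np.abs(est - d_true) <= 1.959963984540054 * se))
                cover_m = float(np.mean(np.abs(est - m_true) <= 1.959963984540054 * se))
            summaries.append(
                {
                    "estimator": name,
                    "kind": kind,
                    "scale": cell["scale"].iloc[0],
                    "n_reps": scenario.n_reps,
                    "n_ok": n_ok,
                    "n_fail": n_fail,
                    "invalid": n_fail > scenario.n_reps / 2,
                    "mean": mean,
                    "bias_vs_d": mean - d_true,
                    "bias_vs_delta": mean - m_true,
                    "mc_se_bias": emp_se / math.sqrt(n_ok) if n_ok > 1 else np.nan,
                    "emp_se": emp_se,
                    "mse_vs_d": float(np.mean((est - d_true) ** 2)) if n_ok else np.nan,
                    "mse_vs_delta": float(np.mean((est - m_true) ** 2)) if n_ok else np.nan,
                    "mean_se": float(np.nanmean(se)) if n_ok else np.nan,
                    "coverage_d": cover_d,
                    "coverage_delta": cover_m,
                    "mean_ess": float(cell["ess"].mean()) if n_ok else np.nan,
                }
            )
        if n_fail and not any(s["estimator"] == name for s in summaries):
            # estimator failed in every replicate
            summaries.append(
                {
                    "estimator": name, "kind": "failed", "scale": link_scale(scenario.params.link),
                    "n_reps": scenario.n_reps, "n_ok": 0, "n_fail": n_fail, "invalid": True,
                    "mean": np.nan, "bias_vs_d": np.nan, "bias_vs_delta": np.nan,
                    "mc_se_bias": np.nan, "emp_se": np.nan, "mse_vs_d": np.nan,
                    "mse_vs_delta": np.nan, "mean_se": np.nan, "coverage_d": np.nan,
                    "coverage_delta": np.nan, "mean_ess": np.nan,
                }
            )
    table = pd.DataFrame(summaries)
    return SimStudyResult(truth=truth, table=table, n_reps=scenario.n_reps, scenario=scenario)
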