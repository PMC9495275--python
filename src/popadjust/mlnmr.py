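"""Multilevel network meta-regression for the two-study anchored network.

The individual-level outcome model is fitted jointly to a subject-level AB
trial and an aggregate AC trial. The AB subjects contribute a Bernoulli
likelihood through the linear predictor directly; each AC arm contributes a
Binomial likelihood whose event probability is the individual-level model
integrated over the AC covariate distribution (rebuilt from the published
summaries). The two studies share the prognostic coefficients, effect-modifier
interactions and treatment effects but have separate baselines.

Estimation is by maximum likelihood: the linear predictor is linear in the
parameter vector, so both likelihood terms have closed-form gradients (the
aggregate arm probability is a finite weighted average over fixed integration
points). Standard errors come from the observed information, computed by
finite differences of the analytic gradient. Any estimand in any target
population is then available through :mod:`popadjust.estimands`, with
delta-method standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .exceptions import ConvergenceError, SingularFitError, ValidationError
from .integration import IntegrationConfig, PopulationDesign, population_points
from .popmodel import (
    AgDTrial,
    Bernoulli,
    IPDTrial,
    Normal,
    OutcomeModelParams,
    PointMass,
    PopulationSpec,
    get_link,
)

__all__ = ["ModelConfig", "MLNMRFit", "reconstruct_population", "fit_mlnmr", "predict_estimands"]


@dataclass(frozen=True)
class ModelConfig:
    """Which covariates enter the outcome model, and how.

    Effect modifiers receive treatment interactions (beta2) on top of their
    prognostic main effect (beta1); they must therefore be a subset of the
    prognostic set. ``shared_em`` pools the interaction coefficients across
    non-reference treatments (one beta2 vector), the usual assumption when
    each non-anchor treatment is seen in only one study.
    """

    prognostic_set: tuple[str, ...]
    effect_modifiers: tuple[str, ...] = ()
    link: str = "logit"
    shared_em: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "prognostic_set", tuple(self.prognostic_set))
        object.__setattr__(self, "effect_modifiers", tuple(self.effect_modifiers))
        get_link(self.link)
        extra = set(self.effect_modifiers) - set(self.prognostic_set)
        if extra:
            raise ValidationError(
                f"effect modifiers {sorted(extra)} lack prognostic main effects; "
                "interactions must be accompanied by main effects"
            )
        if len(set(self.prognostic_set)) != len(self.prognostic_set):
            raise ValidationError("duplicate names in prognostic_set")


def reconstruct_population(
    agd: AgDTrial,
    correlation_source: IPDTrial | str | None = "identity",
    covariates: tuple[str, ...] | None = None,
) -> PopulationSpec:
    """Rebuild the AgD study's covariate distribution from its summaries.

    Continuous covariates become normal(mean, SD), binary ones Bernoulli
    (proportion); an SD of 0 or a proportion of 0/1 degenerates to a point
    mass with a warning. The copula correlation is either the identity
    (``correlation_source="identity"`` or None) or the sample correlation of
    an IPD trial's covariates — the standard borrowing assumption when the
    aggregate publication reports no dependence information.
    """
    names = tuple(covariates) if covariates is not None else tuple(agd.covariate_summaries)
    marginals = []
    for name in names:
        if name not in agd.covariate_summaries:
            raise ValidationError(f"AgD study has no summary for covariate {name!r}")
        summ = agd.covariate_summaries[name]
        if summ["type"] == "continuous":
            if summ["sd"] == 0.0:
                warnings.warn(
                    f"covariate {name!r} has SD 0 in study {agd.study!r}; "
                    "using a point-mass marginal",
                    stacklevel=2,
                )
                marginals.append(PointMass(float(summ["mean"])))
            else:
                marginals.append(Normal(float(summ["mean"]), float(summ["sd"])))
        else:
            prop = float(summ["proportion"])
            if prop in (0.0, 1.0):
                warnings.warn(
                    f"binary covariate {name!r} has proportion {prop} in study "
                    f"{agd.study!r}; using a point-mass marginal",
                    stacklevel=2,
                )
                marginals.append(PointMass(prop))
            else:
                marginals.append(Bernoulli(prop))
    if isinstance(correlation_source, IPDTrial):
        x = correlation_source.covariate_matrix(names)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(x, rowvar=False)
        corr = np.atleast_2d(corr)
        corr[np.isnan(corr)] = 0.0  # constant columns carry no dependence
        np.fill_diagonal(corr, 1.0)
        # project to the nearest PSD correlation if sampling noise broke it
        evals, evecs = np.linalg.eigh(corr)
        if evals.min() < 0:
            corr = evecs @ np.diag(np.clip(evals, 1e-12, None)) @ evecs.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
        provenance = f"correlation from IPD study {correlation_source.study!r}"
    elif correlation_source in (None, "identity"):
        corr = np.eye(len(names))
        provenance = "independence (identity correlation)"
    else:
        raise ValidationError(
            "correlation_source must be an IPDTrial, 'identity', or None"
        )
    return PopulationSpec(
        covariate_names=names,
        marginals=tuple(marginals),
        correlation=corr,
        label=agd.study,
        provenance=f"reconstructed from AgD summaries of {agd.study!r}; {provenance}",
    )


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ParamLayout:
    """Maps between the flat parameter vector and OutcomeModelParams."""

    studies: tuple[str, str]  # (ipd study, agd study)
    covariates: tuple[str, ...]
    em_index: tuple[int, ...]  # positions of effect modifiers within covariates
    treatments: tuple[str, ...]  # non-reference, sorted
    reference: str
    shared_em: bool
    link: str

    @property
    def names(self) -> tuple[str, ...]:
        out = [f"mu[{s}]" for s in self.studies]
        out += [f"beta1[{c}]" for c in self.covariates]
        if self.em_index:
            if self.shared_em:
                out += [f"beta2[{self.covariates[j]}]" for j in self.em_index]
            else:
                for t in self.treatments:
                    out += [f"beta2[{t},{self.covariates[j]}]" for j in self.em_index]
        out += [f"gamma[{t}]" for t in self.treatments]
        return tuple(out)

    @property
    def size(self) -> int:
        n_em = len(self.em_index)
        n_b2 = n_em if self.shared_em else n_em * len(self.treatments)
        return 2 + len(self.covariates) + n_b2 + len(self.treatments)

    def unpack(self, theta: np.ndarray) -> OutcomeModelParams:
        theta = np.asarray(theta, dtype=float)
        p = len(self.covariates)
        n_em = len(self.em_index)
        pos = 2
        beta1 = theta[pos : pos + p]
        pos += p
        beta2: dict[str, np.ndarray] = {}
        if self.shared_em:
            b2 = np.zeros(p)
            b2[list(self.em_index)] = theta[pos : pos + n_em]
            pos += n_em
            for t in self.treatments:
                beta2[t] = b2
        else:
            for t in self.treatments:
                b2 = np.zeros(p)
                b2[list(self.em_index)] = theta[pos : pos + n_em]
                pos += n_em
                beta2[t] = b2
        gamma = {t: float(theta[pos + i]) for i, t in enumerate(self.treatments)}
        return OutcomeModelParams(
            link=self.link,
            baselines={self.studies[0]: float(theta[0]), self.studies[1]: float(theta[1])},
            beta1=beta1,
            beta2=beta2,
            gamma=gamma,
            reference_treatment=self.reference,
        )

    def design_row_block(
        self, study_idx: int, treatment: str, x: np.ndarray
    ) -> np.ndarray:
        """Design matrix D with eta = D @ theta for rows of x under one arm."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        cols = [np.zeros((n, 2))]
        cols[0][:, study_idx] = 1.0
        cols.append(x)  # beta1 block
        n_em = len(self.em_index)
        x_em = x[:, list(self.em_index)] if n_em else np.zeros((n, 0))
        active = treatment != self.reference
        if n_em:
            if self.shared_em:
                cols.append(x_em if active else np.zeros((n, n_em)))
            else:
                for t in self.treatments:
                    cols.append(x_em if (active and t == treatment) else np.zeros((n, n_em)))
        gcols = np.zeros((n, len(self.treatments)))
        if active:
            gcols[:, self.treatments.index(treatment)] = 1.0
        cols.append(gcols)
        return np.hstack(cols)


@dataclass
class MLNMRFit:
    """Result of a joint IPD + AgD maximum-likelihood fit."""

    params_hat: OutcomeModelParams
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int
    integration: IntegrationConfig
    layout: _ParamLayout = field(repr=False)
    theta: np.ndarray = field(repr=False)
    gradient_norm: float = 0.0
    agd_population: PopulationSpec | None = field(default=None, repr=False)

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.layout.names

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))


def _negloglik_and_grad(
    theta: np.ndarray,
    link,
    d_ipd: np.ndarray,
    y: np.ndarray,
    agd_blocks: list[tuple[np.ndarray, int, int]],  # (design on int points, n, events)
    weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    eps = 1e-12
    # IPD Bernoulli term
    eta = d_ipd @ theta
    p = np.clip(np.asarray(link.inv(eta), dtype=float), eps, 1.0 - eps)
    ll = float(y @ np.log(p) + (1.0 - y) @ np.log1p(-p))
    dl_deta = (y - p) / (p * (1.0 - p)) * np.asarray(link.dinv(eta), dtype=float)
    grad = d_ipd.T @ dl_deta
    # AgD Binomial terms: pbar is a weighted average over fixed points
    for d_arm, n, events in agd_blocks:
        eta_a = d_arm @ theta
        pa = np.clip(np.asarray(link.inv(eta_a), dtype=float), eps, 1.0 - eps)
        pbar = float(np.clip(weights @ pa, eps, 1.0 - eps))
        ll += events * np.log(pbar) + (n - events) * np.log1p(-pbar)
        dl_dpbar = events / pbar - (n - events) / (1.0 - pbar)
        dpbar = (weights * np.asarray(link.dinv(eta_a), dtype=float)) @ d_arm
        grad = grad + dl_dpbar * dpbar
    return -ll, -grad


def fit_mlnmr(
    ipd: IPDTrial,
    agd: AgDTrial,
    config: ModelConfig,
    intcfg: IntegrationConfig | None = None,
    correlation_source: IPDTrial | str | None = "ipd",
    max_restarts: int = 3,
    gtol: float = 1e-6,
) -> MLNMRFit:
    """Fit the outcome model jointly to AB subject-level and AC aggregate data.

    The two trials must share exactly one treatment (the anchor), which
    becomes the model's reference. The AC covariate distribution is rebuilt
    from the aggregate summaries (correlations borrowed from the IPD trial by
    default); its integration points are drawn once and held fixed, so the
    objective is smooth. Optimisation is BFGS with the analytic gradient and
    up to ``max_restarts`` jittered restarts; non-convergence raises
    :class:`ConvergenceError` with the residual gradient norm.
    """
    if intcfg is None:
        intcfg = IntegrationConfig(method="qmc", n_points=4096, seed=0)
    anchors = ipd.arm_set & agd.arm_set
    if len(anchors) != 1:
        raise ValidationError(
            f"the IPD and AgD trials must share exactly one anchor treatment; "
            f"shared set is {sorted(anchors)}"
        )
    anchor = next(iter(anchors))
    missing = set(config.prognostic_set) - set(ipd.covariate_names)
    if missing:
        raise ValidationError(f"IPD trial lacks covariates {sorted(missing)}")
    treatments = tuple(sorted((ipd.arm_set | agd.arm_set) - {anchor}))
    covs = config.prognostic_set
    em_index = tuple(covs.index(c) for c in config.effect_modifiers)
    layout = _ParamLayout(
        studies=(ipd.study, agd.study),
        covariates=covs,
        em_index=em_index,
        treatments=treatments,
        reference=anchor,
        shared_em=config.shared_em,
        link=config.link,
    )
    link = get_link(config.link)

    corr_src = ipd if correlation_source == "ipd" else correlation_source
    agd_spec = reconstruct_population(agd, corr_src, covariates=covs)
    design = population_points(agd_spec, intcfg)

    # stack the IPD design arm by arm
    x_ipd = ipd.covariate_matrix(covs)
    trt = ipd.data["trt"].astype(str).to_numpy()
    y = ipd.data["y"].to_numpy(dtype=float)
    d_ipd = np.vstack(
        [layout.design_row_block(0, t, x_ipd[trt == t]) for t in sorted(ipd.arm_set)]
    )
    y = np.concatenate([y[trt == t] for t in sorted(ipd.arm_set)])

    agd_blocks = [
        (layout.design_row_block(1, t, design.points), agd.arms[t].n, agd.arms[t].events)
        for t in sorted(agd.arm_set)
    ]

    def objective(th: np.ndarray) -> tuple[float, np.ndarray]:
        return _negloglik_and_grad(th, link, d_ipd, y, agd_blocks, design.weights)

    x0 = np.zeros(layout.size)
    if config.link == "identity":  # keep probabilities interior at the start
        x0[:2] = 0.5
    elif config.link == "log":
        x0[:2] = np.log(0.5)
    jitter_rng = np.random.default_rng(intcfg.seed + 1_000_003)
    best = None
    n_iter = 0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            objective, x0, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        n_iter += res.nit
        gnorm = float(np.linalg.norm(res.jac, np.inf))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < gtol:
            break
        x0 = res.x + 0.1 * jitter_rng.standard_normal(layout.size)
    res, gnorm = best
    if gnorm >= gtol * 10:  # BFGS can stop a whisker above gtol at a true optimum
        raise ConvergenceError(
            f"ML-NMR fit did not converge after {max_restarts + 1} attempts; "
            f"gradient norm {gnorm:.3g} (tolerance {gtol:g}). "
            "Check for separation in the IPD or a degenerate AgD arm."
        )

    # observed information by central differences of the analytic gradient
    k = layout.size
    hess = np.empty((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(res.x))
    for j in range(k):
        tp, tm = res.x.copy(), res.x.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        hess[:, j] = (objective(tp)[1] - objective(tm)[1]) / (2.0 * h[j])
    hess = 0.5 * (hess + hess.T)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        raise SingularFitError(
            "observed information is singular; likely separation in the IPD trial"
        ) from None
    if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
        raise SingularFitError(
            "observed information is not positive definite; likely separation "
            "or an unidentified parameter"
        )

    return MLNMRFit(
        params_hat=layout.unpack(res.x),
        vcov=vcov,
        loglik=-float(res.fun),
        converged=gnorm < gtol * 10,
        n_iterations=int(n_iter),
        integration=intcfg,
        layout=layout,
        theta=res.x.copy(),
        gradient_norm=gnorm,
        agd_population=agd_spec,
    )


def predict_estimands(
    fit: MLNMRFit,
    target: PopulationSpec,
    contrast: tuple[str, str],
    kind: str = "marginal_population_average",
    study: str | None = None,
    intcfg: IntegrationConfig | None = None,
):
    """Any population-average estimand, in any target population, from one fit.

    Delegates the point estimate to :mod:`popadjust.estimands` at the fitted
    parameters; the standard error is by the delta method, with the gradient
    of the estimand with respect to the parameter vector taken by central
    finite differences (integration points held fixed across evaluations).
    """
    from . import estimands as _est

    a, b = contrast
    fit.params_hat.require_treatment(a)
    fit.params_hat.require_treatment(b)
    if intcfg is None:
        intcfg = fit.integration
    if study is None:
        study = fit.layout.studies[1]  # the AgD study baseline

    def value_at(theta: np.ndarray) -> float:
        params = fit.layout.unpack(theta)
        if kind == "conditional_population_average":
            return _est.conditional_population_average(params, target, a, b).estimate
        if kind == "marginal_population_average":
            return _est.marginal_population_average(
                params, target, a, b, study, intcfg
            ).estimate
        raise ValidationError(
            "kind must be 'marginal_population_average' or "
            "'conditional_population_average'"
        )

    est = value_at(fit.theta)
    grad = np.zeros(fit.layout.size)
    h = 1e-5 * np.maximum(1.0, np.abs(fit.theta))
    for j in range(fit.layout.size):
        tp, tm = fit.theta.copy(), fit.theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        grad[j] = (value_at(tp) - value_at(tm)) / (2.0 * h[j])
    se = float(np.sqrt(max(0.0, grad @ fit.vcov @ grad)))
    return _est.EstimandEstimate(
        kind=kind,
        scale=_est.link_scale(fit.params_hat.link),
        contrast=(a, b),
        population=target.label,
        estimate=float(est),
        se=se,
        method="ML-NMR (maximum likelihood)",
    )
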