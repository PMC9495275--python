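"""Populations, the individual-level outcome model, and trial simulation.

A target population is described by a :class:`PopulationSpec`: independent
marginal distributions (normal, Bernoulli, or a point mass) tied together by a
Gaussian copula with a given correlation matrix. The outcome model is a
generalised linear model for a binary outcome,

    g(p) = mu(study) + x' beta1 + x' beta2[k] + gamma[k],

where ``beta1`` are prognostic (main) covariate effects, ``beta2[k]`` are
effect-modifier interactions for treatment ``k``, and ``gamma[k]`` is the
individual-level treatment effect at covariate value x = 0. The reference
treatment has ``beta2`` and ``gamma`` identically zero.

From these two objects the module simulates subject-level (IPD) trials,
collapses them to aggregate (AgD) summaries, and computes the true
population-average conditional and marginal estimands used as simulation
oracles.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special

from .exceptions import SimulationError, ValidationError

__all__ = [
    "Normal",
    "Bernoulli",
    "PointMass",
    "Marginal",
    "PopulationSpec",
    "OutcomeModelParams",
    "IPDTrial",
    "AgDTrial",
    "ArmCounts",
    "TrueEstimandPair",
    "LINKS",
    "link_scale",
    "sample_covariates",
    "simulate_ipd_trial",
    "aggregate_trial",
    "true_estimands",
]


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Link:
    """A GLM link: g maps probability -> linear predictor, inv its inverse."""

    name: str
    g: Callable[[np.ndarray], np.ndarray]
    inv: Callable[[np.ndarray], np.ndarray]
    dinv: Callable[[np.ndarray], np.ndarray]  # derivative of inv wrt eta
    scale: str  # name of the effect scale the link induces
    bounded: bool  # True if inv can leave [0,1] (identity/log need checking)


def _probit_dinv(eta: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.asarray(eta) ** 2) / math.sqrt(2.0 * math.pi)


LINKS: dict[str, Link] = {
    "logit": Link(
        "logit", special.logit, special.expit,
        lambda e: special.expit(e) * (1.0 - special.expit(e)),
        scale="log-odds", bounded=False,
    ),
    "identity": Link(
        "identity", lambda p: np.asarray(p, dtype=float), lambda e: np.asarray(e, dtype=float),
        lambda e: np.ones_like(np.asarray(e, dtype=float)),
        scale="risk-difference", bounded=True,
    ),
    "log": Link(
        "log", np.log, np.exp, np.exp, scale="log-risk", bounded=True,
    ),
    "probit": Link(
        "probit", special.ndtri, special.ndtr, _probit_dinv, scale="probit", bounded=False,
    ),
}


def get_link(name: str) -> Link:
    try:
        return LINKS[name]
    except KeyError:
        raise ValidationError(
            f"unknown link {name!r}; choose one of {sorted(LINKS)}"
        ) from None


def link_scale(name: str) -> str:
    """Effect scale induced by a link (eg logit -> 'log-odds')."""
    return get_link(name).scale


# ---------------------------------------------------------------------------
# Marginal distributions and the population spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.sd):
            raise ValidationError("normal marginal requires finite mean and sd")
        if self.sd <= 0:
            raise ValidationError(f"normal marginal requires sd > 0, got {self.sd}")

    @property
    def is_binary(self) -> bool:
        return False


@dataclass(frozen=True)
class Bernoulli:
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValidationError(
                f"Bernoulli marginal requires probability in (0, 1), got {self.p}"
            )

    @property
    def mean(self) -> float:
        return self.p

    @property
    def is_binary(self) -> bool:
        return True


@dataclass(frozen=True)
class PointMass:
    """Degenerate marginal: the covariate is constant in the population."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    @property
    def is_binary(self) -> bool:
        return self.value in (0.0, 1.0)


Marginal = Union[Normal, Bernoulli, PointMass]


@dataclass(frozen=True)
class PopulationSpec:
    """Joint covariate distribution f(x) of a target population.

    Marginals are combined with a Gaussian copula whose correlation matrix is
    ``correlation`` (identity if omitted). The mean vector is exact: normal
    mean, Bernoulli probability, or the point-mass value.
    """

    covariate_names: tuple[str, ...]
    marginals: tuple[Marginal, ...]
    correlation: np.ndarray | None = None
    label: str = "P"
    provenance: str = ""

    def __post_init__(self) -> None:
        names = tuple(self.covariate_names)
        margs = tuple(self.marginals)
        object.__setattr__(self, "covariate_names", names)
        object.__setattr__(self, "marginals", margs)
        if len(names) != len(margs):
            raise ValidationError("one marginal per covariate name is required")
        if len(set(names)) != len(names):
            raise ValidationError("covariate names must be unique")
        if len(names) == 0:
            raise ValidationError("at least one covariate is required")
        p = len(names)
        if self.correlation is None:
            corr = np.eye(p)
        else:
            corr = np.array(self.correlation, dtype=float)
        if corr.shape != (p, p):
            raise ValidationError(f"correlation must be {p}x{p}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValidationError("correlation matrix must have unit diagonal")
        evals = np.linalg.eigvalsh(corr)
        if evals.min() < -1e-10:
            raise ValidationError(
                f"correlation matrix is not positive semi-definite "
                f"(min eigenvalue {evals.min():.3g})"
            )
        corr.setflags(write=False)
        object.__setattr__(self, "correlation", corr)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def mean(self) -> np.ndarray:
        """Exact mean vector x̄ of the population."""
        return np.array([m.mean for m in self.marginals], dtype=float)

    def copula_factor(self) -> np.ndarray:
        """Matrix L with L L' = correlation, for correlating standard normals."""
        corr = self.correlation
        try:
            return np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            # PSD but singular: eigen factorisation with tiny negatives clipped
            w, v = np.linalg.eigh(corr)
            return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    def transform_gaussian(self, z: np.ndarray) -> np.ndarray:
        """Map correlated standard-normal scores (n, p) to covariate values."""
        z = np.asarray(z, dtype=float)
        x = np.empty_like(z)
        for j, m in enumerate(self.marginals):
            if isinstance(m, Normal):
                x[:, j] = m.mean + m.sd * z[:, j]
            elif isinstance(m, Bernoulli):
                x[:, j] = (special.ndtr(z[:, j]) < m.p).astype(float)
            else:
                x[:, j] = m.value
        return x


def sample_covariates(
    spec: PopulationSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` covariate vectors from the population's Gaussian copula.

    Deterministic in (spec, n, seed). Returns an (n, p) float array; binary
    covariates are coded 0/1.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = rng.standard_normal((n, spec.n_covariates)) @ spec.copula_factor().T
    return spec.transform_gaussian(z)


# ---------------------------------------------------------------------------
# Outcome model parameters
# ---------------------------------------------------------------------------

def _as_float_map(m: Mapping[str, float]) -> dict[str, float]:
    return {str(k): float(v) for k, v in m.items()}


@dataclass(frozen=True)
class OutcomeModelParams:
    """Parameters of the individual-level outcome model.

    ``baselines`` maps study label -> baseline mu on the linear-predictor
    scale; ``beta2`` and ``gamma`` map treatment label -> effect-modifier
    interaction vector / treatment effect at x = 0. Treatments absent from
    ``beta2``/``gamma`` other than the reference are not allowed; the reference
    entries may be omitted and are filled with zeros.
    """

    link: str
    baselines: Mapping[str, float]
    beta1: np.ndarray
    beta2: Mapping[str, np.ndarray]
    gamma: Mapping[str, float]
    reference_treatment: str = "A"

    def __post_init__(self) -> None:
        get_link(self.link)
        beta1 = np.atleast_1d(np.asarray(self.beta1, dtype=float))
        beta1.setflags(write=False)
        p = beta1.shape[0]
        gamma = _as_float_map(self.gamma)
        beta2 = {str(k): np.atleast_1d(np.asarray(v, dtype=float)) for k, v in self.beta2.items()}
        ref = self.reference_treatment
        gamma.setdefault(ref, 0.0)
        beta2.setdefault(ref, np.zeros(p))
        if gamma[ref] != 0.0 or np.any(beta2[ref] != 0.0):
            raise ValidationError(
                f"reference treatment {ref!r} must have zero gamma and beta2"
            )
        if set(gamma) != set(beta2):
            raise ValidationError("gamma and beta2 must cover the same treatments")
        for k, v in beta2.items():
            if v.shape != (p,):
                raise ValidationError(
                    f"beta2[{k!r}] has length {v.shape[0]}, expected {p}"
                )
            v.setflags(write=False)
        object.__setattr__(self, "beta1", beta1)
        object.__setattr__(self, "beta2", beta2)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "baselines", _as_float_map(self.baselines))

    @property
    def n_covariates(self) -> int:
        return self.beta1.shape[0]

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(sorted(self.gamma))

    def check_population(self, spec: PopulationSpec) -> None:
        if spec.n_covariates != self.n_covariates:
            raise ValidationError(
                f"population has {spec.n_covariates} covariates but the model "
                f"has {self.n_covariates}"
            )

    def require_treatment(self, k: str) -> None:
        if k not in self.gamma:
            raise ValidationError(
                f"unknown treatment {k!r}; model treatments are {self.treatments}"
            )

    def linear_predictor(self, study: str, treatment: str, x: np.ndarray) -> np.ndarray:
        """mu(study) + x'(beta1 + beta2[trt]) + gamma[trt] for rows of x."""
        self.require_treatment(treatment)
        if study not in self.baselines:
            raise ValidationError(f"no baseline for study {study!r}")
        x = np.atleast_2d(np.asarray(x, dtype=float))
        coef = self.beta1 + self.beta2[treatment]
        return self.baselines[study] + x @ coef + self.gamma[treatment]


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

@dataclass
class IPDTrial:
    """Subject-level trial data.

    ``data`` holds one row per subject with a treatment column ``trt``, the
    covariates, and a binary outcome ``y``.
    """

    study: str
    data: pd.DataFrame
    covariate_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)
        required = {"trt", "y", *self.covariate_names}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"IPD data is missing columns {sorted(missing)}")
        if self.data[list(required)].isna().any().any():
            raise ValidationError("IPD data contains missing values")
        y = self.data["y"]
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("outcome y must be 0 or 1 for every subject")
        if len(self.arm_set) < 2:
            raise ValidationError("an IPD trial needs at least two arms")

    @property
    def arm_set(self) -> frozenset[str]:
        return frozenset(self.data["trt"].astype(str))

    @property
    def n(self) -> int:
        return len(self.data)

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        cols = list(names) if names is not None else list(self.covariate_names)
        unknown = set(cols) - set(self.covariate_names)
        if unknown:
            raise ValidationError(f"unknown covariates {sorted(unknown)}")
        return self.data[cols].to_numpy(dtype=float)

    def arm_rows(self, treatment: str) -> pd.DataFrame:
        return self.data[self.data["trt"] == treatment]


@dataclass(frozen=True)
class ArmCounts:
    n: int
    events: int

    def __post_init__(self) -> None:
        if not (0 <= self.events <= self.n):
            raise ValidationError(
                f"events must satisfy 0 <= events <= n, got events={self.events}, n={self.n}"
            )


@dataclass
class AgDTrial:
    """Aggregate trial data: per-arm counts plus covariate summaries.

    ``covariate_summaries`` maps covariate name to ``{"type": "continuous",
    "mean": m, "sd": s}`` or ``{"type": "binary", "proportion": p}``.
    """

    study: str
    arms: dict[str, ArmCounts]
    covariate_summaries: dict[str, dict]

    def __post_init__(self) -> None:
        self.arms = {
            k: v if isinstance(v, ArmCounts) else ArmCounts(**v)
            for k, v in self.arms.items()
        }
        for name, summ in self.covariate_summaries.items():
            kind = summ.get("type")
            if kind == "continuous":
                if summ["sd"] < 0:
                    raise ValidationError(f"covariate {name!r} has negative SD")
            elif kind == "binary":
                if not (0.0 <= summ["proportion"] <= 1.0):
                    raise ValidationError(
                        f"covariate {name!r} proportion must lie in [0, 1]"
                    )
            else:
                raise ValidationError(
                    f"covariate {name!r} summary type must be 'continuous' or 'binary'"
                )

    @property
    def arm_set(self) -> frozenset[str]:
        return frozenset(self.arms)

    def mean(self, name: str) -> float:
        summ = self.covariate_summaries[name]
        return summ["mean"] if summ["type"] == "continuous" else summ["proportion"]


def aggregate_trial(ipd: IPDTrial) -> AgDTrial:
    """Collapse an IPD trial to its aggregate representation.

    Per-arm sample sizes and event counts, plus trial-wide covariate means and
    sample SDs (binary covariates, detected as 0/1-valued, become proportions).
    """
    arms = {}
    for trt in sorted(ipd.arm_set):
        rows = ipd.arm_rows(trt)
        arms[trt] = ArmCounts(n=len(rows), events=int(rows["y"].sum()))
    summaries: dict[str, dict] = {}
    for name in ipd.covariate_names:
        col = ipd.data[name].to_numpy(dtype=float)
        if np.isin(col, (0.0, 1.0)).all():
            summaries[name] = {"type": "binary", "proportion": float(col.mean())}
        else:
            sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
            summaries[name] = {"type": "continuous", "mean": float(col.mean()), "sd": sd}
    return AgDTrial(study=ipd.study, arms=arms, covariate_summaries=summaries)


def simulate_ipd_trial(
    spec: PopulationSpec,
    params: OutcomeModelParams,
    study: str,
    arms: Sequence[str],
    n_per_arm: int | Mapping[str, int],
    seed: int,
) -> IPDTrial:
    """Simulate a randomised trial from the individual-level outcome model.

    Covariates are drawn from ``spec``; outcomes are Bernoulli with success
    probability ``g^{-1}(mu + x'(beta1 + beta2[k]) + gamma[k])``. Allocation is
    ``n_per_arm`` per arm (a mapping allows unequal allocation). Fully
    deterministic given the seed.
    """
    params.check_population(spec)
    if study not in params.baselines:
        raise ValidationError(f"study {study!r} has no baseline in the model parameters")
    for arm in arms:
        params.require_treatment(arm)
    if len(set(arms)) < 2:
        raise ValidationError("a trial needs at least two distinct arms")
    alloc = (
        {a: int(n_per_arm) for a in arms}
        if not isinstance(n_per_arm, Mapping)
        else {a: int(n_per_arm[a]) for a in arms}
    )
    if min(alloc.values()) < 1:
        raise ValidationError("every arm needs at least one subject")

    link = get_link(params.link)
    rng = np.random.default_rng(seed)
    frames = []
    for arm in arms:
        n = alloc[arm]
        x = sample_covariates(spec, n, rng)
        p = np.asarray(link.inv(params.linear_predictor(study, arm, x)))
        if link.bounded:
            bad = np.flatnonzero((p < 0.0) | (p > 1.0))
            if bad.size:
                i = int(bad[0])
                raise SimulationError(
                    f"{params.link} link produced probability {p[i]:.4g} outside "
                    f"[0, 1] for arm {arm!r}, subject {i} (covariates {x[i]})"
                )
        y = rng.binomial(1, p)
        df = pd.DataFrame(x, columns=list(spec.covariate_names))
        df.insert(0, "trt", arm)
        df["y"] = y
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return IPDTrial(study=study, data=data, covariate_names=spec.covariate_names)


# ---------------------------------------------------------------------------
# True estimands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueEstimandPair:
    """True population-average conditional and marginal effects for a contrast.

    Both are on the linear-predictor scale of the model link. The conditional
    effect is exact (closed form); the marginal effect carries the integration
    error bound of the averaging step.
    """

    contrast: tuple[str, str]
    population: str
    conditional: float
    marginal: float
    integration_error: float


def true_estimands(
    params: OutcomeModelParams,
    spec: PopulationSpec,
    contrast: tuple[str, str],
    intcfg=None,
    study: str | None = None,
) -> TrueEstimandPair:
    """Compute d_ab(P) (closed form) and Delta_ab(P) (by integration).

    The conditional estimand is ``x̄' (beta2_b - beta2_a) + gamma_b - gamma_a``;
    the marginal estimand transforms the population-average event probabilities
    of the two arms back to the link scale. ``study`` picks the baseline used
    for the absolute probabilities (first baseline if omitted); the conditional
    estimand does not depend on it.
    """
    from . import estimands as _est  # deferred: estimands depends on this module

    a, b = contrast
    params.require_treatment(a)
    params.require_treatment(b)
    params.check_population(spec)
    if study is None:
        study = next(iter(params.baselines))
    if intcfg is None:
        intcfg = _est.IntegrationConfig(method="qmc", n_points=1 << 15, seed=0)
    cond = _est.conditional_population_average(params, spec, a, b).estimate
    marg = _est.marginal_population_average(params, spec, a, b, study, intcfg)
    return TrueEstimandPair(
        contrast=(a, b),
        population=spec.label,
        conditional=float(cond),
        marginal=float(marg.estimate),
        integration_error=float(marg.metadata.get("error_bound", np.nan)),
    )
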