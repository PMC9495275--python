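import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import popadjust as pa

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def std_normal_pop() -> pa.PopulationSpec:
    """One standard-normal covariate."""
    return pa.PopulationSpec(("x1",), (pa.Normal(0.0, 1.0),))


@pytest.fixture
def mixed_pop() -> pa.PopulationSpec:
    """A continuous and a binary covariate, correlated through the copula."""
    return pa.PopulationSpec(
        ("age", "female"),
        (pa.Normal(0.5, 1.2), pa.Bernoulli(0.4)),
        correlation=np.array([[1.0, 0.3], [0.3, 1.0]]),
        label="target",
    )


@pytest.fixture
def logit_params() -> pa.OutcomeModelParams:
    """Three-treatment logit model with prognostic and effect-modifier terms."""
    return pa.OutcomeModelParams(
        link="logit",
        baselines={"AB": 0.0, "AC": 0.2},
        beta1=[0.5],
        beta2={"B": [0.3], "C": [0.3]},
        gamma={"B": -0.5, "C": -1.0},
        reference_treatment="A",
    )


def random_params(
    rng: np.random.Generator,
    n_cov: int,
    link: str = "logit",
    em: bool = True,
    treatments: tuple[str, ...] = ("B", "C"),
) -> pa.OutcomeModelParams:
    """Draw a random but well-behaved parameter set for property tests."""
    beta2 = {
        t: rng.normal(0.0, 0.3, n_cov) if em else np.zeros(n_cov) for t in treatments
    }
    return pa.OutcomeModelParams(
        link=link,
        baselines={"AB": float(rng.normal(0, 0.5))},
        beta1=rng.normal(0.0, 0.5, n_cov),
        beta2=beta2,
        gamma={t: float(rng.normal(0.0, 0.7)) for t in treatments},
        reference_treatment="A",
    )


def rescale_for_identity(
    params: pa.OutcomeModelParams, spec: pa.PopulationSpec, margin: float = 0.45
) -> pa.OutcomeModelParams:
    """Shrink coefficients so identity-link probabilities stay inside [0, 1].

    Bounds the linear-predictor excursion over mean +/- 5 SD (or {0, 1} for
    binary covariates) and rescales every coefficient so the predictor stays
    within ``0.5 +/- margin`` for all arms.
    """
    xmax = np.array(
        [
            abs(m.mean) + 5.0 * m.sd if isinstance(m, pa.Normal) else 1.0
            for m in spec.marginals
        ]
    )
    dev = max(
        abs(params.gamma[t]) + float(np.abs(params.beta1 + params.beta2[t]) @ xmax)
        for t in params.treatments
    )
    s = margin / dev if dev > margin else 1.0
    return pa.OutcomeModelParams(
        link="identity",
        baselines={k: 0.5 for k in params.baselines},
        beta1=params.beta1 * s,
        beta2={t: b * s for t, b in params.beta2.items()},
        gamma={t: g * s for t, g in params.gamma.items()},
        reference_treatment=params.reference_treatment,
    )


def random_population(rng: np.random.Generator, n_cov: int, binary_ok: bool = True) -> pa.PopulationSpec:
    marginals = []
    for _ in range(n_cov):
        if binary_ok and rng.random() < 0.4:
            marginals.append(pa.Bernoulli(float(rng.uniform(0.2, 0.8))))
        else:
            marginals.append(pa.Normal(float(rng.normal(0, 1)), float(rng.uniform(0.3, 1.5))))
    if n_cov > 1:
        rho = float(rng.uniform(-0.5, 0.5))
        corr = np.full((n_cov, n_cov), rho)
        np.fill_diagonal(corr, 1.0)
    else:
        corr = None
    return pa.PopulationSpec(
        tuple(f"x{i+1}" for i in range(n_cov)), tuple(marginals), correlation=corr
    )
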