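"""Readers, writers and serialisation for trials, populations and parameters.

File conventions:

* IPD trials: CSV with header ``study,trt,<covariates...>,y`` and ``y`` in
  {0, 1}. One study per file.
* AgD trials, population specs, model parameters, fits and estimand reports:
  JSON (YAML is accepted on read and selected by file extension on write).
* Every round-trip is exact for all fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .estimands import EstimandEstimate
from .exceptions import ParseError, ValidationError
from .popmodel import (
    AgDTrial,
    ArmCounts,
    Bernoulli,
    IPDTrial,
    Normal,
    OutcomeModelParams,
    PointMass,
    PopulationSpec,
)

__all__ = [
    "read_ipd_csv",
    "write_ipd_csv",
    "read_agd_json",
    "write_agd_json",
    "population_to_dict",
    "population_from_dict",
    "params_to_dict",
    "params_from_dict",
    "estimate_to_dict",
    "read_structured",
    "write_structured",
]


# ---------------------------------------------------------------------------
# IPD CSV
# ---------------------------------------------------------------------------

def write_ipd_csv(ipd: IPDTrial, path: str | Path) -> None:
    df = ipd.data.copy()
    df.insert(0, "study", ipd.study)
    cols = ["study", "trt", *ipd.covariate_names, "y"]
    df[cols].to_csv(path, index=False)


def read_ipd_csv(path: str | Path) -> IPDTrial:
    """Read one IPD trial; malformed rows raise :class:`ParseError` with the line."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: could not parse CSV ({exc})") from exc
    required = {"study", "trt", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    covariates = tuple(c for c in df.columns if c not in required)
    if not covariates:
        raise ParseError(f"{path}: no covariate columns found")
    for col in (*covariates, "y"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ParseError(
                f"{path}: missing value in column {col!r} at line {bad[0] + 2}"
            )
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path}: column {col!r} is not numeric")
    bad_y = df.index[~df["y"].isin((0, 1))]
    if len(bad_y):
        raise ParseError(
            f"{path}: y must be 0 or 1; offending value "
            f"{df.loc[bad_y[0], 'y']!r} at line {bad_y[0] + 2}"
        )
    studies = df["study"].astype(str).unique()
    if len(studies) != 1:
        raise ParseError(f"{path}: expected a single study, found {sorted(studies)}")
    data = df.drop(columns=["study"])
    data["trt"] = data["trt"].astype(str)
    data["y"] = data["y"].astype(int)
    try:
        return IPDTrial(study=str(studies[0]), data=data, covariate_names=covariates)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Structured JSON / YAML
# ---------------------------------------------------------------------------

def read_structured(path: str | Path) -> Any:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            return yaml.safe_load(text)
        return json.loads(text)
    except Exception as exc:
        raise ParseError(f"{path}: could not parse ({exc})") from exc


def write_structured(obj: Any, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")


def write_agd_json(agd: AgDTrial, path: str | Path) -> None:
    write_structured(agd_to_dict(agd), path)


def agd_to_dict(agd: AgDTrial) -> dict:
    return {
        "study": agd.study,
        "arms": {k: {"n": v.n, "events": v.events} for k, v in agd.arms.items()},
        "covariates": {k: dict(v) for k, v in agd.covariate_summaries.items()},
    }


def agd_from_dict(obj: Mapping[str, Any], origin: str = "<agd>") -> AgDTrial:
    try:
        arms = {
            str(k): ArmCounts(n=int(v["n"]), events=int(v["events"]))
            for k, v in obj["arms"].items()
        }
        return AgDTrial(
            study=str(obj["study"]),
            arms=arms,
            covariate_summaries={str(k): dict(v) for k, v in obj.get("covariates", {}).items()},
        )
    except ValidationError:
        raise
    except Exception as exc:
        raise ParseError(f"{origin}: malformed AgD record ({exc})") from exc


def read_agd_json(path: str | Path) -> AgDTrial:
    return agd_from_dict(read_structured(path), origin=str(path))


# ---------------------------------------------------------------------------
# Populations and parameters
# ---------------------------------------------------------------------------

def _marginal_to_dict(m) -> dict:
    if isinstance(m, Normal):
        return {"dist": "normal", "mean": m.mean, "sd": m.sd}
    if isinstance(m, Bernoulli):
        return {"dist": "bernoulli", "p": m.p}
    if isinstance(m, PointMass):
        return {"dist": "point", "value": m.value}
    raise ValidationError(f"unknown marginal type {type(m).__name__}")


def _marginal_from_dict(d: Mapping[str, Any]):
    dist = d.get("dist")
    if dist == "normal":
        return Normal(float(d["mean"]), float(d["sd"]))
    if dist == "bernoulli":
        return Bernoulli(float(d["p"]))
    if dist == "point":
        return PointMass(float(d["value"]))
    raise ParseError(f"unknown marginal distribution {dist!r}")


def population_to_dict(spec: PopulationSpec) -> dict:
    return {
        "label": spec.label,
        "covariates": list(spec.covariate_names),
        "marginals": [_marginal_to_dict(m) for m in spec.marginals],
        "correlation": np.asarray(spec.correlation).tolist(),
        "provenance": spec.provenance,
    }


def population_from_dict(obj: Mapping[str, Any]) -> PopulationSpec:
    return PopulationSpec(
        covariate_names=tuple(obj["covariates"]),
        marginals=tuple(_marginal_from_dict(m) for m in obj["marginals"]),
        correlation=np.asarray(obj["correlation"], dtype=float)
        if obj.get("correlation") is not None
        else None,
        label=str(obj.get("label", "P")),
        provenance=str(obj.get("provenance", "")),
    )


def params_to_dict(params: OutcomeModelParams) -> dict:
    return {
        "link": params.link,
        "baselines": dict(params.baselines),
        "beta1": np.asarray(params.beta1).tolist(),
        "beta2": {k: np.asarray(v).tolist() for k, v in params.beta2.items()},
        "gamma": dict(params.gamma),
        "reference_treatment": params.reference_treatment,
    }


def params_from_dict(obj: Mapping[str, Any]) -> OutcomeModelParams:
    return OutcomeModelParams(
        link=str(obj["link"]),
        baselines={str(k): float(v) for k, v in obj["baselines"].items()},
        beta1=np.asarray(obj["beta1"], dtype=float),
        beta2={str(k): np.asarray(v, dtype=float) for k, v in obj["beta2"].items()},
        gamma={str(k): float(v) for k, v in obj["gamma"].items()},
        reference_treatment=str(obj.get("reference_treatment", "A")),
    )


def estimate_to_dict(est: EstimandEstimate) -> dict:
    """Flat record for an estimand report (JSON object or CSV row)."""
    return {
        "kind": est.kind,
        "scale": est.scale,
        "contrast": f"{est.contrast[1]} vs {est.contrast[0]}",
        "population": est.population,
        "estimate": est.estimate,
        "se": est.se,
        "method": est.method,
        **{f"meta_{k}": v for k, v in est.metadata.items()},
    }
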