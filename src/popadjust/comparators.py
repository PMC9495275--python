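"""Comparator estimators: MAIC, typical STC, and the unadjusted Bucher method.

All three produce anchored indirect comparisons of treatment C (aggregate
study) versus treatment B (subject-level study) through the common anchor A,
but they do not target the same estimand:

* **MAIC** reweights the AB subjects so their covariate moments match the AC
  population, then differences crude (marginal) contrasts — it targets the
  *marginal* population-average effect in the AC population.
* **Typical STC** subtracts a *conditional* treatment coefficient from an AB
  outcome regression (covariates centred at the AC means) from the *marginal*
  crude AC contrast. On a noncollapsible scale this mixes estimand families
  and is biased for both; its output is labelled ``mixed (typical STC)`` to
  make the mismatch explicit rather than hide it.
* **Bucher** differences the two crude contrasts with no adjustment — a
  marginal estimand, unbiased only when effect-modifier distributions agree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools import sm_exceptions

from .estimands import EstimandEstimate
from .exceptions import OverlapError, SingularFitError, ValidationError
from .mlnmr import ModelConfig
from .popmodel import AgDTrial, ArmCounts, IPDTrial, get_link

__all__ = [
    "MAICWeights",
    "maic_weights",
    "effective_sample_size",
    "maic_anchored",
    "stc_typical",
    "bucher",
    "crude_contrast",
]


# ---------------------------------------------------------------------------
# MAIC weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAICWeights:
    """Moment-matching weights for the IPD subjects.

    ``weights`` are normalised to sum to one. ``alpha`` are the coefficients of
    the log-linear weight model on the centred moment functions;
    ``max_moment_gap`` is the largest absolute difference between a weighted
    moment and its aggregate target.
    """

    weights: np.ndarray
    alpha: np.ndarray
    moment_order: int
    matched_covariates: tuple[str, ...]
    ess: float
    converged: bool
    max_moment_gap: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValidationError("weights must be nonnegative")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)


def effective_sample_size(w: "MAICWeights | np.ndarray") -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    weights = w.weights if isinstance(w, MAICWeights) else np.asarray(w, dtype=float)
    if (weights < 0).any():
        raise ValidationError("weights must be nonnegative")
    total_sq = float(weights.sum()) ** 2
    sq_total = float((weights**2).sum())
    if sq_total == 0.0:
        raise ValidationError("all weights are zero; effective sample size undefined")
    return total_sq / sq_total


def _moment_targets(
    ipd: IPDTrial, agd: AgDTrial, covariates: Sequence[str], moment_order: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Raw moment functions h(x) per subject and their aggregate targets.

    Order 1 matches means; order 2 additionally matches raw second moments
    (mean^2 + SD^2) of continuous covariates. Squared binary covariates are
    collinear with the mean and are skipped.
    """
    x = ipd.covariate_matrix(covariates)
    cols, targets, labels = [], [], []
    for j, name in enumerate(covariates):
        if name not in agd.covariate_summaries:
            raise ValidationError(f"AgD study has no summary for covariate {name!r}")
        summ = agd.covariate_summaries[name]
        target_mean = summ["mean"] if summ["type"] == "continuous" else summ["proportion"]
        cols.append(x[:, j])
        targets.append(float(target_mean))
        labels.append(name)
        if moment_order == 2 and summ["type"] == "continuous":
            cols.append(x[:, j] ** 2)
            targets.append(float(summ["mean"] ** 2 + summ["sd"] ** 2))
            labels.append(f"{name}^2")
    return np.column_stack(cols), np.asarray(targets), labels


def maic_weights(
    ipd: IPDTrial,
    agd: AgDTrial,
    covariates: Sequence[str],
    moment_order: int = 2,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> MAICWeights:
    """Method-of-moments weights matching IPD covariate moments to AgD targets.

    Solves the convex problem min_alpha sum_i exp(z_i' alpha), whose stationary
    point makes the weighted centred moments vanish, by Newton's method with
    step halving (moment functions standardised internally for conditioning).
    A target outside the convex hull of the observed moment functions admits
    no solution and raises :class:`OverlapError` — MAIC cannot extrapolate.
    """
    if moment_order not in (1, 2):
        raise ValidationError("moment_order must be 1 (means) or 2 (means and variances)")
    h, targets, labels = _moment_targets(ipd, agd, covariates, moment_order)
    n = h.shape[0]

    # necessary hull condition, per moment function
    for j, lab in enumerate(labels):
        lo, hi = h[:, j].min(), h[:, j].max()
        if lo == hi:
            if not math.isclose(lo, targets[j], rel_tol=0, abs_tol=1e-12):
                raise OverlapError(
                    f"moment {lab!r} is constant at {lo} in the IPD but the target "
                    f"is {targets[j]}; no weights can match it"
                )
        elif not (lo < targets[j] < hi):
            raise OverlapError(
                f"target for {lab!r} ({targets[j]:.6g}) lies outside the range of "
                f"the IPD values [{lo:.6g}, {hi:.6g}]; MAIC cannot extrapolate "
                "beyond the observed population"
            )

    z = h - targets
    keep = [j for j in range(z.shape[1]) if z[:, j].std() > 0]
    scale = np.ones(z.shape[1])
    scale[keep] = z[:, keep].std(axis=0)
    zs = z / scale

    alpha_s = np.zeros(zs.shape[1])
    converged = False
    for _ in range(max_iter):
        e = np.exp(zs @ alpha_s)
        grad = zs.T @ e
        if np.linalg.norm(grad, np.inf) < tol * max(1.0, e.sum()):
            converged = True
            break
        hess = (zs * e[:, None]).T @ zs
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(len(alpha_s)), -grad)
        except np.linalg.LinAlgError:
            raise OverlapError("singular moment system; targets not matchable") from None
        # step halving on the convex objective; near the optimum the descent
        # can fall below float precision, so accept to a relative tolerance
        f0 = e.sum()
        t = 1.0
        while t > 1e-8:
            cand = alpha_s + t * step
            f1 = np.exp(zs @ cand).sum()
            if f1 <= f0 * (1.0 + 1e-12) or not np.isfinite(f0):
                alpha_s = cand
                break
            t /= 2.0
        else:
            break
        if not np.isfinite(np.exp(zs @ alpha_s)).all() or np.linalg.norm(alpha_s) > 1e3:
            raise OverlapError(
                "weight coefficients are diverging; the moment targets sit on or "
                "outside the boundary of what the IPD population can represent"
            )
    if not converged:
        e = np.exp(zs @ alpha_s)
        grad = zs.T @ e
        converged = np.linalg.norm(grad, np.inf) < tol * max(1.0, e.sum())
    if not converged:
        raise OverlapError(
            "MAIC weight solver did not converge; the moment targets are at or "
            "beyond the edge of the IPD covariate distribution"
        )

    w = np.exp(zs @ alpha_s)
    w = w / w.sum()
    gaps = np.abs(w @ h - targets)
    return MAICWeights(
        weights=w,
        alpha=alpha_s / scale,
        moment_order=moment_order,
        matched_covariates=tuple(covariates),
        ess=effective_sample_size(w),
        converged=bool(converged),
        max_moment_gap=float(gaps.max()),
    )


# ---------------------------------------------------------------------------
# Crude (marginal) contrasts from 2x2-type tables
# ---------------------------------------------------------------------------

def _table_contrast(
    n_a: float, e_a: float, n_b: float, e_b: float, scale: str
) -> tuple[float, float]:
    """Crude contrast (b vs a) and its variance from (possibly weighted) counts."""
    if scale == "log-risk":  # the log link's scale is the log relative risk
        scale = "log-relative-risk"
    if min(e_a, n_a - e_a, e_b, n_b - e_b) <= 0.0:
        warnings.warn(
            "zero cell in a 2x2 table; adding a 0.5 continuity correction to "
            "all four cells",
            stacklevel=3,
        )
        e_a, e_b = e_a + 0.5, e_b + 0.5
        n_a, n_b = n_a + 1.0, n_b + 1.0
    pa, pb = e_a / n_a, e_b / n_b
    if scale == "log-odds":
        est = math.log(pb / (1 - pb)) - math.log(pa / (1 - pa))
        var = 1 / e_a + 1 / (n_a - e_a) + 1 / e_b + 1 / (n_b - e_b)
    elif scale == "risk-difference":
        est = pb - pa
        var = pa * (1 - pa) / n_a + pb * (1 - pb) / n_b
    elif scale == "log-relative-risk":
        est = math.log(pb / pa)
        var = (1 - pa) / e_a + (1 - pb) / e_b
    else:
        raise ValidationError(
            "scale must be 'log-odds', 'risk-difference' or 'log-relative-risk'"
        )
    return est, var


def crude_contrast(
    counts: Mapping[str, ArmCounts], a: str, b: str, scale: str = "log-odds"
) -> tuple[float, float]:
    """Unadjusted contrast (b vs a) and variance from per-arm counts."""
    ca, cb = counts[a], counts[b]
    return _table_contrast(ca.n, ca.events, cb.n, cb.events, scale)


def _anchor_and_active(trial_arms: frozenset[str], other_arms: frozenset[str]) -> tuple[str, str]:
    shared = trial_arms & other_arms
    if len(shared) != 1:
        raise ValidationError(
            f"trials must share exactly one anchor treatment; shared set {sorted(shared)}"
        )
    anchor = next(iter(shared))
    active = trial_arms - {anchor}
    if len(active) != 1:
        raise ValidationError(
            f"expected one non-anchor arm, found {sorted(active)}"
        )
    return anchor, next(iter(active))


# ---------------------------------------------------------------------------
# MAIC anchored comparison
# ---------------------------------------------------------------------------

def _weighted_arm(
    ipd: IPDTrial, w: np.ndarray, treatment: str
) -> tuple[float, float, np.ndarray, np.ndarray]:
    mask = (ipd.data["trt"].astype(str) == treatment).to_numpy()
    wa = w[mask]
    ya = ipd.data["y"].to_numpy(dtype=float)[mask]
    return float(wa.sum()), float(wa @ ya), wa, ya


def maic_anchored(
    ipd_ab: IPDTrial,
    agd_ac: AgDTrial,
    w: MAICWeights,
    scale: str = "log-odds",
    variance: str = "analytic",
    n_boot: int = 1000,
    boot_seed: int = 0,
) -> EstimandEstimate:
    """Anchored MAIC estimate of C vs B in the AC population.

    The AB contrast uses the weighted event table (reported on the effective
    sample size so continuity corrections act on interpretable pseudo-counts);
    the AC contrast is crude. With ``variance="analytic"`` (default) the SE
    combines a sandwich-style weighted variance for the AB term with the
    crude AgD variance; ``variance="bootstrap"`` instead resamples the IPD
    subjects and refits the weights ``n_boot`` times (fixed ``boot_seed``),
    keeping the analytic AgD term.
    """
    if len(w.weights) != ipd_ab.n:
        raise ValidationError("weights were not computed on this IPD trial")
    if variance not in ("analytic", "bootstrap"):
        raise ValidationError("variance must be 'analytic' or 'bootstrap'")
    anchor, b = _anchor_and_active(ipd_ab.arm_set, agd_ac.arm_set)
    _, c = _anchor_and_active(agd_ac.arm_set, ipd_ab.arm_set)

    # weighted AB contrast via ESS-scaled pseudo-counts
    cells = {}
    var_ab = 0.0
    for arm in (anchor, b):
        sw, swy, wa, ya = _weighted_arm(ipd_ab, w.weights, arm)
        if sw <= 0:
            raise ValidationError(f"arm {arm!r} has zero total weight")
        p_hat = swy / sw
        n_eff = effective_sample_size(wa)
        cells[arm] = (n_eff, p_hat * n_eff)
        # sandwich variance of the weighted proportion
        var_p = float(((wa / sw) ** 2 * (ya - p_hat) ** 2).sum())
        if scale == "log-odds":
            denom = max(p_hat * (1 - p_hat), 1e-12)
            var_ab += var_p / denom**2
        elif scale == "risk-difference":
            var_ab += var_p
        elif scale in ("log-relative-risk", "log-risk"):
            var_ab += var_p / max(p_hat, 1e-12) ** 2
        else:
            raise ValidationError(
                "scale must be 'log-odds', 'risk-difference' or 'log-relative-risk'"
            )
    est_ab, _ = _table_contrast(
        cells[anchor][0], cells[anchor][1], cells[b][0], cells[b][1], scale
    )
    est_ac, var_ac = crude_contrast(agd_ac.arms, anchor, c, scale)
    if variance == "bootstrap":
        var_ab = _bootstrap_ab_variance(
            ipd_ab, agd_ac, w, anchor, b, scale, n_boot, boot_seed
        )
    return EstimandEstimate(
        kind="marginal_population_average",
        scale=scale,
        contrast=(b, c),
        population=agd_ac.study,
        estimate=est_ac - est_ab,
        se=math.sqrt(var_ab + var_ac),
        method=f"MAIC (anchored, moments up to order {w.moment_order})",
        metadata={"ess": w.ess, "max_moment_gap": w.max_moment_gap},
    )


def _bootstrap_ab_variance(
    ipd_ab: IPDTrial,
    agd_ac: AgDTrial,
    w: MAICWeights,
    anchor: str,
    b: str,
    scale: str,
    n_boot: int,
    boot_seed: int,
) -> float:
    """Per-subject resampling variance of the weighted AB contrast.

    Each draw resamples the IPD subjects with replacement and refits the
    weights from scratch; draws whose resample loses overlap with the targets
    are skipped (they are counted, and more than 50% skips is an error).
    """
    rng = np.random.default_rng(boot_seed)
    n = ipd_ab.n
    stats, skipped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        data = ipd_ab.data.iloc[idx].reset_index(drop=True)
        if set(data["trt"].astype(str)) != {anchor, b}:
            skipped += 1
            continue
        boot = IPDTrial(ipd_ab.study, data, ipd_ab.covariate_names)
        try:
            wb = maic_weights(
                boot, agd_ac, w.matched_covariates, moment_order=w.moment_order
            )
        except OverlapError:
            skipped += 1
            continue
        cells = {}
        ok = True
        for arm in (anchor, b):
            sw, swy, wa, _ = _weighted_arm(boot, wb.weights, arm)
            if sw <= 0:
                ok = False
                break
            n_eff = effective_sample_size(wa)
            cells[arm] = (n_eff, (swy / sw) * n_eff)
        if not ok:
            skipped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est, _ = _table_contrast(
                cells[anchor][0], cells[anchor][1], cells[b][0], cells[b][1], scale
            )
        stats.append(est)
    if skipped > n_boot / 2:
        raise OverlapError(
            f"bootstrap failed: {skipped}/{n_boot} resamples lost overlap with "
            "the aggregate moment targets"
        )
    return float(np.var(stats, ddof=1))


# ---------------------------------------------------------------------------
# Typical STC
# ---------------------------------------------------------------------------

_SM_LINKS = {
    "logit": sm.families.links.Logit,
    "identity": sm.families.links.Identity,
    "log": sm.families.links.Log,
    "probit": sm.families.links.Probit,
}


def stc_typical(
    ipd_ab: IPDTrial, agd_ac: AgDTrial, config: ModelConfig
) -> EstimandEstimate:
    """Typical simulated treatment comparison, implemented in its flawed form.

    Regresses the AB outcomes on treatment and covariates centred at the AC
    means (effect modifiers also interact with treatment), takes the treatment
    coefficient — a *conditional* quantity — as the AB effect, and subtracts it
    from the *marginal* crude AC contrast. On a noncollapsible scale these two
    pieces are on different scales in a subtle sense, so the result estimates
    neither the marginal nor the conditional population-average effect; the
    returned kind says so.
    """
    anchor, b = _anchor_and_active(ipd_ab.arm_set, agd_ac.arm_set)
    _, c = _anchor_and_active(agd_ac.arm_set, ipd_ab.arm_set)
    for name in config.prognostic_set:
        if name not in agd_ac.covariate_summaries:
            raise ValidationError(f"AgD study has no summary for covariate {name!r}")

    x = ipd_ab.covariate_matrix(config.prognostic_set)
    centers = np.array([agd_ac.mean(nm) for nm in config.prognostic_set])
    xc = x - centers
    t = (ipd_ab.data["trt"].astype(str) == b).to_numpy(dtype=float)
    cols = [np.ones(ipd_ab.n), t, *xc.T]
    names = ["const", f"trt[{b}]", *config.prognostic_set]
    for em in config.effect_modifiers:
        j = config.prognostic_set.index(em)
        cols.append(t * xc[:, j])
        names.append(f"trt[{b}]:{em}")
    design = np.column_stack(cols)
    y = ipd_ab.data["y"].to_numpy(dtype=float)

    family = sm.families.Binomial(link=_SM_LINKS[config.link]())
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.GLM(y, design, family=family).fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes vary
        raise SingularFitError(f"STC outcome regression failed: {exc}") from exc
    if any(issubclass(w.category, sm_exceptions.PerfectSeparationWarning) for w in caught):
        raise SingularFitError("separation detected in the STC outcome regression")
    if not np.all(np.isfinite(fit.bse)) or np.abs(fit.params).max() > 1e3:
        raise SingularFitError(
            "STC outcome regression is separated or unidentified "
            f"(max |coef| = {np.abs(fit.params).max():.3g})"
        )
    idx = names.index(f"trt[{b}]")
    d_ab = float(fit.params[idx])
    se_ab = float(fit.bse[idx])

    scale = get_link(config.link).scale
    est_ac, var_ac = crude_contrast(agd_ac.arms, anchor, c, scale)
    return EstimandEstimate(
        kind="mixed (typical STC)",
        scale=scale,
        contrast=(b, c),
        population=agd_ac.study,
        estimate=est_ac - d_ab,
        se=math.sqrt(se_ab**2 + var_ac),
        method="typical STC (conditional AB effect minus marginal AC contrast)",
        metadata={
            "warning": 1.0,  # flags the estimand mismatch; see docstring
            "d_ab_conditional": d_ab,
            "delta_ac_marginal": est_ac,
        },
    )


# ---------------------------------------------------------------------------
# Bucher
# ---------------------------------------------------------------------------

def bucher(
    ab_counts: Mapping[str, ArmCounts] | AgDTrial,
    ac_counts: Mapping[str, ArmCounts] | AgDTrial,
    scale: str = "log-odds",
    population: str = "AC",
) -> EstimandEstimate:
    """Unadjusted anchored indirect comparison from the two crude tables.

    C vs B equals (C vs A) minus (B vs A); the variance is the sum of the two
    crude variances. Marginal estimand, specific to each trial's own
    population — unbiased only without effect-modifier imbalance.
    """
    arms_ab = ab_counts.arms if isinstance(ab_counts, AgDTrial) else dict(ab_counts)
    arms_ac = ac_counts.arms if isinstance(ac_counts, AgDTrial) else dict(ac_counts)
    anchor, b = _anchor_and_active(frozenset(arms_ab), frozenset(arms_ac))
    _, c = _anchor_and_active(frozenset(arms_ac), frozenset(arms_ab))
    est_ab, var_ab = crude_contrast(arms_ab, anchor, b, scale)
    est_ac, var_ac = crude_contrast(arms_ac, anchor, c, scale)
    return EstimandEstimate(
        kind="marginal_population_average",
        scale=scale,
        contrast=(b, c),
        population=population,
        estimate=est_ac - est_ab,
        se=math.sqrt(var_ab + var_ac),
        method="Bucher (unadjusted anchored comparison)",
    )
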