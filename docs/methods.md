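# Methods

This note records the modelling assumptions, numerical choices and
limitations behind `popadjust`, in the order a user meets them.

## Estimand taxonomy

Three families of treatment effect are distinguished, and every estimate the
package emits is labelled with one of them plus a measurement scale:

* **individual-level conditional** — the effect at specified covariate
  values; for this model class,
  $x^\top(\beta_{2,b}-\beta_{2,a}) + \gamma_b - \gamma_a$.
* **population-average conditional** $d_{ab}(P)$ — the individual-level
  effect averaged over population $P$. The linear predictor makes the
  average collapse to the plug-in at the population mean covariates, so
  $d_{ab}(P)$ is computed in closed form and is exact. It does not depend on
  the study baseline $\mu(P)$ or on the prognostic coefficients $\beta_1$.
* **marginal population-average** $\Delta_{ab}(P) = g(\bar p_b) - g(\bar p_a)$ —
  the contrast of population-average event probabilities. It depends on the
  baseline and on *all* prognostic variation, which is exactly why it is
  less transportable across populations than the conditional estimand.

For collapsible scales (identity link / risk difference) the two
population-average families coincide. For the logit link they differ
whenever prognostic covariates vary: averaging probabilities shrinks the
contrast, so the conditional effect lies strictly further from the null.
`cond_marg_ratio` returns the exact ratio $d/\Delta$ from integration.
`attenuation_approximation` additionally exposes the classical
logistic-normal closed form $\sqrt{1 + c^2\,\mathrm{var}(x^\top\beta_1)}$
with $c = 16\sqrt{3}/(15\pi)$; it is advisory only — it treats the
prognostic predictor as normal and ignores effect-modifier terms, and can
understate the attenuation when interactions contribute prognostic variance
(the exact ratio is always the ground truth).

## Populations and the synthetic evidence base

A `PopulationSpec` is a set of marginals (normal for continuous covariates,
Bernoulli for binary, point mass for degenerate) tied by a Gaussian copula.
This family was chosen because it admits exact mean vectors, cheap
correlated sampling and direct reconstruction from published summary tables;
it is a documented stand-in, not a claim about any particular real trial
population. Trial simulation draws covariates from the population, applies
the linear predictor and samples Bernoulli outcomes; identity and log links
abort with the offending row if a probability leaves $[0,1]$. Allocation is
equal per arm unless an explicit per-arm mapping is given.

What the generator does *not* emulate: missing data, dropout, measurement
error in covariates, non-proportional covariate effects, continuous or
time-to-event outcomes, and more than two studies. Passing tests therefore
demonstrate correctness of the estimand algebra and estimator implementations
under a clean randomized-trial data-generating process, not robustness to
real-data pathologies.

## Integration

Population averages are computed by one of three interchangeable rules:

* **qmc** (default, 4096 points): scrambled Sobol points pushed through the
  copula. The point stream is laid out as 8 *independently scrambled*
  replicates, so the batch variance across replicates is a statistically
  valid standard error. For discrete (Bernoulli) covariates the
  low-discrepancy stream has an additional near-deterministic threshold-
  crossing quantization error of order one point per scramble that batch
  variance cannot see; the reported error bound is floored at
  (range of integrand)/(points per scramble) in that case. This floor is a
  heuristic, which is why integral-identity tests use the tolerance
  `max(1e-4, 3 * error_bound)` rather than the error bound alone.
* **gauss-hermite**: tensor-product quadrature, available when all
  non-degenerate marginals are normal and at most 4 dimensions are
  stochastic; error reported as 0. Used wherever exactness matters (truth
  computation, closed-form identity checks).
* **mc**: plain Monte Carlo, mainly as an independent cross-check.

Both arms of a contrast are always evaluated on the *same* point set, which
cancels the shared component of the integration error in the difference.
Closed-form identities are tested to 1e-12; integral identities to
`max(1e-4, 3 * error_bound)` as above.

## ML-NMR fitting

The two-study anchored network (AB with IPD, AC with aggregate counts) is
fitted by maximum likelihood: the AB subjects contribute Bernoulli terms
through the linear predictor; each AC arm contributes a Binomial term whose
probability is the model integrated over the AC covariate distribution,
reconstructed from the published means/SDs/proportions with copula
correlations borrowed from the IPD trial (identity on request). A
frequentist fit was chosen over the Bayesian machinery usual for this model
class deliberately: the estimand algebra is estimation-method agnostic, and
maximum likelihood keeps the package desk-scale and dependency-light.

Numerical choices:

* Integration points for the aggregate likelihood are drawn once per fit and
  held fixed (common random numbers), making the objective smooth in the
  parameters.
* The linear predictor is linear in the full parameter vector, so the
  gradient of both likelihood terms is analytic — including the aggregate
  term, whose arm probability is a finite weighted average over the fixed
  points. BFGS with this gradient converges in ~15 iterations on the
  reference scenarios; up to 3 restarts from jittered starts (jitter seed
  derived from the integration seed) guard against rare stalls, and a
  residual gradient norm above 10x the 1e-6 tolerance raises a convergence
  error rather than returning a dubious fit.
* The covariance matrix is the inverse observed information, computed by
  central finite differences of the analytic gradient; non-positive-definite
  information (separation, unidentified parameters) raises an error.
* Estimand predictions delegate to the estimands module at the fitted
  parameters; standard errors are delta-method with finite-difference
  gradients, integration points again held fixed.
* Effect-modifier interactions are pooled across non-reference treatments by
  default (`shared_em=True`), the standard identifying assumption when each
  non-anchor treatment appears in only one study.

With point-mass AgD covariates the aggregate integral degenerates to a
plug-in and the joint fit coincides with a pooled GLM on the equivalent
stacked subject-level data; the test suite checks this equivalence against
statsmodels to 1e-6 (using the logit link, where the GLM oracle is
numerically robust).

## MAIC

Weights solve the convex problem $\min_\alpha \sum_i \exp(z_i^\top\alpha)$,
where $z_i$ stacks the centred moment functions: covariate minus target
mean, and for `moment_order=2` also the squared covariate minus the target
raw second moment (mean² + SD², so mean and variance are matched jointly).
Squared binary covariates are collinear with the mean and are skipped.
Newton's method with step halving on standardized moment columns converges
to a 1e-10 gradient tolerance; steps are accepted to a relative tolerance
because near the optimum the descent falls below float precision. Weighted
moments reproduce their targets to better than 1e-8 on every convergent run.

A target outside the convex hull of the observed moment values admits no
solution; this is detected per-coordinate up front and via solver divergence
otherwise, and raised as an overlap error — weighting cannot extrapolate
beyond the observed population, and the failure is reported as a finding,
never hidden. The Kish effective sample size $(\sum w)^2/\sum w^2$ is
attached to every weight set. One caution: adding the variance constraint
almost always costs ESS, but not strictly per-instance — the mean-tilt
coefficient can relax slightly when the variance term joins, and the test
suite demonstrates a small counterexample, so only the aggregate direction
is asserted.

The anchored estimate differences the weighted AB crude contrast from the
AgD crude contrast on the chosen scale (log odds ratio by default). The
default variance is a sandwich-style weighted variance for the AB term plus
the standard crude variance for the AgD term; a per-subject bootstrap
(resampling the IPD and refitting the weights, 1000 draws by default with a
fixed seed) is available as an alternative for the AB term. Zero cells
receive a 0.5 continuity correction on ESS-scaled pseudo-counts, always
with a warning.

## Typical STC

Implemented deliberately in its flawed conventional form: an outcome
regression on the AB subjects with covariates centred at the AgD means
(effect modifiers also interacting with treatment), whose treatment
coefficient — a conditional quantity — is subtracted from the marginal crude
AgD contrast. On a noncollapsible scale the result estimates neither
population-average estimand; asymptotically it misses the marginal truth by
the AB trial's conditional-marginal gap and the conditional truth by the AC
trial's gap. The returned estimand kind is `"mixed (typical STC)"` with a
warning flag in the metadata, so the mismatch is visible in every report.
Separation in the regression raises an error (detected via the GLM backend's
separation warning).

## Simulation harness

A scenario fixes both trial populations, the generating parameters, sample
sizes, estimators and replicate count. Replicate $r$ uses seed
`base_seed + r` (trial-level seeds derived through a seed sequence). Truth
is computed once with exact quadrature (QMC at $2^{16}$ points when
quadrature is unavailable) in the AC population, the common target of the
anchored comparison. Results report bias, empirical SE, MSE and 95% CI
coverage against *both* $d_{BC}$ and $\Delta_{BC}$; the two bias columns
differ by exactly $\Delta_{BC} - d_{BC}$ in every row, which the runner's
tests assert as an identity. Failed replicates (most commonly MAIC overlap
failures) are logged and counted, never silently dropped; a cell with more
than 50% failures is flagged invalid. Acceptance-level simulation checks use
3 Monte-Carlo SEs, trading strictness for desk-scale replicate counts
(200 replicates at 1000/arm for parameter recovery, 500 for the STC
mismatch exhibit, 100 for the acceptance script's scoring run).

## Known limitations

* Binary outcomes only; two-study anchored networks only; no unanchored
  comparisons, no random-effects heterogeneity, no MCMC posterior summaries.
* The Gaussian-copula population family cannot represent non-monotone
  dependence or heavy-tailed covariates.
* The worst-case conditional-vs-marginal difference across any *external*
  scenario grid can be computed with `cond_marg_ratio`, but the package
  ships no such grid; published bounds defined over unavailable scenario
  sets cannot be verified from here.
* The MAIC bootstrap variance resamples the IPD only; uncertainty in the
  published aggregate summaries themselves is not propagated by any of the
  estimators.
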