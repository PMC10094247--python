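# Methods

## Model

### Quasi-Bayesian mediation (continuous outcome)

For treatment `T` (Iso2 positivity, coded 0/1), mediator `M` and outcome
`Y`, two linear models are fit by ordinary least squares:

```
M = a0 + a1·T (+ C·g_m) + e_m
Y = b0 + c'·T + b·M (+ C·g_y) + e_y
```

Parameter uncertainty is propagated by drawing `sims` vectors from the
asymptotic normal of each fit, `N(coef, σ²(XᵀX)⁻¹)`, via the Cholesky
factor `√σ²·chol(XᵀX⁻¹)`.  Per draw:

- ACME (average causal mediation effect) = `a1·b`
- ADE (average direct effect) = `c'`
- total effect = ACME + ADE, exactly, by the linearity of the models —
  the decomposition identity holds per draw and therefore for the
  point estimates (means of draws).

Percentile intervals at `ci_level` give the CIs; the p-value is
`max(2·min(Pr(draw ≤ 0), Pr(draw ≥ 0)), 2/sims)` — it can never be
smaller than `2/sims`.  Monte-Carlo standard errors of the point
estimates (`sd(draws)/√sims`) are reported so downstream checks can
distinguish simulation noise from real discrepancy.

### Survival mediation (expected-survival-time scale)

The outcome model is a Weibull accelerated failure-time (AFT) regression
`log T = Xβ + σW` (`W` standard minimum extreme value), fit by maximum
likelihood over `(β, log σ)` with analytic gradients and covariance from
the inverse observed information.  Effects are decomposed on the scale of
expected survival time `E[T] = exp(Xβ)·Γ(1+σ)`.  Per parameter draw, the
four counterfactual means `h(t, M(t'))` are formed with per-subject
mediator prediction errors shared between `M(1)` and `M(0)`; the reported
decomposition averages the two treatment arms:

```
ACME  = ½[(h11 − h10) + (h01 − h00)]
ADE   = ½[(h11 − h01) + (h10 − h00)]
total = h11 − h00   (= ACME + ADE exactly, by telescoping)
```

### Exhaustive mediation screen

A candidate panel of `k` identifiers (gene rows plus pathway-score rows)
is enumerated as all `k²` ordered (mediator, target) pairs, including the
`k` self-referential diagonal pairs, which are reported with status
`degenerate` rather than silently dropped — the enumeration count is part
of the output contract.  Each pair gets a deterministic seed derived from
`(global seed, CRC32(mediator id), CRC32(target id))`, so results are
independent of panel order and of which other candidates are present; a
screen row is bitwise-reproducible by running the standalone mediation
function with the row's recorded seed.  A run is *significant* when both
the ACME and the total-effect simulation p-values are below `alpha`
(raw, by design — the frequency ranking is a triage step, but BH
q-values over all `ok` runs are also reported).  Mediator and target
frequency tables count appearances in significant runs.

### Survival primitives

- Kaplan–Meier and the k-sample log-rank test delegate to `lifelines`.
- The maximally selected cutpoint scans every admissible split
  (`marker > cut`, each side ≥ `min_fraction` of samples) with a
  vectorized two-group log-rank statistic; ties prefer the lower cutoff.
  The selected statistic is anti-conservative if its p-value is read from
  χ²(1); the package returns the statistic and leaves inference to the
  log-rank test on the chosen split, which inherits that caveat.
- Univariate Cox uses the Breslow partial likelihood with Newton–Raphson
  and step-halving; ties share the risk set of their tie run.
- The Weibull AFT fit exposes `fixed_log_scale` so the exponential
  special case has a closed form to test against.

### Other statistics

- Differential testing: Welch t with per-group variances shrunk toward
  the grand-mean pooled variance (prior df 4), Welch–Satterthwaite
  degrees of freedom credited with the prior df, BH adjustment.
  Features constant in both strata get p = 1 by convention.
- Single-sample set scores: integrated running-sum of the weighted
  in-set rank CDF minus the uniform out-of-set CDF, weight exponent 0.25,
  z-normalized per set across samples.
- Preranked enrichment: signed maximum deviation of the weighted KS
  running sum; null from random same-size sets; NES divides by the mean
  absolute same-sign null; p-values use +1 smoothing; BH across sets.
- Conditional association reversal: per-stratum Spearman correlation
  (rank-then-Pearson with the t approximation); a feature is reversed
  when both strata are individually significant with opposite signs.
  Under pure noise the per-feature flag rate is α²/2, which the tests
  verify against Poisson bounds.

## Synthetic cohort generator

`generate_cohort` plants a known chain.  Iso2 is zero-inflated
(`iso2_positive_fraction` of samples get a log-normal level, the rest are
exactly 0, making the positivity call unambiguous); TNF is
`1 + alpha1·1[iso2>0] + noise`; each of the five target-module genes is
`0.5 + beta1·1[iso2>0] + beta2·TNF + noise`.  True ACME = `alpha1·beta2`
(default 0.8), true ADE = `beta1` (default 0.3).  Decoy genes and
pathway-score-like decoy rows are pure noise.  Survival is Weibull
proportional hazards (shape 1.5, scale 5.0) with an
`gamma_iso1·iso1·1[iso2>0]` interaction in the log-hazard, so Iso1 is
prognostic only in Iso2-positive samples.  Censoring is Uniform(0, c)
with `c` calibrated by bisection so the expected censored fraction equals
`censor_rate`; the bound depends on the event-time draw only through a
scalar, keeping censoring independent of covariates.

`generate_survival_mediation_cohort` plants a pathway score that fully
mediates (by default) a continuous exposure's effect on survival:
`score = mediator_slope·iso1 + noise`,
`log T = 2 + direct_effect·iso1 + mediator_effect·score + σ·W`.

**Scope of the generator.**  Passing the planted-recovery and coverage
tests shows the estimator recovers effects *under its own assumptions* —
linear models, normal errors, correctly specified mediator and outcome
equations, no unmeasured confounding.  It does not validate the
sequential-ignorability assumption on real data, nor robustness to model
misspecification.

## Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| `sims` | 1000 (min 100) | CI endpoints stable to ~0.01 of the effect SE; p floor 0.002 |
| `alpha` | 0.05 | conventional screen threshold |
| `ci_level` | 0.95 | conventional |
| `minimum_group_fraction` | 0.1 | cutpoint scan admissibility |
| set-score weight exponent | 0.25 | mild rank weighting; keeps scores near-linear in ranks |
| variance-prior df | 4 | moderate shrinkage, dominates only for tiny strata |
| cohort defaults | n=500, ACME 0.8, ADE 0.3, noise 0.5 | effects ≈ 2 noise SDs: detectable but not trivial |

Problem sizes in the tests and acceptance script (panel sizes, seed
counts, replicate counts) are the package's own choices, scaled so the
full suite runs in well under a minute per module on one CPU while
keeping binomial/Poisson tolerance bands tight enough to catch real
calibration errors.

## Numerical choices

- All randomness flows from explicit integer seeds; derived seeds are
  produced by `numpy.random.SeedSequence` and masked below 2³¹.
- The draw order inside a mediation run (mediator parameters first, then
  outcome) is part of the reproducibility contract between the screen and
  the standalone function.
- The screen shares the mediator design factorization across all pairs
  with the same mediator, and the outcome design across targets, but
  every pair's draws go through the same kernel as the standalone path;
  agreement is at float round-off (~1e-13 relative).
- AFT optimization is BFGS on `(β, log σ)` with analytic gradients;
  covariance via a finite-difference Hessian at the optimum, with an
  eigenvalue-clipped fallback when the Cholesky of the covariance fails.
- Exponentials in the expected-time computation are clipped at ±700
  before `exp` to avoid overflow in extreme draws.

## Limitations

- Sequential ignorability is assumed, untestable, and likely violated in
  observational cohorts; screen output is a ranking of candidates for
  follow-up, not causal certification.
- The survival decomposition is tied to the Weibull AFT form; real
  hazards that cross or plateau will bias the expected-time scale.
- Raw-p significance in the screen controls nothing family-wise; the
  reported BH q-values should gate any confirmatory claim.
- The moderated differential test assumes roughly comparable variances
  across features for the shrinkage target to help.
- p-values from simulation are floored at `2/sims`; ranking by p below
  that floor is meaningless — use the effect size.
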