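"""Quasi-Bayesian causal mediation analysis for one (treatment, mediator,
outcome) triple.

The estimator follows the standard simulation-based potential-outcome
scheme: fit a mediator model M ~ T [+ C] and an outcome model
Y ~ T + M [+ C] (no treatment-mediator interaction, so ACME(0) = ACME(1)),
draw ``sims`` parameter vectors from the asymptotic multivariate normal of
each fit, and for every draw evaluate counterfactual predictions to obtain
the average causal mediation effect (ACME), average direct effect (ADE) and
total effect.  Point estimates are the means of the draws, intervals are
percentile intervals, and two-sided p-values are simulation tail
proportions floored at 2/sims.

For continuous outcomes both models are least squares and the per-draw
ACME reduces to the product of the treatment->mediator and
mediator->outcome coefficients, so ACME + ADE = total holds exactly per
draw.  For survival outcomes the outcome model is a Weibull accelerated
failure time regression and effects are evaluated on the expected survival
time scale E[T | t, M(t')] = exp(x beta) * Gamma(1 + sigma); the same
telescoping makes the decomposition exact per draw on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats, special

from .grouping import AnalysisError
from .survival import SurvivalData, weibull_aft_fit

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_FAILED = "failed"

_COLLINEAR_TOL = 1e-8


@dataclass
class MediationResult:
    """Point estimates, percentile CIs and simulation p-values of one run.

    ``acme_mc_se``/``total_mc_se`` are Monte-Carlo standard errors of the
    reported point estimates (sd of draws / sqrt(sims)); ``status`` is
    ``ok``, ``degenerate`` (self-referential or collinear models) or
    ``failed`` (outcome model did not converge).
    """

    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci_acme: tuple[float, float]
    ci_ade: tuple[float, float]
    ci_total: tuple[float, float]
    p_acme: float
    p_ade: float
    p_total: float
    acme_mc_se: float
    total_mc_se: float
    sims: int
    seed: int
    status: str = STATUS_OK

    def to_dict(self) -> dict:
        d = {
            "acme": self.acme,
            "ci_acme_lo": self.ci_acme[0],
            "ci_acme_hi": self.ci_acme[1],
            "p_acme": self.p_acme,
            "ade": self.ade,
            "ci_ade_lo": self.ci_ade[0],
            "ci_ade_hi": self.ci_ade[1],
            "p_ade": self.p_ade,
            "total": self.total,
            "ci_total_lo": self.ci_total[0],
            "ci_total_hi": self.ci_total[1],
            "p_total": self.p_total,
            "prop_mediated": self.prop_mediated,
            "acme_mc_se": self.acme_mc_se,
            "total_mc_se": self.total_mc_se,
            "sims": self.sims,
            "seed": self.seed,
            "status": self.status,
        }
        return d


def _invalid_result(sims: int, seed: int, status: str) -> MediationResult:
    nan = float("nan")
    return MediationResult(
        acme=nan, ade=nan, total=nan, prop_mediated=nan,
        ci_acme=(nan, nan), ci_ade=(nan, nan), ci_total=(nan, nan),
        p_acme=nan, p_ade=nan, p_total=nan,
        acme_mc_se=nan, total_mc_se=nan, sims=sims, seed=seed, status=status,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares fit returning (coef, (X'X)^-1, sigma^2 with df = n-p)."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    return coef, xtx_inv, sigma2


def _param_draws(
    rng: np.random.Generator,
    mean: np.ndarray,
    chol_lower: np.ndarray,
    sims: int,
) -> np.ndarray:
    """sims x p draws from N(mean, L L'); the z-draw order is part of the
    reproducibility contract shared with the screen's vectorized path."""
    z = rng.standard_normal((sims, mean.size))
    return mean + z @ chol_lower.T


def _sim_pvalue(draws: np.ndarray) -> float:
    sims = draws.size
    lo = float(np.mean(draws <= 0))
    hi = float(np.mean(draws >= 0))
    return max(2.0 * min(lo, hi), 2.0 / sims)


def _summarize(
    acme_d: np.ndarray,
    ade_d: np.ndarray,
    total_d: np.ndarray,
    ci_level: float,
    sims: int,
    seed: int,
) -> MediationResult:
    tail = (1.0 - ci_level) / 2.0
    q = np.array([tail, 1.0 - tail]) * 100.0

    acme = float(np.mean(acme_d))
    ade = float(np.mean(ade_d))
    total = float(np.mean(total_d))
    prop = acme / total if abs(total) > 1e-12 else float("nan")
    return MediationResult(
        acme=acme,
        ade=ade,
        total=total,
        prop_mediated=prop,
        ci_acme=tuple(np.percentile(acme_d, q)),
        ci_ade=tuple(np.percentile(ade_d, q)),
        ci_total=tuple(np.percentile(total_d, q)),
        p_acme=_sim_pvalue(acme_d),
        p_ade=_sim_pvalue(ade_d),
        p_total=_sim_pvalue(total_d),
        acme_mc_se=float(np.std(acme_d, ddof=1) / np.sqrt(sims)),
        total_mc_se=float(np.std(total_d, ddof=1) / np.sqrt(sims)),
        sims=sims,
        seed=seed,
        status=STATUS_OK,
    )


def _validate_vectors(treatment, mediator, n_outcome: int, covariates):
    t = np.asarray(treatment, dtype=float)
    m = np.asarray(mediator, dtype=float)
    if t.shape[0] != m.shape[0] or t.shape[0] != n_outcome:
        raise ValueError("treatment, mediator and outcome must have equal length")
    if np.var(t) == 0:
        raise AnalysisError("treatment is constant; both levels must be present")
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != t.shape[0]:
            C = C.T
        if C.shape[0] != t.shape[0]:
            raise ValueError("covariates must have one row per subject")
    return t, m, C


def _mediator_degenerate(t: np.ndarray, m: np.ndarray, C) -> bool:
    """Mediator carries no variation beyond the treatment (+covariates)."""
    X = np.column_stack([np.ones_like(t), t] + ([C] if C is not None else []))
    resid = m - X @ np.linalg.lstsq(X, m, rcond=None)[0]
    denom = max(float(np.var(m)), 1.0)
    return float(resid @ resid) / len(t) / denom < _COLLINEAR_TOL


def mediate_continuous(
    treatment: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    sims: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    control_value: float = 0.0,
    treat_value: float = 1.0,
) -> MediationResult:
    """Quasi-Bayesian mediation with a continuous outcome (both models OLS).

    The treatment may be binary (the conventional 0/1 positivity indicator)
    or continuous; effects are reported for the contrast
    ``treat_value`` vs ``control_value``.
    """
    y = np.asarray(outcome, dtype=float)
    t, m, C = _validate_vectors(treatment, mediator, y.shape[0], covariates)
    if _mediator_degenerate(t, m, C):
        return _invalid_result(sims, seed, STATUS_DEGENERATE)

    extra = [C] if C is not None else []
    X_m = np.column_stack([np.ones_like(t), t] + extra)
    X_y = np.column_stack([np.ones_like(t), t, m] + extra)
    if np.linalg.matrix_rank(X_y) < X_y.shape[1]:
        return _invalid_result(sims, seed, STATUS_DEGENERATE)

    coef_m, xtx_m, s2_m = _ols(X_m, m)
    coef_y, xtx_y, s2_y = _ols(X_y, y)
    chol_m = np.sqrt(s2_m) * np.linalg.cholesky(xtx_m)
    chol_y = np.sqrt(s2_y) * np.linalg.cholesky(xtx_y)

    rng = np.random.default_rng(seed)
    acme_d, ade_d, total_d = _continuous_draws(
        rng, coef_m, chol_m, coef_y, chol_y, sims, treat_value - control_value
    )
    return _summarize(acme_d, ade_d, total_d, ci_level, sims, seed)


def _continuous_draws(
    rng: np.random.Generator,
    coef_m: np.ndarray,
    chol_m: np.ndarray,
    coef_y: np.ndarray,
    chol_y: np.ndarray,
    sims: int,
    contrast: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared draw kernel: mediator params first, then outcome params.

    Without interaction, per draw ACME = a1 * b * contrast and
    ADE = c' * contrast, so the decomposition is exact.
    """
    theta_m = _param_draws(rng, coef_m, chol_m, sims)
    theta_y = _param_draws(rng, coef_y, chol_y, sims)
    a1 = theta_m[:, 1]
    cprime = theta_y[:, 1]
    b = theta_y[:, 2]
    acme_d = a1 * b * contrast
    ade_d = cprime * contrast
    return acme_d, ade_d, acme_d + ade_d


def mediate_survival(
    treatment: np.ndarray,
    mediator: np.ndarray,
    outcome: SurvivalData,
    covariates: np.ndarray | None = None,
    sims: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    control_value: float = 0.0,
    treat_value: float = 1.0,
) -> MediationResult:
    """Quasi-Bayesian mediation with a Weibull AFT survival outcome.

    Effects are reported on the expected-survival-time scale: for each
    parameter draw, potential mediator values M_i(t') are simulated from
    the mediator model (with a per-subject error draw shared between the
    two counterfactual treatment values), plugged into
    E[T | t, m] = exp(b0 + bT t + bM m [+ C d]) * Gamma(1 + sigma), and
    averaged over subjects.  A non-convergent outcome fit or a cohort with
    no events yields a ``failed`` result rather than an exception.
    """
    t, m, C = _validate_vectors(treatment, mediator, len(outcome), covariates)
    if _mediator_degenerate(t, m, C):
        return _invalid_result(sims, seed, STATUS_DEGENERATE)

    extra = [C] if C is not None else []
    X_m = np.column_stack([np.ones_like(t), t] + extra)
    coef_m, xtx_m, s2_m = _ols(X_m, m)
    chol_m = np.sqrt(s2_m) * np.linalg.cholesky(xtx_m)
    sigma_m = np.sqrt(s2_m)

    design = np.column_stack([t, m] + extra)
    try:
        aft = weibull_aft_fit(outcome, design)
    except AnalysisError:
        return _invalid_result(sims, seed, STATUS_FAILED)
    if not aft.converged or not np.all(np.isfinite(aft.covariance)):
        return _invalid_result(sims, seed, STATUS_FAILED)

    rng = np.random.default_rng(seed)
    theta_m = _param_draws(rng, coef_m, chol_m, sims)
    mean_y = np.r_[aft.coefficients, aft.log_scale]
    try:
        chol_y = np.linalg.cholesky(aft.covariance)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(aft.covariance)
        chol_y = np.linalg.cholesky(v @ np.diag(np.maximum(w, 1e-12)) @ v.T)
    theta_y = _param_draws(rng, mean_y, chol_y, sims)
    eps = rng.standard_normal((sims, t.size)) * sigma_m

    n = t.size
    ones = np.ones(n)

    def mediator_pred(tv: float) -> np.ndarray:
        cols = [ones, np.full(n, tv)] + ([C] if C is not None else [])
        Xt = np.column_stack(cols)
        return theta_m @ Xt.T + eps  # sims x n

    M1 = mediator_pred(treat_value)
    M0 = mediator_pred(control_value)

    b0 = theta_y[:, 0][:, None]
    bT = theta_y[:, 1][:, None]
    bM = theta_y[:, 2][:, None]
    extra_lin = 0.0
    if C is not None:
        extra_lin = (C @ theta_y[:, 3:-1].T).T  # sims x n
    gamma_term = special.gamma(1.0 + np.exp(theta_y[:, -1]))[:, None]

    def expected_time(tv: float, M: np.ndarray) -> np.ndarray:
        lin = b0 + bT * tv + bM * M + extra_lin
        return np.exp(np.clip(lin, -700, 700)) * gamma_term

    h11 = expected_time(treat_value, M1).mean(axis=1)
    h10 = expected_time(treat_value, M0).mean(axis=1)
    h01 = expected_time(control_value, M1).mean(axis=1)
    h00 = expected_time(control_value, M0).mean(axis=1)

    acme_d = 0.5 * ((h11 - h10) + (h01 - h00))
    ade_d = 0.5 * ((h11 - h01) + (h10 - h00))
    total_d = h11 - h00  # == acme_d + ade_d by telescoping
    return _summarize(acme_d, ade_d, total_d, ci_level, sims, seed)


def total_effect(
    treatment: np.ndarray,
    outcome: np.ndarray | SurvivalData,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Marginal treatment -> outcome effect with a Wald p-value.

    Continuous outcome: the OLS coefficient of T in Y ~ T [+ C]; survival
    outcome: the log-time coefficient of T in a Weibull AFT fit.  A
    constant continuous outcome returns (0.0, 1.0) by convention.
    """
    t = np.asarray(treatment, dtype=float)
    if np.var(t) == 0:
        raise AnalysisError("treatment is constant")
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != t.shape[0]:
            C = C.T

    if isinstance(outcome, SurvivalData):
        design = np.column_stack([t] + ([C] if C is not None else []))
        aft = weibull_aft_fit(outcome, design)
        est = float(aft.coefficients[1])
        se = float(np.sqrt(aft.covariance[1, 1]))
        p = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0
        return est, p

    y = np.asarray(outcome, dtype=float)
    if np.var(y) == 0:
        return 0.0, 1.0
    X = np.column_stack([np.ones_like(t), t] + ([C] if C is not None else []))
    coef, xtx_inv, s2 = _ols(X, y)
    est = float(coef[1])
    se = float(np.sqrt(s2 * xtx_inv[1, 1]))
    if se == 0:
        return est, 1.0
    df = len(t) - X.shape[1]
    p = float(2.0 * stats.t.sf(abs(est) / se, df))
    return est, p
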