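"""Survival analysis: Kaplan-Meier curves, log-rank tests, univariate Cox
regression, optimal log-rank cutpoints, four-group isoform stratification,
and Weibull accelerated-failure-time fitting.

Kaplan-Meier estimation and the multi-group log-rank test delegate to
lifelines.  The univariate Cox model is a direct Newton-Raphson maximization
of the Breslow partial likelihood (the tie convention is fixed here rather
than configurable), because downstream code needs its score and information
explicitly.  The Weibull AFT model is fit by maximum likelihood on
(beta, log sigma) with the covariance taken as the inverse observed
information -- the parameterization the quasi-Bayesian mediation draws
require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .grouping import AnalysisError


@dataclass
class SurvivalData:
    """Right-censored times with event indicators (True/1 = event observed)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event).astype(bool)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if self.time.size == 0:
            raise ValueError("empty survival data")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("all survival times must be positive and finite")

    def __len__(self) -> int:
        return self.time.size


class KaplanMeierCurve:
    """Right-continuous product-limit survival curve, callable at any time."""

    def __init__(self, times: np.ndarray, survival: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.survival = np.asarray(survival, dtype=float)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


def km_estimate(data: SurvivalData) -> KaplanMeierCurve:
    """Product-limit estimator of the survival function."""
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=data.event)
    sf = kmf.survival_function_
    return KaplanMeierCurve(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy())


def logrank_test(data: SurvivalData, groups: np.ndarray) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (chi-square, df, p)."""
    groups = np.asarray(groups)
    if groups.shape[0] != len(data):
        raise ValueError("groups length must match survival data")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise AnalysisError("log-rank test needs >= 2 nonempty groups")
    res = multivariate_logrank_test(data.time, groups, data.event)
    return float(res.test_statistic), int(labels.size - 1), float(res.p_value)


def _two_group_logrank_chi2(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> float:
    """Vectorized two-group log-rank chi-square (no p-value)."""
    order = np.argsort(time, kind="stable")
    t, d, g = time[order], event[order].astype(float), in_group1[order].astype(float)
    n = t.size
    # at-risk counts just before each ordered time
    at_risk = n - np.arange(n)
    at_risk1 = g[::-1].cumsum()[::-1]
    uniq, start = np.unique(t, return_index=True)
    # events per distinct time, and events in group 1
    d_tot = np.add.reduceat(d, start)
    d1 = np.add.reduceat(d * g, start)
    n_tot = at_risk[start].astype(float)
    n1 = at_risk1[start]
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d_tot * n1 / n_tot
        var = np.where(
            n_tot > 1,
            d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1),
            0.0,
        )
    o_minus_e = float(np.sum(d1 - expected))
    v = float(np.sum(var))
    if v <= 0:
        return 0.0
    return o_minus_e**2 / v


@dataclass
class CoxFit:
    log_hr: float
    se: float
    p: float
    iterations: int
    converged: bool
    loglik: float
    score_residual: float


def cox_univariate(
    data: SurvivalData,
    covariate: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Univariate Cox proportional-hazards fit (Breslow ties, Newton-Raphson).

    Returns the log hazard ratio with its Wald standard error and p-value.
    Non-convergence within ``max_iter`` is flagged, not raised.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape[0] != len(data):
        raise ValueError("covariate length must match survival data")
    if np.var(x) == 0:
        raise AnalysisError("covariate is constant")
    if not np.any(data.event):
        raise AnalysisError("no events observed")

    order = np.argsort(-data.time, kind="stable")  # decreasing time
    t, d, xv = data.time[order], data.event[order], x[order]

    def score_info(beta: float) -> tuple[float, float, float]:
        w = np.exp(beta * xv)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xv)
        s2 = np.cumsum(w * xv * xv)
        # subjects tied on time share one risk set: use the last index of each tie run
        last_of_run = np.r_[t[1:] != t[:-1], True]
        idx = np.where(last_of_run, np.arange(t.size), t.size)
        run_idx = np.minimum.accumulate(idx[::-1])[::-1]
        # risk set for time t_i = all subjects with time >= t_i
        r0, r1, r2 = s0[run_idx], s1[run_idx], s2[run_idx]
        ll = float(np.sum((beta * xv - np.log(r0))[d]))
        score = float(np.sum((xv - r1 / r0)[d]))
        info = float(np.sum((r2 / r0 - (r1 / r0) ** 2)[d]))
        return ll, score, info

    beta = 0.0
    converged = False
    it = 0
    ll, score, info = score_info(beta)
    for it in range(1, max_iter + 1):
        if info <= 0:
            break
        step = score / info
        # step-halving against likelihood decrease
        for _ in range(20):
            ll_new, score_new, info_new = score_info(beta + step)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta += step
        ll, score, info = ll_new, score_new, info_new
        if abs(score) < tol:
            converged = True
            break
    se = float(np.sqrt(1.0 / info)) if info > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) else 1.0
    return CoxFit(
        log_hr=float(beta),
        se=se,
        p=p,
        iterations=it,
        converged=converged,
        loglik=ll,
        score_residual=abs(score),
    )


def optimal_cutpoint(
    data: SurvivalData,
    marker: np.ndarray,
    min_fraction: float = 0.1,
) -> tuple[float, float]:
    """Marker threshold maximizing the two-group log-rank statistic.

    Scans every admissible split (group = marker > cutoff) leaving at least
    ``min_fraction`` of the samples on each side; ties on the statistic are
    broken toward the lower cutoff.  Note the returned maximum is a
    maximally selected statistic and is inflated relative to a prespecified
    split.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.shape[0] != len(data):
        raise ValueError("marker length must match survival data")
    if np.var(marker) == 0:
        raise AnalysisError("marker is constant; no split exists")
    if not 0.0 < min_fraction < 0.5:
        raise ValueError(f"min_fraction must be in (0, 0.5), got {min_fraction}")

    n = marker.size
    min_count = min_fraction * n
    best_cut, best_stat = None, -np.inf
    for cut in np.unique(marker)[:-1]:
        high = marker > cut
        n_high = int(high.sum())
        if n_high < min_count or (n - n_high) < min_count:
            continue
        stat = _two_group_logrank_chi2(data.time, data.event, high)
        if stat > best_stat:
            best_cut, best_stat = float(cut), float(stat)
    if best_cut is None:
        raise AnalysisError(
            f"no admissible split with min_fraction={min_fraction} per side"
        )
    return best_cut, best_stat


FOUR_GROUP_LABELS = (
    "iso1_high_iso2_high",
    "iso1_high_iso2_low",
    "iso1_low_iso2_high",
    "iso1_low_iso2_low",
)


def stratify_four_groups(
    iso1: np.ndarray, iso2: np.ndarray, cut1: float, cut2: float
) -> np.ndarray:
    """Cross-classify samples by strict '>' against each isoform cutoff."""
    iso1 = np.asarray(iso1, dtype=float)
    iso2 = np.asarray(iso2, dtype=float)
    if iso1.shape != iso2.shape:
        raise ValueError("iso1 and iso2 must have equal length")
    if not (np.all(np.isfinite(iso1)) and np.all(np.isfinite(iso2))):
        raise ValueError("isoform values must be finite")
    high1, high2 = iso1 > cut1, iso2 > cut2
    labels = np.empty(iso1.shape, dtype=object)
    labels[high1 & high2] = FOUR_GROUP_LABELS[0]
    labels[high1 & ~high2] = FOUR_GROUP_LABELS[1]
    labels[~high1 & high2] = FOUR_GROUP_LABELS[2]
    labels[~high1 & ~high2] = FOUR_GROUP_LABELS[3]
    return labels


@dataclass
class AftFit:
    """Weibull AFT maximum-likelihood fit.

    ``coefficients`` are on the log-time scale (intercept first);
    ``log_scale`` is log sigma of log T = X beta + sigma W with W standard
    minimum extreme value.  ``covariance`` is the inverse observed
    information over (beta, log sigma) -- or beta only when the scale was
    held fixed.
    """

    coefficients: np.ndarray
    log_scale: float
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_events: int
    scale_fixed: bool = False

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))


def weibull_aft_fit(
    data: SurvivalData,
    covariates: np.ndarray | None = None,
    fixed_log_scale: float | None = None,
) -> AftFit:
    """Maximum-likelihood Weibull accelerated-failure-time regression.

    log T = b0 + X b + sigma W, W ~ standard minimum extreme value.  The
    intercept is always included; ``covariates`` is n x p (or None for an
    intercept-only model).  A rank-deficient design raises
    :class:`AnalysisError`; non-convergence is flagged on the returned fit.
    """
    n = len(data)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
        X = np.column_stack([np.ones(n), covariates])
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise AnalysisError("design matrix is rank deficient")
    if not np.any(data.event):
        raise AnalysisError("no events observed")

    log_t = np.log(data.time)
    delta = data.event.astype(float)
    n_events = int(delta.sum())

    def unpack(theta):
        if fixed_log_scale is None:
            return theta[:p], theta[p]
        return theta, fixed_log_scale

    def negloglik(theta):
        beta, log_sigma = unpack(theta)
        sigma = np.exp(log_sigma)
        z = (log_t - X @ beta) / sigma
        ez = np.exp(np.clip(z, -700, 700))
        ll = np.sum(delta * (-log_sigma + z) - ez)
        return -ll

    # gradient of the negative loglik
    def neg_grad(theta):
        beta, log_sigma = unpack(theta)
        sigma = np.exp(log_sigma)
        z = (log_t - X @ beta) / sigma
        ez = np.exp(np.clip(z, -700, 700))
        g_beta = X.T @ (ez - delta) / sigma  # d(ll)/d(beta)
        if fixed_log_scale is None:
            g_ls = float(np.sum(z * ez) - np.sum(delta * (1.0 + z)))
            return -np.r_[g_beta, g_ls]
        return -g_beta

    beta0, *_ = np.linalg.lstsq(X, log_t, rcond=None)
    resid_sd = float(np.std(log_t - X @ beta0))
    theta0 = np.r_[beta0, np.log(max(resid_sd, 1e-2))]
    if fixed_log_scale is not None:
        theta0 = beta0

    res = optimize.minimize(
        negloglik, theta0, jac=neg_grad, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    converged = bool(res.success or np.linalg.norm(neg_grad(res.x)) < 1e-4)
    hess = approx_hess(res.x, negloglik)
    try:
        covariance = np.linalg.inv(hess)
        covariance = (covariance + covariance.T) / 2.0
    except np.linalg.LinAlgError:
        covariance = np.full((res.x.size, res.x.size), np.nan)
        converged = False

    if fixed_log_scale is None:
        coef, log_scale = res.x[:p], float(res.x[p])
        scale_fixed = False
    else:
        coef, log_scale = res.x, float(fixed_log_scale)
        scale_fixed = True
    return AftFit(
        coefficients=coef,
        log_scale=log_scale,
        covariance=covariance,
        loglik=float(-res.fun),
        converged=converged,
        n_events=n_events,
        scale_fixed=scale_fixed,
    )
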