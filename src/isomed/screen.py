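"""Exhaustive pairwise mediation screening and the conditional analyses
built on it.

The screen enumerates every ordered (mediator, target) pair over a candidate
panel of genes and pathway scores -- diagonal self-pairs included, so a
panel of g genes and p pathways yields exactly (g + p)^2 runs -- and runs
one quasi-Bayesian mediation per pair with the isoform-positivity indicator
as treatment.  Self-pairs are recorded but flagged degenerate (the outcome
model would regress a variable on itself).  Each pair's random stream is
keyed by (global seed, mediator id, target id), so results are identical
under any execution order or parallel split.

A run is called significant when both its ACME and its total effect reach
raw p < alpha; BH-adjusted columns are reported alongside for transparency.
Mediator and target frequency tables count appearances among significant
runs only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .grouping import AnalysisError, benjamini_hochberg
from .io import ConfigError, RunConfig
from .mediation import (
    STATUS_DEGENERATE,
    STATUS_OK,
    _COLLINEAR_TOL,
    _continuous_draws,
    _summarize,
    mediate_survival,
)
from .survival import SurvivalData


@dataclass
class CandidatePanel:
    """Candidate mediator/target identifiers: gene features plus pathway
    score rows.  Combined identifiers must be unique."""

    gene_ids: list[str]
    pathway_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        combined = list(self.gene_ids) + list(self.pathway_ids)
        if len(combined) != len(set(combined)):
            dups = sorted({i for i in combined if combined.count(i) > 1})
            raise ConfigError(f"duplicate panel identifiers: {dups}")
        if not combined:
            raise ConfigError("candidate panel is empty")

    @property
    def all_ids(self) -> list[str]:
        return list(self.gene_ids) + list(self.pathway_ids)

    def __len__(self) -> int:
        return len(self.gene_ids) + len(self.pathway_ids)


def enumerate_pairs(panel: CandidatePanel) -> list[tuple[str, str]]:
    """All ordered (mediator, target) pairs, row-major over the panel order."""
    ids = panel.all_ids
    return [(m, t) for m in ids for t in ids]


def pair_seed(global_seed: int, mediator_id: str, target_id: str) -> int:
    """Deterministic per-pair seed keyed by pair identity, not run index."""
    ss = np.random.SeedSequence(
        [
            int(global_seed) & 0x7FFFFFFF,
            zlib.crc32(mediator_id.encode()),
            zlib.crc32(target_id.encode()),
        ]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ScreenResult:
    """All enumerated runs plus frequency rankings over the significant ones."""

    runs: pd.DataFrame
    n_enumerated: int
    mediator_freq: pd.DataFrame
    target_freq: pd.DataFrame
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.runs["significant"].sum())


def _resolve_values(
    expr: pd.DataFrame, scores: pd.DataFrame | None, ids: list[str]
) -> np.ndarray:
    rows = []
    missing = []
    for i in ids:
        if i in expr.index:
            rows.append(expr.loc[i].to_numpy(dtype=float))
        elif scores is not None and i in scores.index:
            rows.append(scores.loc[i].to_numpy(dtype=float))
        else:
            missing.append(i)
    if missing:
        raise ConfigError(f"panel identifiers not found in expression or scores: {missing}")
    return np.vstack(rows)


def run_screen(
    expr: pd.DataFrame,
    scores: pd.DataFrame | None,
    treatment: np.ndarray,
    panel: CandidatePanel,
    config: RunConfig,
) -> ScreenResult:
    """Run the full ordered-pair mediation screen.

    Model fits are vectorized (the mediator design is shared by every
    mediator, and for a fixed mediator the outcome design is shared by
    every target); the quasi-Bayesian draws are generated pair by pair from
    each pair's own seeded stream, which keeps the screen embarrassingly
    order-independent.
    """
    treatment = np.asarray(treatment, dtype=float)
    if treatment.shape[0] != expr.shape[1]:
        raise ValueError("treatment length must match the number of samples")
    if np.var(treatment) == 0:
        raise AnalysisError("treatment is constant; both levels must be present")
    ids = panel.all_ids
    V = _resolve_values(expr, scores, ids)  # panel x samples
    n = treatment.shape[0]
    k = len(ids)
    sims, alpha, ci = config.sims, config.alpha, config.ci_level

    ones = np.ones(n)
    X_m = np.column_stack([ones, treatment])
    xtx_m_inv = np.linalg.inv(X_m.T @ X_m)
    L_m = np.linalg.cholesky(xtx_m_inv)
    coef_m = (xtx_m_inv @ (X_m.T @ V.T)).T  # k x 2
    resid_m = V - coef_m @ X_m.T
    s2_m = np.einsum("ij,ij->i", resid_m, resid_m) / (n - 2)
    # mediator indistinguishable from the treatment -> degenerate
    var_m = np.maximum(V.var(axis=1), 1.0)
    mediator_degen = (np.einsum("ij,ij->i", resid_m, resid_m) / n / var_m) < _COLLINEAR_TOL

    records: list[dict] = []
    for i, med in enumerate(ids):
        singular = True
        if not mediator_degen[i]:
            X_y = np.column_stack([ones, treatment, V[i]])
            xtx_y = X_y.T @ X_y
            singular = np.linalg.matrix_rank(xtx_y) < 3
            if not singular:
                xtx_y_inv = np.linalg.inv(xtx_y)
                L_y = np.linalg.cholesky(xtx_y_inv)
                coef_y = (xtx_y_inv @ (X_y.T @ V.T)).T  # k x 3
                resid_y = V - coef_y @ X_y.T
                s2_y = np.einsum("ij,ij->i", resid_y, resid_y) / (n - 3)
        for j, tgt in enumerate(ids):
            if i == j or mediator_degen[i] or singular:
                records.append(
                    {
                        "mediator_id": med,
                        "target_id": tgt,
                        "acme": np.nan,
                        "p_acme": np.nan,
                        "total": np.nan,
                        "p_total": np.nan,
                        "ade": np.nan,
                        "p_ade": np.nan,
                        "status": STATUS_DEGENERATE,
                        "seed": pair_seed(config.seed, med, tgt),
                    }
                )
                continue
            seed = pair_seed(config.seed, med, tgt)
            rng = np.random.default_rng(seed)
            chol_m_i = np.sqrt(s2_m[i]) * L_m
            chol_y_ij = np.sqrt(s2_y[j]) * L_y
            acme_d, ade_d, total_d = _continuous_draws(
                rng, coef_m[i], chol_m_i, coef_y[j], chol_y_ij, sims, 1.0
            )
            res = _summarize(acme_d, ade_d, total_d, ci, sims, seed)
            records.append(
                {
                    "mediator_id": med,
                    "target_id": tgt,
                    "acme": res.acme,
                    "p_acme": res.p_acme,
                    "total": res.total,
                    "p_total": res.p_total,
                    "ade": res.ade,
                    "p_ade": res.p_ade,
                    "status": STATUS_OK,
                    "seed": seed,
                }
            )

    runs = pd.DataFrame.from_records(records)
    ok = runs["status"] == STATUS_OK
    runs["q_acme"] = np.nan
    runs["q_total"] = np.nan
    if ok.any():
        runs.loc[ok, "q_acme"] = benjamini_hochberg(runs.loc[ok, "p_acme"].to_numpy())
        runs.loc[ok, "q_total"] = benjamini_hochberg(runs.loc[ok, "p_total"].to_numpy())
    runs["significant"] = ok & (runs["p_acme"] < alpha) & (runs["p_total"] < alpha)

    sig = runs[runs["significant"]]
    mediator_freq = (
        sig.groupby("mediator_id").size().rename("count").reset_index()
        .sort_values(["count", "mediator_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    target_freq = (
        sig.groupby("target_id").size().rename("count").reset_index()
        .sort_values(["count", "target_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return ScreenResult(
        runs=runs,
        n_enumerated=k * k,
        mediator_freq=mediator_freq,
        target_freq=target_freq,
        alpha=alpha,
    )


def survival_mediation(
    exposure: np.ndarray,
    mediator_scores: pd.DataFrame,
    survival: SurvivalData,
    config: RunConfig,
    control_value: float = 0.0,
    treat_value: float = 1.0,
) -> pd.DataFrame:
    """Mediation of a continuous exposure's prognostic effect through each
    pathway score.

    Per pathway: mediator model score ~ exposure (linear), outcome model
    Weibull AFT time ~ exposure + score, effects on the expected
    survival-time scale.  BH-adjusted ACME p-values are reported across
    pathways alongside the raw ones; failed fits are flagged per pathway.
    """
    exposure = np.asarray(exposure, dtype=float)
    if np.var(exposure) == 0:
        raise AnalysisError("exposure is constant")
    if mediator_scores.shape[0] == 0:
        raise AnalysisError("no mediator pathway supplied")

    rows = []
    for name in mediator_scores.index:
        seed = pair_seed(config.seed, str(name), "__survival__")
        res = mediate_survival(
            exposure,
            mediator_scores.loc[name].to_numpy(dtype=float),
            survival,
            sims=config.sims,
            ci_level=config.ci_level,
            seed=seed,
            control_value=control_value,
            treat_value=treat_value,
        )
        row = res.to_dict()
        row["pathway"] = str(name)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("pathway")
    ok = table["status"] == STATUS_OK
    table["q_acme"] = np.nan
    if ok.any():
        table.loc[ok, "q_acme"] = benjamini_hochberg(table.loc[ok, "p_acme"].to_numpy())
    return table


def _spearman_vs_vector(values: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman correlation of each row of ``values`` with ``x`` plus the
    t-approximation p-value (the convention scipy uses for n > 2)."""
    n = x.shape[0]
    rx = rankdata(x)
    rv = rankdata(values, axis=1)
    rx_c = rx - rx.mean()
    rv_c = rv - rv.mean(axis=1, keepdims=True)
    denom = np.sqrt((rv_c**2).sum(axis=1) * (rx_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, rv_c @ rx_c / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(t_stat), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, np.clip(p, 0.0, 1.0))
    return r, p


def conditional_association_reversal(
    expr: pd.DataFrame,
    scores: pd.DataFrame | None,
    iso1: np.ndarray,
    iso2_positive: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Features whose Iso1 association flips sign between Iso2 strata.

    Each feature (gene row, plus pathway-score row when given) is Spearman-
    correlated with iso1 separately within the Iso2-positive and
    Iso2-negative strata; a feature is flagged ``reversed`` when both
    correlations are individually significant (p < alpha) with opposite
    signs.  Under pure noise the expected flag rate per feature is
    alpha^2 / 2.
    """
    iso1 = np.asarray(iso1, dtype=float)
    iso2_positive = np.asarray(iso2_positive, dtype=bool)
    if iso1.shape[0] != expr.shape[1] or iso2_positive.shape[0] != expr.shape[1]:
        raise ValueError("iso1 and iso2_positive must match the sample count")
    n_pos, n_neg = int(iso2_positive.sum()), int((~iso2_positive).sum())
    if n_pos < 3:
        raise AnalysisError(f"Iso2-positive stratum has {n_pos} samples, need >= 3")
    if n_neg < 3:
        raise AnalysisError(f"Iso2-negative stratum has {n_neg} samples, need >= 3")

    frames = [expr] if scores is None else [expr, scores]
    values = pd.concat(frames, axis=0)
    arr = values.to_numpy(dtype=float)

    r_pos, p_pos = _spearman_vs_vector(arr[:, iso2_positive], iso1[iso2_positive])
    r_neg, p_neg = _spearman_vs_vector(arr[:, ~iso2_positive], iso1[~iso2_positive])
    reversed_flag = (p_pos < alpha) & (p_neg < alpha) & (r_pos * r_neg < 0)
    return pd.DataFrame(
        {
            "r_pos": r_pos,
            "p_pos": p_pos,
            "r_neg": r_neg,
            "p_neg": p_neg,
            "reversed": reversed_flag,
        },
        index=values.index,
    )


def intersect_reversed(reversal: pd.DataFrame, candidate_ids: list[str]) -> list[str]:
    """Intersection of reversed features with an upstream candidate list,
    preserving the candidate order."""
    reversed_ids = set(reversal.index[reversal["reversed"]])
    return [c for c in candidate_ids if c in reversed_ids]
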