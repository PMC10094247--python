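"""Per-sample gene-set activity scores and preranked gene-set enrichment.

The sample-wise score is an ssGSEA-style rank statistic: within each sample,
features are ranked (average ranks on ties) and a weighted running sum walks
the ranked list from the top; the score is the integral (sum over all list
positions) of the difference between the weighted in-set empirical CDF and
the uniform out-of-set CDF.  Scores therefore depend on expression only
through within-sample ranks and are invariant to any strictly monotone
per-sample transform.

Preranked GSEA uses the classical maximum-deviation weighted
Kolmogorov-Smirnov running sum with a set-label permutation null,
sign-matched normalization (NES), +1-smoothed permutation p-values, and BH
q-values across the tested collection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grouping import AnalysisError, benjamini_hochberg

DEFAULT_WEIGHT = 0.25


def ssgsea_sample_score(
    expr_ranks: np.ndarray,
    in_set: np.ndarray,
    weight_exponent: float = DEFAULT_WEIGHT,
) -> float:
    """Integrated running-sum score of one gene set in one sample.

    Parameters
    ----------
    expr_ranks:
        Within-sample ranks of all features (1..n, average ranks on ties;
        rank n = highest expression).
    in_set:
        Boolean membership mask aligned with ``expr_ranks``.
    weight_exponent:
        Exponent applied to the in-set ranks (0 gives the unweighted KS
        walk; 0.25 is the conventional default).
    """
    ranks = np.asarray(expr_ranks, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = ranks.shape[0]
    k = int(in_set.sum())
    if k == 0:
        raise AnalysisError("gene set has no member among the ranked features")

    # walk the list from highest to lowest rank
    order = np.argsort(-ranks, kind="stable")
    member = in_set[order]
    weights = np.abs(ranks[order]) ** weight_exponent

    in_steps = np.where(member, weights, 0.0)
    denom_in = in_steps.sum()
    cdf_in = np.cumsum(in_steps) / denom_in if denom_in > 0 else np.zeros(n)
    if n > k:
        out_steps = np.where(member, 0.0, 1.0 / (n - k))
        cdf_out = np.cumsum(out_steps)
    else:
        cdf_out = np.zeros(n)
    return float(np.sum(cdf_in - cdf_out))


def score_matrix(
    expr: pd.DataFrame,
    collection,
    weight_exponent: float = DEFAULT_WEIGHT,
    normalize: bool = True,
) -> pd.DataFrame:
    """Gene-set x sample activity-score matrix.

    Sets with no member among the matrix features are skipped with a
    warning; if none overlaps, an :class:`AnalysisError` is raised.  With
    ``normalize`` each set's scores are z-scored across samples, making
    downstream regression coefficients comparable between pathways.
    """
    features = expr.index
    ranks = rankdata(expr.to_numpy(dtype=float), axis=0)  # per-sample, ties averaged

    rows: dict[str, np.ndarray] = {}
    for name in collection.names():
        mask = np.asarray(features.isin(collection[name]))
        if not mask.any():
            warnings.warn(f"gene set {name!r} has no member in the matrix; skipped")
            continue
        rows[name] = np.array(
            [
                ssgsea_sample_score(ranks[:, j], mask, weight_exponent)
                for j in range(ranks.shape[1])
            ]
        )
    if not rows:
        raise AnalysisError("no gene set overlaps the expression matrix features")

    scores = pd.DataFrame(rows, index=expr.columns).T
    if normalize:
        values = scores.to_numpy()
        sd = values.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        scores = pd.DataFrame(
            (values - values.mean(axis=1, keepdims=True)) / sd,
            index=scores.index,
            columns=scores.columns,
        )
    return scores


def _gsea_es(stat_sorted_desc: np.ndarray, member: np.ndarray, weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = stat_sorted_desc.shape[0]
    k = int(member.sum())
    hit = np.abs(stat_sorted_desc) ** weight * member
    denom = hit.sum()
    if denom == 0:
        # all in-set statistics are zero: fall back to unweighted steps
        hit = member.astype(float)
        denom = hit.sum()
    steps = hit / denom - (~member).astype(float) / (n - k)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranking: pd.Series,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> dict:
    """Enrichment of one gene set toward the extremes of a ranked statistic.

    ``ranking`` maps feature -> real statistic (e.g. a differential t
    statistic).  The null is built by drawing ``n_perm`` random same-size
    sets; NES divides ES by the mean |null ES| of matching sign, and the
    p-value is the same-sign permutation tail with +1 smoothing.  The q
    field is filled by :func:`preranked_gsea_collection`; a single-set call
    reports q = p.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    stats_arr = ranking.to_numpy(dtype=float)
    if np.allclose(stats_arr, stats_arr[0]):
        raise AnalysisError("degenerate ranking: all statistics equal")
    member = np.asarray(ranking.index.isin(gene_set))
    k = int(member.sum())
    if k < 2:
        raise AnalysisError(f"gene set overlaps ranking in {k} features, need >= 2")
    if k == len(ranking):
        raise AnalysisError("gene set covers the whole ranking; ES undefined")

    order = np.argsort(-stats_arr, kind="stable")
    sorted_stats = stats_arr[order]
    member_sorted = member[order]
    es = _gsea_es(sorted_stats, member_sorted, weight)

    rng = np.random.default_rng(seed)
    n = len(ranking)
    null_es = np.empty(n_perm)
    positions = np.arange(n)
    for b in range(n_perm):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(positions, size=k, replace=False)] = True
        null_es[b] = _gsea_es(sorted_stats, perm_mask, weight)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes, p = np.sign(es) * np.inf, 1.0 / (n_perm + 1)
    else:
        mean_abs = float(np.mean(np.abs(null_es[same_sign])))
        nes = es / mean_abs if mean_abs > 0 else 0.0
        exceed = int(np.sum(np.abs(null_es[same_sign]) >= abs(es)))
        p = (1 + exceed) / (1 + n_same)
    return {"es": es, "nes": nes, "p": float(p), "q": float(p), "n_overlap": k}


def preranked_gsea_collection(
    ranking: pd.Series,
    collection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Run preranked GSEA per set and BH-adjust p into FDR q across sets."""
    rows = {}
    for i, name in enumerate(collection.names()):
        try:
            rows[name] = preranked_gsea(
                ranking, collection[name], n_perm=n_perm, seed=seed + i, weight=weight
            )
        except AnalysisError as exc:
            warnings.warn(f"gene set {name!r} skipped: {exc}")
    if not rows:
        raise AnalysisError("no gene set could be tested against the ranking")
    table = pd.DataFrame(rows).T
    table.index.name = "set_name"
    table["q"] = benjamini_hochberg(table["p"].to_numpy(dtype=float))
    return table
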