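"""Isoform fractions, positivity calls, moderated differential testing, and
hypergeometric over-representation analysis.

Positivity uses a strict ``> threshold`` rule with threshold 0 by default:
a transcript observed at exactly zero is treated as undetected.  The
differential test is a Welch two-sample t statistic whose per-group
variances are shrunk toward the grand mean variance with a fixed prior
weight, stabilizing small-sample estimates without a full empirical-Bayes
hyperparameter fit; p-values are Benjamini-Hochberg adjusted across all
features of one contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: prior pseudo-degrees of freedom for variance shrinkage
VARIANCE_PRIOR_DF = 4.0


class AnalysisError(ValueError):
    """Inputs are structurally valid but unusable for this analysis."""


def isoform_fractions(iso_values: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample isoform fractions for one gene.

    Parameters
    ----------
    iso_values:
        Non-negative array of shape (n_isoforms, n_samples).

    Returns
    -------
    fractions:
        Same shape; columns sum to 1 where the sample total is positive.
        All-zero samples get all-zero fractions.
    undefined:
        Boolean per-sample flag marking the all-zero (undefined) samples.
    """
    values = np.asarray(iso_values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"expected 2-D (isoforms x samples), got shape {values.shape}")
    if np.any(values < 0):
        raise ValueError("isoform values must be non-negative")
    totals = values.sum(axis=0)
    undefined = totals == 0
    safe_totals = np.where(undefined, 1.0, totals)
    fractions = values / safe_totals
    fractions[:, undefined] = 0.0
    return fractions, undefined


def call_positivity(values: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Strict-inequality positivity call: positive iff value > threshold."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("positivity requires finite values")
    return values > threshold


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    return multipletests(pvalues, method="fdr_bh")[1]


def differential_test(
    expr: pd.DataFrame,
    groups: np.ndarray,
    alpha_adj: float = 0.05,
) -> pd.DataFrame:
    """Moderated two-sample test of every feature between two strata.

    Parameters
    ----------
    expr:
        Features x samples log-scale expression.
    groups:
        Boolean per-sample vector (True = positive stratum); both strata
        need at least two samples.
    alpha_adj:
        Adjusted-p threshold defining the ``significant`` flag.

    Returns
    -------
    DataFrame indexed by feature with columns effect (mean difference,
    positive = up in the True stratum), statistic, p, p_adjusted, direction,
    significant.  Features constant in both strata get p = 1 and effect 0
    by convention.
    """
    groups = np.asarray(groups, dtype=bool)
    if groups.shape[0] != expr.shape[1]:
        raise ValueError(
            f"groups length {groups.shape[0]} != n_samples {expr.shape[1]}"
        )
    n1, n0 = int(groups.sum()), int((~groups).sum())
    if n1 < 2 or n0 < 2:
        raise AnalysisError(
            f"both strata need >= 2 samples, got {n1} positive / {n0} negative"
        )

    x1 = expr.to_numpy(dtype=float)[:, groups]
    x0 = expr.to_numpy(dtype=float)[:, ~groups]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1, v0 = x1.var(axis=1, ddof=1), x0.var(axis=1, ddof=1)
    effect = m1 - m0

    # shrink per-group variances toward the grand mean pooled variance
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    v_prior = float(pooled.mean())
    d0 = VARIANCE_PRIOR_DF
    v1_mod = (d0 * v_prior + (n1 - 1) * v1) / (d0 + n1 - 1)
    v0_mod = (d0 * v_prior + (n0 - 1) * v0) / (d0 + n0 - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1_mod / n1 + v0_mod / n0
        statistic = np.where(se2 > 0, effect / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
        # Welch-Satterthwaite df on the moderated variances, credited with d0
        df_num = se2**2
        df_den = (v1_mod / n1) ** 2 / (n1 - 1) + (v0_mod / n0) ** 2 / (n0 - 1)
        df = np.where(df_den > 0, df_num / df_den, 1.0) + d0
    p = 2.0 * stats.t.sf(np.abs(statistic), df)

    degenerate = (v1 == 0) & (v0 == 0) & (effect == 0)
    p = np.where(degenerate, 1.0, p)
    statistic = np.where(degenerate, 0.0, statistic)
    p = np.clip(p, 0.0, 1.0)

    p_adjusted = benjamini_hochberg(p)
    result = pd.DataFrame(
        {
            "effect": effect,
            "statistic": statistic,
            "p": p,
            "p_adjusted": p_adjusted,
            "direction": np.where(effect >= 0, "up", "down"),
            "significant": p_adjusted < alpha_adj,
        },
        index=expr.index,
    )
    return result


def ora_hypergeometric(
    hits: list[str],
    gene_set: list[str],
    universe: list[str],
) -> tuple[int, float, float]:
    """Upper-tail hypergeometric over-representation of ``hits`` in ``gene_set``.

    The effective set is the intersection of the set with the universe.
    Returns (overlap count, p-value of >= observed overlap, enrichment
    ratio (k/n)/(K/N)).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    hit_set = set(hits)
    if not hit_set <= universe_set:
        raise ValueError("hits must be a subset of the universe")
    eff_set = set(gene_set) & universe_set

    N, K, n = len(universe_set), len(eff_set), len(hit_set)
    k = len(hit_set & eff_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K and n else 1.0
    ratio = (k / n) / (K / N) if K and n else 0.0
    return k, min(p, 1.0), ratio


def ora_collection(
    hits: list[str],
    collection,
    universe: list[str],
) -> pd.DataFrame:
    """Run :func:`ora_hypergeometric` over every set and BH-adjust across sets."""
    rows = []
    for name in collection.names():
        k, p, ratio = ora_hypergeometric(hits, collection[name], universe)
        rows.append({"set_name": name, "overlap": k, "p": p, "enrichment_ratio": ratio})
    table = pd.DataFrame(rows).set_index("set_name")
    table["p_adjusted"] = benjamini_hochberg(table["p"].to_numpy())
    return table
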