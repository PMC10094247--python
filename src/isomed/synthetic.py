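"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a tumor cohort carrying two transcript isoforms of an
immune-checkpoint gene: a dominant full-length isoform (Iso1, continuous
log-expression) and a truncated isoform (Iso2) that is zero-inflated --
undetected in roughly half of the samples and strictly positive otherwise.
A single causal chain is planted on the log-expression scale:

    1[Iso2 > 0]  --alpha1-->  TNF  --beta2-->  T-cell module genes

with an optional direct edge (beta1) from Iso2 positivity to the module
genes.  Decoy genes are i.i.d. Gaussian noise in log space.  Survival times
follow a Weibull proportional-hazards model whose log hazard contains an
Iso1 effect that is active only in Iso2-positive samples, with independent
uniform censoring; this mirrors the downstream conditional-prognosis
analyses.  Every draw is keyed to the spec seed, so identical specs produce
bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ConfigError, GeneSetCollection

MEDIATOR_GENE = "TNF"
#: planted downstream T-cell proliferation module (targets of the chain)
TARGET_GENES = ("CD3D", "CD3E", "CD8A", "GZMB", "PRF1")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    alpha1 -- effect of Iso2 positivity on the mediator TNF (log units);
    beta2  -- effect of TNF on each target gene (per log unit);
    beta1  -- direct Iso2-positivity effect on each target gene;
    gamma_iso1 -- log-hazard effect of Iso1, active only when Iso2 positive;
    censor_rate -- target fraction of censored subjects (independent uniform
    censoring calibrated on the drawn event times).
    """

    n_samples: int = 500
    n_decoy_genes: int = 50
    n_pathways: int = 10
    iso2_positive_fraction: float = 0.5
    alpha1: float = 1.0
    beta2: float = 0.8
    beta1: float = 0.3
    gamma_iso1: float = 0.7
    noise_sd: float = 0.5
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 20:
            raise ConfigError(f"n_samples must be >= 20, got {self.n_samples}")
        if self.n_decoy_genes < 1:
            raise ConfigError(f"n_decoy_genes must be >= 1, got {self.n_decoy_genes}")
        if self.n_pathways < 1:
            raise ConfigError(f"n_pathways must be >= 1, got {self.n_pathways}")
        if not 0.0 < self.iso2_positive_fraction < 1.0:
            raise ConfigError(
                "iso2_positive_fraction must be strictly between 0 and 1, "
                f"got {self.iso2_positive_fraction}"
            )
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError(f"censor_rate must be in [0, 1), got {self.censor_rate}")


@dataclass
class GroundTruth:
    """Planted effects for recovery tests: true ACME is alpha1*beta2 for
    every (TNF, target) pair, true ADE is beta1."""

    true_acme: float
    true_ade: float
    mediator_ids: list[str]
    target_ids: list[str]
    survival_interaction: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _calibrate_uniform_censoring(times: np.ndarray, censor_rate: float) -> float:
    """Upper bound c of the Uniform(0, c) censoring law such that the
    expected censored fraction over the drawn event times equals censor_rate.

    P(C < t) = min(t/c, 1) for C ~ U(0, c); solve mean_i min(t_i/c, 1) =
    censor_rate by bisection.  The bound depends on the event-time draw only
    through this scalar, so censoring stays independent of the covariates.
    """
    lo, hi = float(np.min(times)) * 1e-3, float(np.max(times)) * 1e6

    def censored_frac(c: float) -> float:
        return float(np.mean(np.minimum(times / c, 1.0)))

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_frac(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one cohort: (expression features x samples, annotation, truth).

    Expression rows are iso1, iso2, TNF, the five target-module genes,
    ``DECOY_i`` noise genes and ``PW_DECOY_i`` pathway-score-like noise rows.
    The annotation carries iso1/iso2, the positivity group label, and
    censored survival (time, event).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    positive = rng.random(n) < spec.iso2_positive_fraction
    pos = positive.astype(float)
    # zero-inflated Iso2: exactly 0 when undetected, log-normal magnitude when present
    iso2 = np.where(positive, rng.lognormal(mean=0.0, sigma=0.5, size=n), 0.0)
    iso1 = rng.normal(loc=2.0, scale=0.8, size=n)

    alpha0, beta0 = 1.0, 0.5
    tnf = alpha0 + spec.alpha1 * pos + rng.normal(0.0, spec.noise_sd, size=n)

    rows: dict[str, np.ndarray] = {"iso1": iso1, "iso2": iso2, MEDIATOR_GENE: tnf}
    for gene in TARGET_GENES:
        rows[gene] = (
            beta0
            + spec.beta1 * pos
            + spec.beta2 * tnf
            + rng.normal(0.0, spec.noise_sd, size=n)
        )
    for i in range(spec.n_decoy_genes):
        rows[f"DECOY_{i:03d}"] = rng.normal(0.0, 1.0, size=n)
    for i in range(spec.n_pathways):
        rows[f"PW_DECOY_{i:03d}"] = rng.normal(0.0, 1.0, size=n)

    expr = pd.DataFrame(rows, index=samples).T

    # Weibull PH survival: h(t|x) = h0(t) exp(gamma_iso1 * iso1 * 1[iso2>0])
    shape_k, scale_lambda = 1.5, 5.0
    eta = spec.gamma_iso1 * iso1 * pos
    u = rng.random(n)
    event_time = scale_lambda * (-np.log(u) / np.exp(eta)) ** (1.0 / shape_k)
    if spec.censor_rate > 0:
        c_max = _calibrate_uniform_censoring(event_time, spec.censor_rate)
        censor_time = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)

    annotation = pd.DataFrame(
        {
            "iso1": iso1,
            "iso2": iso2,
            "group": np.where(positive, "iso2_pos", "iso2_neg"),
            "time": time,
            "event": event,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    truth = GroundTruth(
        true_acme=spec.alpha1 * spec.beta2,
        true_ade=spec.beta1,
        mediator_ids=[MEDIATOR_GENE],
        target_ids=list(TARGET_GENES),
        survival_interaction=spec.gamma_iso1,
    )
    return expr, annotation, truth


def generate_gene_sets(
    truth: GroundTruth,
    features: list[str],
    n_sets: int,
    set_size: int,
    seed: int,
) -> GeneSetCollection:
    """One planted set containing the ground-truth targets plus n_sets-1
    random decoy sets drawn without replacement from the feature universe."""
    if set_size < 2:
        raise ConfigError(f"set_size must be >= 2, got {set_size}")
    if set_size > len(features):
        raise ConfigError(
            f"set_size {set_size} exceeds available feature count {len(features)}"
        )
    if n_sets < 1:
        raise ConfigError(f"n_sets must be >= 1, got {n_sets}")
    rng = np.random.default_rng(seed)
    pool = [f for f in features if f not in truth.target_ids]

    planted = list(truth.target_ids)
    if set_size > len(planted):
        extra = rng.choice(pool, size=set_size - len(planted), replace=False)
        planted = planted + [str(g) for g in extra]

    sets = {"PLANTED_TARGET_MODULE": planted}
    descriptions = {"PLANTED_TARGET_MODULE": "planted downstream module"}
    for i in range(n_sets - 1):
        members = rng.choice(features, size=set_size, replace=False)
        name = f"DECOY_SET_{i:03d}"
        sets[name] = [str(g) for g in members]
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def generate_survival_mediation_cohort(
    n_samples: int = 500,
    mediator_slope: float = 1.0,
    mediator_effect: float = -0.5,
    direct_effect: float = 0.0,
    noise_sd: float = 0.5,
    log_scale_sigma: float = 0.6,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, "np.ndarray", "np.ndarray", np.ndarray]:
    """Cohort for survival-mediation checks: a continuous exposure (iso1),
    one pathway score that fully (or partially) transmits its survival
    effect, and Weibull AFT event times.

        score = mediator_slope * iso1 + N(0, noise_sd)
        log T = b0 + mediator_effect * score + direct_effect * iso1 + sigma * W

    Returns (scores 1 x n DataFrame, iso1, time, event).  With
    direct_effect = 0 the exposure harms survival only through the score
    (full mediation); with mediator_slope = 0 the score is an independent
    decoy.
    """
    rng = np.random.default_rng(seed)
    iso1 = rng.normal(0.0, 1.0, size=n_samples)
    score = mediator_slope * iso1 + rng.normal(0.0, noise_sd, size=n_samples)
    b0 = 2.0
    # W ~ standard minimum extreme value: log(-log U), U uniform
    w = np.log(-np.log(rng.random(n_samples)))
    log_t = b0 + mediator_effect * score + direct_effect * iso1 + log_scale_sigma * w
    event_time = np.exp(log_t)
    if censor_rate > 0:
        c_max = _calibrate_uniform_censoring(event_time, censor_rate)
        censor_time = rng.uniform(0.0, c_max, size=n_samples)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n_samples, dtype=int)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    scores = pd.DataFrame({"PW_PLANTED": score}, index=samples).T
    return scores, iso1, time, event
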