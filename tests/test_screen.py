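import numpy as np
import pandas as pd
import pytest

from isomed.grouping import AnalysisError
from isomed.io import ConfigError, RunConfig
from isomed.mediation import mediate_continuous
from isomed.screen import (
    CandidatePanel,
    ScreenResult,
    conditional_association_reversal,
    enumerate_pairs,
    intersect_reversed,
    pair_seed,
    run_screen,
    survival_mediation,
)
from isomed.survival import SurvivalData
from isomed.synthetic import CohortSpec, generate_cohort, generate_survival_mediation_cohort


class TestEnumeratePairs:
    def test_full_panel_arithmetic(self):
        panel = CandidatePanel(
            gene_ids=[f"G{i}" for i in range(365)],
            pathway_ids=[f"P{i}" for i in range(77)],
        )
        pairs = enumerate_pairs(panel)
        assert len(pairs) == 195_364
        assert len(panel) == 442

    def test_singleton_panel(self):
        pairs = enumerate_pairs(CandidatePanel(gene_ids=["A"]))
        assert pairs == [("A", "A")]

    def test_exhaustive_small_panel(self):
        panel = CandidatePanel(gene_ids=["A", "B"], pathway_ids=["P"])
        pairs = enumerate_pairs(panel)
        assert len(pairs) == 9
        assert len(set(pairs)) == 9
        assert sum(m == t for m, t in pairs) == 3

    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ConfigError):
            CandidatePanel(gene_ids=["A", "B"], pathway_ids=["A"])

    def test_pair_seed_keyed_by_identity(self):
        assert pair_seed(1, "A", "B") == pair_seed(1, "A", "B")
        assert pair_seed(1, "A", "B") != pair_seed(1, "B", "A")
        assert pair_seed(1, "A", "B") != pair_seed(2, "A", "B")
        assert 0 <= pair_seed(3, "X", "Y") < 2**31


@pytest.fixture(scope="module")
def screen_setup():
    spec = CohortSpec(n_samples=300, n_decoy_genes=10, seed=19)
    expr, annot, truth = generate_cohort(spec)
    pos = (annot["iso2"] > 0).to_numpy().astype(float)
    ids = ["TNF", "CD3D"] + [f"DECOY_{i:03d}" for i in range(6)]
    panel = CandidatePanel(gene_ids=ids)
    config = RunConfig(sims=200, seed=5)
    result = run_screen(expr, None, pos, panel, config)
    return expr, pos, panel, config, result


class TestRunScreen:
    def test_row_count_and_diagonal_status(self, screen_setup):
        _, _, panel, _, result = screen_setup
        k = len(panel)
        assert result.n_enumerated == k * k
        assert len(result.runs) == k * k
        diag = result.runs[result.runs.mediator_id == result.runs.target_id]
        assert len(diag) == k
        assert (diag["status"] == "degenerate").all()

    def test_planted_chain_is_significant(self, screen_setup):
        _, _, _, _, result = screen_setup
        row = result.runs[
            (result.runs.mediator_id == "TNF") & (result.runs.target_id == "CD3D")
        ].iloc[0]
        assert row["significant"]
        assert row["acme"] > 0

    def test_rows_match_standalone_mediation(self, screen_setup):
        expr, pos, _, config, result = screen_setup
        for _, row in result.runs[result.runs.status == "ok"].head(5).iterrows():
            res = mediate_continuous(
                pos,
                expr.loc[row["mediator_id"]].to_numpy(),
                expr.loc[row["target_id"]].to_numpy(),
                sims=config.sims,
                ci_level=config.ci_level,
                seed=int(row["seed"]),
            )
            assert row["acme"] == pytest.approx(res.acme, rel=1e-9)
            assert row["p_acme"] == pytest.approx(res.p_acme, abs=1e-12)

    def test_order_independence_via_shuffled_panel(self, screen_setup):
        expr, pos, panel, config, result = screen_setup
        shuffled = CandidatePanel(gene_ids=list(reversed(panel.gene_ids)))
        result2 = run_screen(expr, None, pos, shuffled, config)
        merged = result.runs.merge(
            result2.runs, on=["mediator_id", "target_id"], suffixes=("_a", "_b")
        )
        ok = merged[merged.status_a == "ok"]
        np.testing.assert_allclose(ok["acme_a"], ok["acme_b"], rtol=1e-9)
        np.testing.assert_allclose(ok["p_acme_a"], ok["p_acme_b"], atol=1e-12)

    def test_frequency_tables_recomputable_from_runs(self, screen_setup):
        _, _, _, _, result = screen_setup
        sig = result.runs[result.runs["significant"]]
        recount = sig.groupby("mediator_id").size()
        table = result.mediator_freq.set_index("mediator_id")["count"]
        for mid, cnt in recount.items():
            assert table[mid] == cnt
        assert table.sum() == len(sig)
        assert (result.mediator_freq["count"] <= len(sig)).all()

    def test_unresolvable_identifier_fails_before_running(self, screen_setup):
        expr, pos, _, config, _ = screen_setup
        with pytest.raises(ConfigError, match="NOT_THERE"):
            run_screen(expr, None, pos, CandidatePanel(gene_ids=["NOT_THERE"]), config)

    def test_pathway_ids_resolved_against_scores(self, screen_setup):
        expr, pos, _, config, _ = screen_setup
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            rng.normal(size=(2, expr.shape[1])),
            index=["PWA", "PWB"],
            columns=expr.columns,
        )
        panel = CandidatePanel(gene_ids=["TNF"], pathway_ids=["PWA", "PWB"])
        res = run_screen(expr, scores, pos, panel, config)
        assert res.n_enumerated == 9

    def test_null_screen_specificity(self):
        spec = CohortSpec(n_samples=300, n_decoy_genes=20, seed=11)
        expr, annot, _ = generate_cohort(spec)
        rng = np.random.default_rng(5)
        permuted = rng.permutation((annot["iso2"] > 0).to_numpy().astype(float))
        panel = CandidatePanel(gene_ids=[f"DECOY_{i:03d}" for i in range(20)])
        res = run_screen(expr, None, permuted, panel, RunConfig(sims=200, seed=3))
        ok = res.runs[res.runs.status == "ok"]
        frac = (ok["p_acme"] < 0.05).mean()
        margin = 2.58 * np.sqrt(0.05 * 0.95 / len(ok))
        assert frac <= 0.05 + margin


class TestSurvivalMediation:
    def test_planted_pathway_mediates_prognosis(self):
        hits = 0
        for s in range(10):
            scores, iso1, time, event = generate_survival_mediation_cohort(seed=s)
            table = survival_mediation(
                iso1, scores, SurvivalData(time, event), RunConfig(sims=200, seed=s)
            )
            row = table.loc["PW_PLANTED"]
            hits += row["status"] == "ok" and row["p_acme"] < 0.05 and row["p_ade"] >= 0.05
        assert hits >= 8

    def test_constant_exposure_rejected(self, rng):
        scores = pd.DataFrame(rng.normal(size=(1, 30)), index=["P"])
        data = SurvivalData(rng.exponential(1.0, 30) + 0.01, np.ones(30))
        with pytest.raises(AnalysisError):
            survival_mediation(np.ones(30), scores, data, RunConfig(seed=0))


class TestConditionalAssociationReversal:
    def test_constructed_sign_flip_flagged(self, rng):
        n = 100
        iso1 = rng.normal(size=n)
        strata = np.arange(n) < 50
        y = np.where(strata, iso1, -iso1) + rng.normal(0, 0.1, n)
        expr = pd.DataFrame({"flip": y, "noise": rng.normal(size=n)}).T
        table = conditional_association_reversal(expr, None, iso1, strata, alpha=0.05)
        assert bool(table.loc["flip", "reversed"])
        assert not bool(table.loc["noise", "reversed"])

    def test_identical_association_not_flagged(self, rng):
        n = 100
        iso1 = rng.normal(size=n)
        strata = np.arange(n) < 50
        y = iso1 + rng.normal(0, 0.2, n)
        expr = pd.DataFrame({"same": y}).T
        table = conditional_association_reversal(expr, None, iso1, strata, alpha=0.05)
        assert not bool(table.loc["same", "reversed"])

    def test_pure_noise_rate_matches_alpha_squared_over_two(self):
        alpha, n_feat, n_seeds, n = 0.1, 200, 50, 120
        total = 0
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            expr = pd.DataFrame(
                rng.normal(size=(n_feat, n)), index=[f"g{i}" for i in range(n_feat)]
            )
            iso1 = rng.normal(size=n)
            strata = np.arange(n) < n // 2
            table = conditional_association_reversal(expr, None, iso1, strata, alpha)
            total += int(table["reversed"].sum())
        lam = n_feat * n_seeds * alpha**2 / 2.0
        from scipy.stats import poisson

        lo, hi = poisson.ppf([0.005, 0.995], lam)
        assert lo <= total <= hi

    def test_small_stratum_rejected_by_name(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 10)))
        strata = np.arange(10) < 2
        with pytest.raises(AnalysisError, match="positive"):
            conditional_association_reversal(expr, None, rng.normal(size=10), strata)

    def test_intersection_preserves_candidate_order(self, rng):
        n = 80
        iso1 = rng.normal(size=n)
        strata = np.arange(n) < 40
        flip = np.where(strata, iso1, -iso1)
        expr = pd.DataFrame({"a": flip, "b": rng.normal(size=n), "c": flip}).T
        table = conditional_association_reversal(expr, None, iso1, strata, 0.05)
        assert intersect_reversed(table, ["c", "b", "a"]) == ["c", "a"]
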