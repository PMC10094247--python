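"""Generate the synthetic cohort every downstream script analyzes.

Writes expression, annotation, gene sets and the planted ground truth under
results/cohort/.  Re-running with the same seed reproduces the files bit
for bit.
"""

from pathlib import Path

from isomed.io import write_expression, write_gmt
from isomed.synthetic import CohortSpec, generate_cohort, generate_gene_sets

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(n_samples=500, n_decoy_genes=50, seed=SEED)
    expr, annot, truth = generate_cohort(spec)
    sets = generate_gene_sets(
        truth, list(expr.index), n_sets=10, set_size=5, seed=SEED
    )

    write_expression(expr, OUT / "expression.tsv")
    annot.to_csv(OUT / "annotation.tsv", sep="\t")
    write_gmt(sets, OUT / "gene_sets.gmt")
    truth.to_json(OUT / "ground_truth.json")

    pos = (annot["iso2"] > 0).sum()
    print(f"cohort: {expr.shape[0]} features x {expr.shape[1]} samples")
    print(f"Iso2-positive samples: {pos} / {len(annot)}")
    print(f"planted ACME = {truth.true_acme:.3f}, planted ADE = {truth.true_ade:.3f}")
    print(f"event rate: {annot['event'].mean():.3f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
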