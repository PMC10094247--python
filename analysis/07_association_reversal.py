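"""Screen for features whose association with Iso1 reverses sign between
Iso2-positive and Iso2-negative samples, over both genes and pathway
scores."""

from pathlib import Path

from isomed.grouping import call_positivity
from isomed.io import read_annotation, read_expression
from isomed.screen import conditional_association_reversal, intersect_reversed

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "reversal"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = read_expression(BASE / "cohort" / "expression.tsv")
    annot = read_annotation(BASE / "cohort" / "annotation.tsv").loc[expr.columns]
    scores = read_expression(BASE / "pathway_scores.tsv")

    iso1 = annot["iso1"].to_numpy()
    strata = call_positivity(annot["iso2"].to_numpy())
    table = conditional_association_reversal(
        expr.drop(index=["iso1", "iso2"]), scores, iso1, strata, alpha=0.05
    )
    table.to_csv(OUT / "reversal.tsv", sep="\t")

    reversed_ids = list(table.index[table["reversed"]])
    print(f"tested {len(table)} features across "
          f"{int(strata.sum())} positive / {int((~strata).sum())} negative samples")
    print(f"reversed associations: {len(reversed_ids)}")
    if reversed_ids:
        cols = ["r_pos", "p_pos", "r_neg", "p_neg"]
        print(table.loc[reversed_ids, cols].round(4).to_string())
    panel = ["TNF", "CD3D", "CD8A", "PLANTED_TARGET_MODULE"]
    print(f"reversed within the planted panel: {intersect_reversed(table, panel)}")


if __name__ == "__main__":
    main()
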