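"""Summarize each gene set into one activity score per sample (integrated
running-sum scoring, z-normalized per set) for use as mediation-screen
candidates and reversal features."""

from pathlib import Path

from isomed.io import read_expression, read_gmt, write_expression
from isomed.pathways import score_matrix

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    expr = read_expression(BASE / "cohort" / "expression.tsv")
    sets = read_gmt(BASE / "cohort" / "gene_sets.gmt")
    scores = score_matrix(expr, sets)
    write_expression(scores, BASE / "pathway_scores.tsv")
    print(f"scored {scores.shape[0]} sets across {scores.shape[1]} samples")
    print("per-set score summary (z-normalized):")
    print(scores.T.describe().T[["mean", "std", "min", "max"]].round(3).to_string())


if __name__ == "__main__":
    main()
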