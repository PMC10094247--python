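"""Quantify how much of Iso1's prognostic effect flows through each
pathway score, on the expected-survival-time scale, in a cohort with a
planted fully-mediating pathway."""

from pathlib import Path

from isomed.io import RunConfig
from isomed.screen import survival_mediation
from isomed.survival import SurvivalData
from isomed.synthetic import generate_survival_mediation_cohort

SEED = 1
BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "survival_mediation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scores, iso1, time, event = generate_survival_mediation_cohort(seed=SEED)
    table = survival_mediation(
        iso1, scores, SurvivalData(time, event), RunConfig(sims=1000, seed=SEED)
    )
    table.to_csv(OUT / "survival_mediation.tsv", sep="\t")

    print(f"cohort: {len(iso1)} samples, {int(event.sum())} events")
    cols = ["acme", "p_acme", "ade", "p_ade", "total", "prop_mediated", "status"]
    print(table[cols].round(4).to_string())
    row = table.loc["PW_PLANTED"]
    print(f"\nplanted pathway: ACME {row['acme']:.3f} (p = {row['p_acme']:.3g}), "
          f"ADE {row['ade']:.3f} (p = {row['p_ade']:.3g}) -- "
          f"{'full mediation pattern' if row['p_acme'] < 0.05 <= row['p_ade'] else 'see table'}")


if __name__ == "__main__":
    main()
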