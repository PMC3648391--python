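"""Group statistics over the cohort outcomes: mean +/- SEM, one-way ANOVA,
Fisher's protected LSD.

Reads the per-animal tables written by 02-04, adds a simulated day-1
neurological score table, and runs the study's statistical layer on each
outcome.  Writes results/group_statistics.csv and prints the report.
"""

from pathlib import Path

import pandas as pd

from strokeflow import anova_from_table, fisher_plsd, generate_score_table, summarize

ROOT = Path(__file__).resolve().parents[1]


def load_outcomes() -> dict[str, pd.DataFrame]:
    res = ROOT / "results"
    outcomes: dict[str, pd.DataFrame] = {}

    rcbf = pd.read_csv(res / "rcbf_ratios.csv")
    day14 = rcbf[rcbf.timepoint == "day14"]
    outcomes["rcbf_day14_ratio"] = day14.rename(columns={"rcbf_ratio": "value"})[
        ["animal_id", "group", "value"]
    ]

    infarct = pd.read_csv(res / "infarct_volume.csv")
    mcao = infarct[infarct.group != "sham"]  # sham has no infarct to compare
    outcomes["infarct_percent"] = mcao.rename(columns={"infarct_percent": "value"})[
        ["animal_id", "group", "value"]
    ]

    vessels = pd.read_csv(res / "vessel_density.csv")
    outcomes["vessel_density_per_mm2"] = vessels.rename(
        columns={"density_per_mm2": "value"}
    )[["animal_id", "group", "value"]]

    scores = generate_score_table(
        {"non_exercise": 4.06, "early_exercise": 4.12}, n_per_group=12, sd=1.0, seed=83
    )
    outcomes["neuro_score_day1"] = scores.rename(columns={"score": "value"})[
        ["animal_id", "group", "value"]
    ]
    return outcomes


def main() -> None:
    rows = []
    for outcome, table in load_outcomes().items():
        summary = summarize(table).table
        print(f"\n=== {outcome} ===")
        print(summary.round(3).to_string(index=False))
        anova = anova_from_table(table)
        print(
            f"ANOVA: F({anova.df_between},{anova.df_within}) = {anova.f:.3f}, "
            f"p = {anova.p:.4f}"
        )
        labels = anova.group_labels
        groups = [table.loc[table.group == g, "value"].to_numpy(float) for g in labels]
        plsd = fisher_plsd(groups, labels=labels, anova=anova, alpha=0.05)
        for _, pair in plsd.pairs.iterrows():
            flag = "*" if pair.significant else " "
            print(
                f"  PLSD {pair.group1} vs {pair.group2}: diff = {pair.mean_diff:+.3f}, "
                f"p = {pair.p:.4f} {flag}"
            )
            rows.append(
                {
                    "outcome": outcome,
                    "group1": pair.group1,
                    "group2": pair.group2,
                    "mean_diff": pair.mean_diff,
                    "t": pair.t,
                    "p_pairwise": pair.p,
                    "significant": pair.significant,
                    "anova_F": anova.f,
                    "anova_p": anova.p,
                }
            )
    out = ROOT / "results" / "group_statistics.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\n-> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
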