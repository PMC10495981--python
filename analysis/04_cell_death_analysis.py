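"""Cytotoxicity: baseline-corrected PI/Hoechst death scores per condition.

Scores the simulated plate from step 01 (dead fractions: organoid-only
0.05, syngeneic 0.10, allogeneic 0.25; n = 6 wells each), subtracting the
genotype-matched organoid-only baseline, and compares conditions by
one-way ANOVA with Sidak-adjusted pairwise tests.
"""

import argparse
from pathlib import Path

import pandas as pd

from ielquant.cytotox import condition_summary, plate_scores
from ielquant.stats import anova_sidak


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    plate = pd.read_csv(args.data / "plate.csv")
    scores = plate_scores(plate)
    scores.to_csv(args.out / "death_scores.csv", index=False)
    summary = condition_summary(scores)
    summary.to_csv(args.out / "death_summary.csv", index=False)
    print(summary.to_string(index=False))

    labels = ["organoid_only", "syngeneic", "allogeneic"]
    groups = [scores.loc[scores.condition == c, "corrected"].to_numpy() for c in labels]
    results = anova_sidak(groups, labels=labels)
    table = pd.DataFrame([r.__dict__ for r in results])
    table.to_csv(args.out / "death_comparisons.csv", index=False)
    print("\nANOVA F = {:.2f}, p = {:.2e}".format(results[0].statistic, results[0].p_value))
    for r in results[1:]:
        print(f"  {r.group_a} vs {r.group_b}: t = {r.statistic:.2f}, "
              f"Sidak-adjusted p = {r.adjusted_p:.2e}")


if __name__ == "__main__":
    main()
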