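"""Relative expression: 2^-ddCt fold changes under both conventions.

T-cell effector genes (Ifng, Gzmb, Tnf) are normalized to the syngeneic
co-culture; the stem-cell marker Lgr5 to the genotype-matched organoid-only
control.  Recovered condition-level folds are compared with the known
simulated folds (8 / 4 / 2 and 0.4).
"""

import argparse
from pathlib import Path

import pandas as pd

from ielquant.expression import condition_folds, normalize_scheme
from ielquant.workflows import EPITHELIAL_FOLDS, TCELL_FOLDS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    tc = pd.read_csv(args.data / "ct_tcell_genes.csv")
    ep = pd.read_csv(args.data / "ct_epithelial_genes.csv")

    frames, rows = [], []
    for gene, true_fold in TCELL_FOLDS.items():
        folds = normalize_scheme(tc, gene, "vs_syngeneic")
        frames.append(folds)
        got = condition_folds(folds)["allogeneic"]
        rows.append(dict(gene=gene, scheme="vs_syngeneic", true_fold=true_fold,
                         recovered_fold=got))
    for gene, true_fold in EPITHELIAL_FOLDS.items():
        folds = normalize_scheme(ep, gene, "vs_organoid_only")
        frames.append(folds)
        got = condition_folds(folds)["allogeneic"]
        rows.append(dict(gene=gene, scheme="vs_organoid_only", true_fold=true_fold,
                         recovered_fold=got))

    pd.concat(frames, ignore_index=True).to_csv(args.out / "fold_changes.csv", index=False)
    table = pd.DataFrame(rows)
    table["rel_error_pct"] = 100 * (table.recovered_fold - table.true_fold).abs() / table.true_fold
    table.to_csv(args.out / "fold_recovery.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
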