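"""Relative gene expression by the delta-delta-Ct (ddCt) method.

Expression of a target gene is first normalized to a housekeeping gene
within each sample (``dCt = mean Ct_target - mean Ct_housekeeping`` over
technical replicates), then to a reference group
(``fold = 2^-(dCt_sample - dCt_reference)``), assuming doubling per cycle.

Two reference conventions are supported, matching how epithelial and
T-cell genes are reported in allogeneic co-culture experiments:

* ``vs_organoid_only`` — epithelial genes (e.g. Lgr5, Olfm4): each sample
  is normalized to the organoid-only control wells of the *same organoid
  genotype* (the allogeneic co-culture to the BALB/c organoid control, the
  syngeneic one to the B6 control).
* ``vs_syngeneic`` — T-cell genes (e.g. Ifng, Tnf, Gzmb, Prf1, Fasl):
  every sample is normalized to the syngeneic co-culture condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCHEMES = ("vs_organoid_only", "vs_syngeneic")
_REFERENCE_CONDITION = {"vs_organoid_only": "organoid_only", "vs_syngeneic": "syngeneic"}


@dataclass(frozen=True)
class FoldChange:
    gene: str
    sample_id: str
    condition: str
    fold: float
    scheme: str


def delta_ct(sample_records: pd.DataFrame, target_gene: str, housekeeping_gene: str) -> float:
    """dCt of one sample: mean Ct of the target minus mean Ct of the
    housekeeping gene across technical replicates."""
    by_gene = sample_records.groupby("gene")["ct"].mean()
    for gene in (target_gene, housekeeping_gene):
        if gene not in by_gene.index:
            sample = sample_records["sample_id"].iloc[0] if len(sample_records) else "<empty>"
            raise ValueError(f"sample {sample!r} has no Ct values for gene {gene!r}")
    return float(by_gene[target_gene] - by_gene[housekeeping_gene])


def fold_change(sample_dct: float, reference_dct: float) -> float:
    """2^-(ddCt) with ddCt = dCt_sample - dCt_reference."""
    if not (np.isfinite(sample_dct) and np.isfinite(reference_dct)):
        raise ValueError("delta-Ct values must be finite")
    return float(2.0 ** -(sample_dct - reference_dct))


def normalize_scheme(
    records: pd.DataFrame,
    gene: str,
    scheme: str,
    housekeeping: str = "Hprt",
    per_sample: bool = True,
) -> pd.DataFrame:
    """Fold changes for every sample under one normalization convention.

    With ``per_sample=True`` (default) the ddCt is computed per biological
    sample against the mean dCt of its reference group; with ``False`` the
    computation runs on condition-level mean Ct values (one fold per
    condition).  A single reference sample reports fold 1 exactly; a
    reference group reports folds with geometric mean 1.

    Returns a DataFrame with columns (gene, sample_id, condition, fold,
    scheme).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    ref_condition = _REFERENCE_CONDITION[scheme]
    needed = {"sample_id", "condition", "organoid_genotype", "gene", "replicate", "ct"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")

    sub = records[records["gene"].isin([gene, housekeeping])]
    samples = (
        sub[["sample_id", "condition", "organoid_genotype"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    if not per_sample:
        # pool replicates and samples: one pseudo-sample per condition
        pooled = sub.copy()
        pooled["sample_id"] = pooled["condition"]
        samples = (
            pooled[["sample_id", "condition", "organoid_genotype"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
        )
        sub = pooled

    dcts = {
        sid: delta_ct(sub[sub["sample_id"] == sid], gene, housekeeping)
        for sid in samples.index
    }

    def reference_dct(genotype: str) -> float:
        if scheme == "vs_organoid_only":
            ref_ids = [
                sid for sid, row in samples.iterrows()
                if row["condition"] == ref_condition and row["organoid_genotype"] == genotype
            ]
            if not ref_ids:
                raise ValueError(
                    f"no organoid-only reference samples with genotype {genotype!r} for gene {gene!r}"
                )
        else:
            ref_ids = [sid for sid, row in samples.iterrows() if row["condition"] == ref_condition]
            if not ref_ids:
                raise ValueError(f"no {ref_condition!r} reference samples for gene {gene!r}")
        return float(np.mean([dcts[sid] for sid in ref_ids]))

    rows = []
    for sid, row in samples.iterrows():
        ref = reference_dct(row["organoid_genotype"])
        rows.append(
            FoldChange(
                gene=gene,
                sample_id=sid,
                condition=row["condition"],
                fold=fold_change(dcts[sid], ref),
                scheme=scheme,
            )
        )
    return pd.DataFrame([f.__dict__ for f in rows])


def condition_folds(folds: pd.DataFrame) -> pd.Series:
    """Geometric-mean fold per condition (folds are ratios, so the
    geometric mean is the natural group summary)."""
    return folds.groupby("condition")["fold"].apply(
        lambda f: float(np.exp(np.mean(np.log(f))))
    )
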