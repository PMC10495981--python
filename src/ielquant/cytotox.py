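"""Seeding-density-independent PI/Hoechst cell-death quantification.

The cell-impermeant dye propidium iodide (PI) marks dead cells while the
cell-permeant dye Hoechst 33342 marks all nuclei; the PI/Hoechst intensity
ratio therefore reports relative cell death independently of how many
organoid cells were seeded in the well.  Spontaneous baseline death is
removed by subtracting the mean ratio of genotype-matched organoid-only
control wells (B6 controls for syngeneic co-cultures, BALB/c controls for
allogeneic ones) — the matching is enforced explicitly, never inferred.

Two acquisition routes feed the same score: plate-reader wells (one PI and
one Hoechst scalar per well) and replicate microscope images (mean pixel
intensities per channel, ratios averaged across replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WellReading:
    well_id: str
    condition: str
    organoid_genotype: str
    pi_intensity: float
    hoechst_intensity: float

    def __post_init__(self) -> None:
        if self.pi_intensity < 0:
            raise ValueError("pi_intensity must be >= 0")
        if self.hoechst_intensity <= 0:
            raise ValueError("hoechst_intensity (the normalizer) must be > 0")


@dataclass(frozen=True)
class DeathScore:
    well_id: str
    condition: str
    organoid_genotype: str
    raw_ratio: float
    corrected: float


def well_death_ratio(reading: WellReading) -> float:
    """PI / Hoechst intensity ratio of one well (dimensionless)."""
    if reading.hoechst_intensity <= 0:
        raise ValueError("hoechst_intensity must be > 0 to normalize")
    return reading.pi_intensity / reading.hoechst_intensity


def baseline_corrected_scores(
    test_wells: list[WellReading],
    control_wells: list[WellReading],
    aggregate=np.mean,
) -> list[DeathScore]:
    """Subtract the genotype-matched organoid-only baseline from each well.

    ``aggregate`` (default mean) reduces the control ratios of each
    genotype to a single baseline.  A test well whose genotype has no
    control group raises a ValueError naming the genotype.
    """
    if not control_wells:
        raise ValueError("control_wells must be nonempty")
    baselines: dict[str, float] = {}
    by_geno: dict[str, list[float]] = {}
    for w in control_wells:
        by_geno.setdefault(w.organoid_genotype, []).append(well_death_ratio(w))
    for geno, ratios in by_geno.items():
        baselines[geno] = float(aggregate(ratios))
    scores = []
    for w in test_wells:
        if w.organoid_genotype not in baselines:
            raise ValueError(
                f"no organoid-only control wells for genotype {w.organoid_genotype!r}"
            )
        raw = well_death_ratio(w)
        scores.append(
            DeathScore(
                well_id=w.well_id,
                condition=w.condition,
                organoid_genotype=w.organoid_genotype,
                raw_ratio=raw,
                corrected=raw - baselines[w.organoid_genotype],
            )
        )
    return scores


def image_death_ratio(pi_images, hoechst_images) -> float:
    """Mean-intensity PI/Hoechst ratio from replicate image pairs.

    Accepts single 2D arrays or sequences of replicate pairs; each
    replicate contributes mean(PI) / mean(Hoechst) and the replicate
    ratios are averaged (not pooled at pixel level).
    """
    pi_list = [np.asarray(pi_images)] if np.ndim(pi_images) == 2 else [np.asarray(a) for a in pi_images]
    ho_list = [np.asarray(hoechst_images)] if np.ndim(hoechst_images) == 2 else [np.asarray(a) for a in hoechst_images]
    if len(pi_list) != len(ho_list) or not pi_list:
        raise ValueError("need >= 1 matched PI/Hoechst replicate image pairs")
    ratios = []
    for pi, ho in zip(pi_list, ho_list):
        if pi.shape != ho.shape:
            raise ValueError(f"image shape mismatch: {pi.shape} vs {ho.shape}")
        denom = float(ho.mean())
        if denom <= 0:
            raise ValueError("mean Hoechst intensity must be > 0")
        ratios.append(float(pi.mean()) / denom)
    return float(np.mean(ratios))


# -- plate-table helpers ----------------------------------------------------

def wells_from_dataframe(df: pd.DataFrame) -> list[WellReading]:
    cols = {"well_id", "condition", "organoid_genotype", "pi_intensity", "hoechst_intensity"}
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"plate table is missing columns: {sorted(missing)}")
    return [
        WellReading(
            well_id=str(r.well_id),
            condition=str(r.condition),
            organoid_genotype=str(r.organoid_genotype),
            pi_intensity=float(r.pi_intensity),
            hoechst_intensity=float(r.hoechst_intensity),
        )
        for r in df.itertuples(index=False)
    ]


def plate_scores(
    df: pd.DataFrame, control_condition: str = "organoid_only"
) -> pd.DataFrame:
    """Score a whole plate table: baseline-correct every non-control well
    against the genotype-matched control wells; controls are scored against
    their own group (their mean corrected score is 0 by construction)."""
    wells = wells_from_dataframe(df)
    controls = [w for w in wells if w.condition == control_condition]
    scores = baseline_corrected_scores(wells, controls)
    return pd.DataFrame([s.__dict__ for s in scores])


def condition_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-condition n / mean / sd of corrected death scores."""
    return (
        scores.groupby("condition")["corrected"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
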