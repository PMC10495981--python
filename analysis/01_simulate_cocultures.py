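"""Generate the synthetic co-culture data set used by all later analyses.

Writes, under results/data/:
  * two 45-min time-lapse movies (30 s frames) of labeled T cells in an
    organoid cross-section — one with confined walkers (10 um, the
    allogeneic-like restricted-patrolling condition) and one with free
    walkers at equal speed (the syngeneic-like condition) — as TIFF +
    ground-truth track CSV + epithelium ROI GeoJSON;
  * a PI/Hoechst plate table (organoid-only / syngeneic / allogeneic);
  * qPCR Ct tables for T-cell effector genes and the stem-cell marker.
"""

import argparse
import math
from dataclasses import replace
from pathlib import Path

from ielquant import io as qio
from ielquant.synthetic import simulate_ct_table, simulate_plate, simulate_timelapse
from ielquant.synthetic import SimulationConfig
from ielquant.workflows import EPITHELIAL_FOLDS, PLATE_CONDITIONS, TCELL_FOLDS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    base = SimulationConfig(
        outer_radius_um=100.0, lumen_radius_um=35.0, n_tcells=5,
        mean_speed_um_s=0.1, min_tcell_separation_um=30.0, seed=args.seed,
    )
    for name, radius in (("confined", 10.0), ("free", math.inf)):
        cfg = replace(base, confinement_radius_um=radius)
        stack, truth = simulate_timelapse(cfg)
        qio.write_stack(args.out / f"timelapse_{name}.tif", stack,
                        cfg.pixel_size_um, cfg.frame_interval_s)
        qio.write_ground_truth_csv(args.out / f"true_tracks_{name}.csv",
                                   truth.true_positions)
        truth.roi.write(args.out / f"roi_{name}.geojson")
        print(f"{name}: {cfg.n_tcells} cells x {cfg.n_frames} frames, "
              f"ROI area {truth.roi.area_um2:.0f} um^2")

    plate, fracs = simulate_plate(list(PLATE_CONDITIONS), seed=args.seed)
    plate.to_csv(args.out / "plate.csv", index=False)
    print(f"plate: {len(plate)} wells, true dead fractions {fracs}")

    tc = simulate_ct_table(list(TCELL_FOLDS), TCELL_FOLDS, seed=args.seed)
    tc.to_csv(args.out / "ct_tcell_genes.csv", index=False)
    ep = simulate_ct_table(
        list(EPITHELIAL_FOLDS), EPITHELIAL_FOLDS, seed=args.seed + 1,
        reference_condition="organoid_only", test_condition="allogeneic",
        genotype_map={"organoid_only": "BALB/c", "allogeneic": "BALB/c"},
    )
    ep.to_csv(args.out / "ct_epithelial_genes.csv", index=False)
    print(f"Ct tables: {len(tc)} + {len(ep)} records "
          f"(true folds {TCELL_FOLDS} and {EPITHELIAL_FOLDS})")


if __name__ == "__main__":
    main()
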