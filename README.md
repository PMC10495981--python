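# ielquant

Quantitative analysis of ex vivo T-cell/organoid co-cultures, the assay
used to study graft-versus-host-like attack of the intestinal epithelium:
donor T cells (intraepithelial lymphocytes, IELs) are co-cultured with
syngeneic or allogeneic small-intestinal organoids, imaged live, and read
out for motility, epithelial killing, and gene expression. `ielquant`
implements the full downstream analysis as a tested Python pipeline and
ships a synthetic-data generator with known ground truth so every stage
can be validated without any external data.

The pipeline stages, and the quantities they produce:

* **Spot detection** — scale-normalized Laplacian-of-Gaussian blob
  detection of fluorescently labeled T cells (expected diameter
  d = 7 μm, σ = (d/2)/√2), per frame, with sub-pixel refinement.
* **Particle tracking** — Simple LAP (linear assignment problem) linking:
  per-frame-pair assignments with max link distance 15 μm, then one global
  gap-closing assignment (max distance 15 μm, max frame gap 2), cost =
  squared displacement. No splitting or merging.
* **Motility** — per-track mean speed v̄ (μm/s); tracks with
  v̄ < 0.05 μm/s excluded; *patrolled area* = area(⋃ 7 μm buffers around
  retained tracks ∩ epithelial ROI) / area(ROI), with the organoid lumen
  excluded from the ROI.
* **Cytotoxicity** — seeding-density-independent relative cell death
  PI/Hoechst per well, baseline-corrected by subtracting the mean ratio of
  genotype-matched organoid-only controls; plate-reader and
  microscope-image variants.
* **Relative expression** — ddCt fold changes 2^(−ΔΔCt) versus the *Hprt*
  housekeeping gene, under two conventions: epithelial genes vs the
  genotype-matched organoid-only control, T-cell effector genes vs the
  syngeneic co-culture.
* **Statistics** — two-tailed Welch t tests and one-way ANOVA with
  Šídák-adjusted post-hoc comparisons (p_adj = 1 − (1 − p)^m), α = 0.05.

See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

The `analysis/` scripts run the whole study on synthetic data; each writes
its tables under `results/`:

```bash
python analysis/01_simulate_cocultures.py --seed 0
python analysis/02_detect_and_track.py
python analysis/03_motility_analysis.py --seed 0
python analysis/04_cell_death_analysis.py
python analysis/05_expression_analysis.py
```

Step 03 prints, for one confined-walker (restricted patrolling) and one
free-walker movie and then for 20 seed-matched pairs:

```
confined: 5/5 tracks retained, median speed 0.100 um/s, patrolled fraction 0.159
free: 5/5 tracks retained, median speed 0.101 um/s, patrolled fraction 0.193

20-pair contrast: confined 0.155 vs free 0.195; confined smaller in 100% of
pairs; Welch p = 1.80e-04
```

i.e. detection + tracking recover the simulated 0.1 μm/s walkers, and
cells confined to 10 μm territories patrol a significantly smaller
fraction of the epithelium than free walkers at identical speed — the
restricted-patrolling phenotype, reproduced in kind. Step 04 prints the
cell-death ladder (baseline-corrected scores: allogeneic 0.251 >
syngeneic 0.065 > control 0, ANOVA p = 3.6e-17) and step 05 the fold-change
round trip (true folds 8/4/2/0.4 recovered within ~3%).

Equivalent one-off commands are available on the `ielquant` CLI
(`simulate`, `detect`, `track`, `motility`, `death`, `ddct`, `report`);
run `ielquant --help`.

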