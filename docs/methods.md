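# Methods

`ielquant` quantifies intraepithelial T-cell behavior and epithelial damage
in ex vivo T-cell/organoid co-cultures from three kinds of raw data:
time-lapse fluorescence movies, plate-reader fluorometry, and qPCR Ct
tables. Because no public data set accompanies this kind of assay, every
stage is exercised on a synthetic-data generator with known ground truth;
this note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Synthetic co-culture movies

A movie is a three-channel stack (Hoechst = all nuclei, propidium iodide =
dead nuclei, plus a T-cell label channel), sampled every 30 s for 45 min
(91 frames including t = 0). The epithelium is an annulus (outer boundary
minus lumen); nuclei are placed uniformly by area inside it and a fixed
`round(dead_fraction * n_nuclei)` subset, drawn without replacement, is
marked dead so the ground-truth count is exact.

**T-cell motion.** Each cell follows a discrete mean-reverting walk around
an anchor point:

    x_{t+1} = anchor + a * (x_t − anchor) + η,   η ~ N(0, s² I)

with the per-axis noise scale `s = v·Δt / sqrt(π/2)` calibrated so the
mean step length of the noise term equals `v·Δt` (the mean of a 2D
Rayleigh), and the reversion factor `a` chosen so the stationary per-axis
s.d. is `R/√2`, i.e. the r.m.s. distance from the anchor approximates the
confinement radius `R`. `R = ∞` gives `a = 1`, a free random walk; this
single knob produces the restricted-vs-free patrolling contrast the
pipeline must resolve. Confined trajectories are additionally clamped
radially into the epithelial annulus (a confined intraepithelial cell does
not enter the lumen); free walkers are left unclamped and may exit the
epithelium. Anchors are drawn with a minimum mutual separation
(dart-throwing with a best-candidate fallback), reflecting cells patrolling
distinct territories and making ground-truth identities well defined.

**Rendering.** All objects are isotropic Gaussian blobs (default
σ = 2.5 μm, i.e. ≈7 μm-wide lymphocyte-sized spots) on a constant
background with additive Gaussian read noise; defaults give peak SNR 10.
Photobleaching, optics, organoid growth/deformation and axial drift are
deliberately not modeled — passing tests therefore validate the analysis
chain, not robustness to those real-data effects.

**Plate and Ct generators.** Well fluorometry: Hoechst ∝ seeded cells,
PI ∝ dead cells, independent multiplicative well noise (CV ≈ 8%) and a
±30% seeding-density spread to exercise density invariance; small additive
channel backgrounds. Ct tables follow
`Ct = base − log2(relative expression) + loading + noise` with a per-sample
loading shift (cancelled by the housekeeping normalization) and independent
technical-replicate noise; the housekeeping gene is flat by construction.

## Detection

A scale-normalized Laplacian-of-Gaussian detector at σ = (d/2)/√2 for
blob diameter d (default 7 μm): the response is `−σ²·LoG`, so matched
bright blobs give positive maxima and the response is linear in intensity.
The sampled LoG kernel's small nonzero sum is removed explicitly (DC
correction against a matched Gaussian smoothing) so constant images map to
a null response. Spots are strict local maxima within a one-radius window,
above a quality threshold, at least one radius from the border (reflect
padding makes closer maxima unreliable); plateau ties keep the
lexicographically smallest pixel; optional sub-pixel refinement fits a 1D
quadratic per axis. Thresholds are instrument-relative: quality bands
quoted for other software (e.g. 40–120) do not transfer, so workflows set
the threshold at 8 robust (MAD-based) sigmas of the response noise floor —
comfortably above noise maxima yet far below the matched-blob response
(≈ amplitude/2).

## Tracking

A two-pass "simple" linear-assignment tracker (no splits/merges).
Frame-to-frame linking solves, per consecutive frame pair, the assignment
minimizing `Σ d² + b·(#unmatched)` with links beyond 15 μm forbidden and
the opt-out cost `b = 1.05 · (15 μm)²`; gap closing is one global
assignment between segment ends and later starts spanning 2…`max_frame_gap`
frames (difference 1 is adjacent frames, already the linker's job; the
default gap 2 therefore allows exactly one missed frame) and ≤ 15 μm.
Both stages are realized exactly by an augmented square cost matrix whose
lower-right block mirrors feasibility at zero cost, solved with
`scipy.optimize.linear_sum_assignment`; an exhaustive-enumeration reference
(`ielquant.evaluation`) confirms stage-wise optimality on random small
instances. Track ids are renumbered by (first frame, x, y of the first
spot), which makes output independent of spot input order.

## Motility read-outs

Mean track speed is the mean over consecutive-spot links of
displacement/elapsed time, with gap-spanning links divided by their true
frame difference; tracks strictly below 0.05 μm/s are excluded (equality
retained — the exclusion rule is read literally), and single-spot tracks
score 0 with a warning. The patrolled area is the union of 7 μm buffers
swept along all retained tracks — interpreted as a buffer *radius* of 7 μm
around the track polyline — computed by exact polygon geometry (shapely
buffers at 64 segments/quadrant, ≈1e-4 relative disk-area error, plus
boolean union), **clipped to the epithelial ROI** before dividing by the
ROI area so the fraction is bounded by 1 even when tracks leave the
epithelium. The ROI is a polygon with lumen holes, exchanged as GeoJSON in
μm. A 0.1 μm rasterization oracle validates the geometry but is never the
product path.

## Cytotoxicity score

`raw = PI/Hoechst` per well is seeding-density independent (both channels
scale with cell number); `corrected = raw − mean(raw of genotype-matched
organoid-only controls)`. The baseline aggregate is the arithmetic mean
(configurable); genotype matching is an explicit data-model requirement —
a missing control group is an error naming the genotype, never silently
inferred. No background subtraction is applied before the ratio (an
optional per-plate blank exists but is off by default). The image variant
averages replicate mean-intensity ratios rather than pooling pixels.

## Relative expression

Pure ddCt with amplification efficiency fixed at 2: technical replicates
are averaged to a per-sample ΔCt, folds are `2^(−ΔΔCt)`. Two reference
conventions: epithelial genes against genotype-matched organoid-only
controls, T-cell genes against the syngeneic condition. ΔΔCt is computed
per biological sample against the mean ΔCt of the reference group (a
condition-level path is also exposed); with a single reference sample the
reference fold is exactly 1, with a reference group the folds have
geometric mean 1. Condition-level summaries use the geometric mean, the
natural average for ratios.

## Statistics

Two groups: two-tailed unpaired t test, Welch variant (unequal variances,
Welch–Satterthwaite df) by default. Three or more: one-way ANOVA, then
Šídák-adjusted pairwise comparisons `p_adj = 1 − (1 − p)^m` over the
user-selected family (default: all pairs), with pairwise t statistics on
the pooled ANOVA error variance (df = N − k), matching common interactive
packages; a Welch-pairwise option exists. α = 0.05 throughout. Null
simulations (3 equal-mean normal groups, n = 7, 2000 replicates) confirm
type-I calibration of both tests.

## Experiment sizes and design choices

* **Tracking-oracle check**: 50 random instances, ≤5 spots/frame,
  ≤6 frames — small enough for exact enumeration yet rich in birth/death
  and gap structure.
* **Speed/identity recovery**: 20 confined walkers (R = 10 μm) at
  0.1 μm/s in a 384 μm field (epithelium 60–150 μm radius), anchor
  separation 40 μm. Identity fidelity is only measurable when ground-truth
  identities are unambiguous, so anchors are spaced beyond the 15 μm link
  distance plus typical excursions.
* **Confined-vs-free contrast**: 20 seed-matched movie pairs, 5 cells per
  movie in an epithelium of ≈27,600 μm² (outer 100 μm, lumen 35 μm). The
  scene keeps expected total coverage well below ROI saturation: a
  confined cell's territory is ≈π(R + r_buf)² ≈ 900 μm², and when buffered
  territories overlap heavily or fill the ROI the union compresses exactly
  the difference this read-out measures. Unconfined walkers may drift out
  of the epithelium and are clipped by the ROI, which occasionally narrows
  a single pair's contrast; the distribution-level contrast is robust.
* **Plate**: dead fractions 0.05 (organoid-only, both genotypes) / 0.10
  (syngeneic) / 0.25 (allogeneic), 6 wells each.
* **Ct round trip**: folds 8/4/2 (effector genes, vs syngeneic) and 0.4
  (stem-cell marker, vs organoid-only), 6 biological samples × 3 technical
  replicates, Ct noise σ = 0.1 — a typical qPCR precision at which the
  per-fold standard error is ≈3–5%.

## Degenerate inputs and numerical conventions

Zero-speed walks return the anchor verbatim; empty spot lists track to
empty track lists; a frame with no spots breaks links (bridged, if close
enough, by gap closing); zero tracks give patrolled fraction 0; zero-length
track geometry collapses to a disk buffer. Forbidden assignment entries
use a large finite cost (1e9) rather than infinity so the solver's
feasibility is unconditional. All generators are bit-reproducible under a
fixed seed (NumPy `default_rng`, child streams spawned per cell).

## Known limitations

2D only (no z-stacks, no 3D linking); no track splitting/merging or
motion-model prediction; rendering ignores photon statistics and optics;
fixed cell count per movie (no entry/exit through the imaging field); no
primer-efficiency correction or multi-housekeeping normalization; the
patrolled-area statistic depends on the manually drawn ROI in real data,
whereas the simulator's ROI is exact.
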