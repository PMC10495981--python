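"""Synthetic co-culture data with known ground truth.

Every downstream stage of the pipeline (spot detection, tracking, motility
statistics, cytotoxicity scores, relative expression) is exercised on data
produced here, so each generator returns the ground truth alongside the
measurement it emulates:

* ``simulate_timelapse`` — a three-channel time-lapse of an organoid
  cross-section: Hoechst (all nuclei), propidium iodide (dead nuclei only)
  and a T-cell label channel in which cells perform confined or free random
  walks at a configurable mean speed, sampled every 30 s for 45 min.
* ``simulate_plate`` — well-level PI / Hoechst fluorometry with varying
  seeding density and known per-condition dead fractions.
* ``simulate_ct_table`` — qPCR Ct tables with known fold changes relative
  to a reference condition.

The rendering model is deliberately simple: isotropic Gaussian blobs on a
constant background with additive Gaussian read noise.  Photobleaching,
optics, organoid growth and axial drift are out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import RegionOfInterest, annulus_roi

# E[|eta|] for a 2D isotropic Gaussian with per-axis sd s is s*sqrt(pi/2)
_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and scene parameters for a synthetic time-lapse.

    Defaults emulate a spinning-disc acquisition of one organoid
    cross-section: 30 s frame interval over 45 min (91 frames including
    t=0), ~1 um pixels, a 7 um-wide T-cell blob (psf_sigma ~ 2.5 um) and
    peak signal-to-noise of 10.
    """

    image_width_px: int = 256
    image_height_px: int = 256
    pixel_size_um: float = 1.0
    frame_interval_s: float = 30.0
    n_frames: int = 91
    organoid_center_um: tuple[float, float] = (128.0, 128.0)
    outer_radius_um: float = 80.0
    lumen_radius_um: float = 30.0
    n_nuclei: int = 200
    dead_fraction: float = 0.1
    n_tcells: int = 10
    mean_speed_um_s: float = 0.1
    confinement_radius_um: float = math.inf  # inf -> free (unconfined) walk
    min_tcell_separation_um: float = 20.0
    psf_sigma_um: float = 2.5
    signal_amplitude: float = 100.0
    background_level: float = 20.0
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.outer_radius_um > self.lumen_radius_um >= 0:
            raise ValueError("require outer_radius_um > lumen_radius_um >= 0")
        if self.n_nuclei < 0 or self.n_tcells < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must lie in [0, 1]")
        if self.mean_speed_um_s < 0:
            raise ValueError("mean_speed_um_s must be >= 0")
        if self.confinement_radius_um <= 0:
            raise ValueError("confinement_radius_um must be > 0 (use inf for a free walk)")
        if self.psf_sigma_um <= 0:
            raise ValueError("psf_sigma_um must be > 0")
        if min(self.signal_amplitude, self.background_level, self.noise_sigma) < 0:
            raise ValueError("intensity parameters must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_positions: np.ndarray  # (n_tcells, n_frames, 2) in um
    dead_labels: np.ndarray  # (n_nuclei,) bool
    roi: RegionOfInterest
    true_dead_fraction: float
    true_mean_speed_um_s: float
    true_folds: dict = field(default_factory=dict)
    nuclei_positions_um: np.ndarray | None = None
    tcell_anchors_um: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Random walks
# ---------------------------------------------------------------------------

def simulate_confined_walk(
    n_steps: int,
    dt: float,
    speed: float,
    confinement_radius: float,
    anchor,
    seed,
) -> np.ndarray:
    """Discrete mean-reverting random walk around ``anchor``.

    The update is ``x_{t+1} = anchor + a * (x_t - anchor) + eta`` with
    isotropic Gaussian ``eta`` whose per-axis sd is calibrated so the mean
    step length of the noise term equals ``speed * dt``.  The reversion
    factor ``a`` is chosen so the stationary per-axis sd is
    ``confinement_radius / sqrt(2)`` (i.e. rms distance from the anchor
    ~ confinement_radius); ``confinement_radius = inf`` gives ``a = 1``,
    a free random walk.

    Parameters
    ----------
    n_steps : number of positions returned (the first is the anchor).
    dt : frame interval in seconds, > 0.
    speed : mean step speed in um/s, >= 0.
    confinement_radius : um, > 0, or ``math.inf`` for an unconfined walk.
    anchor : 2-vector, um.
    seed : int seed or a ``numpy.random.Generator``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if speed < 0:
        raise ValueError("speed must be >= 0")
    if confinement_radius <= 0:
        raise ValueError("confinement_radius must be > 0 (inf for free walk)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anchor = np.asarray(anchor, dtype=float)

    step_sd = speed * dt / _RAYLEIGH_MEAN  # per-axis sd of the noise term
    if math.isinf(confinement_radius):
        a = 1.0
    else:
        # stationary per-axis variance: step_sd^2 / (1 - a^2) = R^2 / 2
        ratio = 2.0 * step_sd**2 / confinement_radius**2
        a = math.sqrt(max(0.0, 1.0 - ratio))

    pos = np.empty((n_steps, 2), dtype=float)
    pos[0] = anchor
    if speed == 0.0:
        pos[:] = anchor
        return pos
    eta = rng.normal(0.0, step_sd, size=(n_steps - 1, 2))
    x = anchor.copy()
    for t in range(1, n_steps):
        x = anchor + a * (x - anchor) + eta[t - 1]
        pos[t] = x
    return pos


def _sample_annulus(rng, center, r_inner, r_outer, n):
    """Uniform-by-area points in an annulus."""
    r = np.sqrt(rng.uniform(r_inner**2, r_outer**2, size=n))
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def _sample_separated_anchors(rng, center, r_inner, r_outer, n, min_sep, max_tries=200):
    """Dart-throwing with a best-candidate fallback.

    T cells patrol distinct regions of the epithelium, so anchors are drawn
    with a minimum mutual separation; when a compliant draw cannot be found
    the candidate with the largest minimum distance to the accepted set is
    kept, so the routine always terminates.
    """
    anchors = np.empty((n, 2))
    for i in range(n):
        best, best_d = None, -1.0
        for _ in range(max_tries):
            cand = _sample_annulus(rng, center, r_inner, r_outer, 1)[0]
            d = np.inf if i == 0 else np.min(np.linalg.norm(anchors[:i] - cand, axis=1))
            if d >= min_sep:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        anchors[i] = best
    return anchors


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def _render_blobs(height, width, centers_px, sigma_px, amplitude):
    """Sum of isotropic Gaussian blobs; centers as (row, col) floats."""
    img = np.zeros((height, width), dtype=float)
    half = int(math.ceil(4 * sigma_px))
    for r0, c0 in np.atleast_2d(centers_px):
        r_lo, r_hi = int(math.floor(r0)) - half, int(math.floor(r0)) + half + 1
        c_lo, c_hi = int(math.floor(c0)) - half, int(math.floor(c0)) + half + 1
        r_lo, r_hi = max(r_lo, 0), min(r_hi, height)
        c_lo, c_hi = max(c_lo, 0), min(c_hi, width)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi, dtype=float) - r0
        cc = np.arange(c_lo, c_hi, dtype=float) - c0
        g = np.exp(-(rr[:, None] ** 2 + cc[None, :] ** 2) / (2 * sigma_px**2))
        img[r_lo:r_hi, c_lo:c_hi] += amplitude * g
    return img


def simulate_timelapse(config: SimulationConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render a three-channel time-lapse stack and its ground truth.

    Returns
    -------
    stack : float32 array of shape (3, n_frames, H, W); channel 0 is
        Hoechst (all nuclei, static), channel 1 is PI (dead nuclei only,
        static) and channel 2 is the T-cell label.
    truth : GroundTruth with true trajectories (um), dead labels and the
        annular epithelium ROI.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_height_px, cfg.image_width_px
    px = cfg.pixel_size_um
    center = np.asarray(cfg.organoid_center_um, dtype=float)

    fov_w, fov_h = W * px, H * px
    if (
        center[0] - cfg.outer_radius_um < 0
        or center[1] - cfg.outer_radius_um < 0
        or center[0] + cfg.outer_radius_um > fov_w
        or center[1] + cfg.outer_radius_um > fov_h
    ):
        warnings.warn("organoid extends beyond the field of view; blobs will be clipped")

    # static nuclei
    nuclei = _sample_annulus(rng, center, cfg.lumen_radius_um, cfg.outer_radius_um, cfg.n_nuclei)
    n_dead = int(round(cfg.dead_fraction * cfg.n_nuclei))
    dead_labels = np.zeros(cfg.n_nuclei, dtype=bool)
    if cfg.n_nuclei:
        dead_idx = rng.choice(cfg.n_nuclei, size=n_dead, replace=False)
        dead_labels[dead_idx] = True

    # T-cell trajectories
    anchors = _sample_separated_anchors(
        rng, center, cfg.lumen_radius_um, cfg.outer_radius_um, cfg.n_tcells,
        cfg.min_tcell_separation_um,
    )
    walk_rngs = rng.spawn(cfg.n_tcells) if cfg.n_tcells else []
    positions = np.zeros((cfg.n_tcells, cfg.n_frames, 2), dtype=float)
    confined = math.isfinite(cfg.confinement_radius_um)
    for i in range(cfg.n_tcells):
        traj = simulate_confined_walk(
            cfg.n_frames, cfg.frame_interval_s, cfg.mean_speed_um_s,
            cfg.confinement_radius_um, anchors[i], walk_rngs[i],
        )
        if confined:
            # confined intraepithelial cells stay in the epithelium: clamp
            # the radial coordinate into the annulus
            rel = traj - center
            rad = np.linalg.norm(rel, axis=1)
            clipped = np.clip(rad, cfg.lumen_radius_um, cfg.outer_radius_um)
            nonzero = rad > 0
            traj = center + rel * np.where(nonzero, clipped / np.where(nonzero, rad, 1.0), 0.0)[:, None]
        positions[i] = traj

    sigma_px = cfg.psf_sigma_um / px
    to_px = lambda pts: np.column_stack([pts[:, 1] / px, pts[:, 0] / px])  # (x,y)um -> (row,col)px

    hoechst = _render_blobs(H, W, to_px(nuclei) if cfg.n_nuclei else np.empty((0, 2)),
                            sigma_px, cfg.signal_amplitude)
    pi_img = _render_blobs(H, W, to_px(nuclei[dead_labels]) if n_dead else np.empty((0, 2)),
                           sigma_px, cfg.signal_amplitude)

    stack = np.empty((3, cfg.n_frames, H, W), dtype=np.float32)
    stack[0] = hoechst
    stack[1] = pi_img
    for t in range(cfg.n_frames):
        if cfg.n_tcells:
            stack[2, t] = _render_blobs(H, W, to_px(positions[:, t]), sigma_px,
                                        cfg.signal_amplitude)
        else:
            stack[2, t] = 0.0
    stack += cfg.background_level
    if cfg.noise_sigma > 0:
        stack += rng.normal(0.0, cfg.noise_sigma, size=stack.shape).astype(np.float32)

    roi = annulus_roi(tuple(center), cfg.outer_radius_um, cfg.lumen_radius_um)
    truth = GroundTruth(
        true_positions=positions,
        dead_labels=dead_labels,
        roi=roi,
        true_dead_fraction=(n_dead / cfg.n_nuclei) if cfg.n_nuclei else 0.0,
        true_mean_speed_um_s=cfg.mean_speed_um_s,
        nuclei_positions_um=nuclei,
        tcell_anchors_um=anchors,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Plate-reader wells
# ---------------------------------------------------------------------------

def simulate_plate(
    conditions,
    per_well_cells: int = 5000,
    hoechst_per_cell: float = 1.0,
    pi_per_dead_cell: float = 1.2,
    pi_background: float = 20.0,
    hoechst_background: float = 50.0,
    well_noise_cv: float = 0.08,
    density_variation: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate PI / Hoechst fluorometry of a co-culture plate.

    ``conditions`` is a list of ``(label, organoid_genotype, dead_fraction,
    n_wells)`` tuples.  Hoechst intensity scales with the (randomly varying)
    number of seeded cells, PI intensity with the number of dead cells, and
    both carry independent multiplicative well-to-well noise — so the raw
    PI/Hoechst ratio, not either channel alone, tracks the dead fraction.

    Returns the well table (columns ``well_id, condition,
    organoid_genotype, pi_intensity, hoechst_intensity``) and a map
    ``condition -> true dead fraction``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    true_fracs = {}
    widx = 0
    for label, genotype, dead_fraction, n_wells in conditions:
        if not 0.0 <= dead_fraction <= 1.0:
            raise ValueError(f"dead_fraction for {label!r} must lie in [0, 1]")
        true_fracs[label] = dead_fraction
        for _ in range(n_wells):
            cells = per_well_cells * rng.uniform(1 - density_variation, 1 + density_variation)
            mult = rng.lognormal(mean=0.0, sigma=well_noise_cv, size=2)
            hoechst = hoechst_background + hoechst_per_cell * cells * mult[0]
            pi = pi_background + pi_per_dead_cell * cells * dead_fraction * mult[1]
            rows.append(
                dict(well_id=f"W{widx:03d}", condition=label, organoid_genotype=genotype,
                     pi_intensity=pi, hoechst_intensity=hoechst)
            )
            widx += 1
    return pd.DataFrame(rows), true_fracs


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    genes,
    true_folds: dict,
    housekeeping: str = "Hprt",
    n_replicates: int = 3,
    ct_noise_sigma: float = 0.1,
    seed: int = 0,
    *,
    reference_condition: str = "syngeneic",
    test_condition: str = "allogeneic",
    genotype_map: dict | None = None,
    n_samples: int = 6,
    base_ct: float = 24.0,
    housekeeping_ct: float = 20.0,
    sample_loading_sd: float = 0.3,
) -> pd.DataFrame:
    """Simulate a long-format Ct table with known fold changes.

    For each target gene the test condition expresses ``true_folds[gene]``
    times the reference condition; the housekeeping gene is flat (fold 1)
    by construction.  Each biological sample carries a loading shift that
    moves all its Ct values together (cancelled by the delta-Ct step) and
    each technical replicate has independent Gaussian Ct noise.

    Ct model: ``Ct = base_ct - log2(relative expression) + loading + noise``.
    """
    for g, f in true_folds.items():
        if f <= 0:
            raise ValueError(f"fold for {g!r} must be > 0")
    rng = np.random.default_rng(seed)
    genotype_map = genotype_map or {reference_condition: "B6", test_condition: "BALB/c"}
    rows = []
    for condition in (reference_condition, test_condition):
        genotype = genotype_map.get(condition, "B6")
        for s in range(n_samples):
            sample_id = f"{condition}_{s}"
            loading = rng.normal(0.0, sample_loading_sd)
            for gene in list(genes) + [housekeeping]:
                if gene == housekeeping:
                    expr, base = 1.0, housekeeping_ct
                else:
                    fold = true_folds.get(gene, 1.0)
                    expr = fold if condition == test_condition else 1.0
                    base = base_ct
                for rep in range(n_replicates):
                    noise = rng.normal(0.0, ct_noise_sigma) if ct_noise_sigma > 0 else 0.0
                    rows.append(
                        dict(sample_id=sample_id, condition=condition,
                             organoid_genotype=genotype, gene=gene, replicate=rep,
                             ct=base - math.log2(expr) + loading + noise)
                    )
    return pd.DataFrame(rows)
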