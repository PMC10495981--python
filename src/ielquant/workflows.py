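"""End-to-end experiments composing the pipeline stages.

Each function here runs one self-contained in-silico experiment — the same
experiments driven by the ``analysis/`` scripts and validated by the test
suite — and returns a plain dict of computed quantities.  All randomness
flows from the ``seed`` argument.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .cytotox import condition_summary, plate_scores
from .detection import DetectionConfig, Spot, detect_stack, log_response, suggest_threshold
from .evaluation import (
    exhaustive_gap_cost,
    exhaustive_linking_cost,
    match_tracks_to_truth,
    raster_union_area,
)
from .expression import condition_folds, normalize_scheme
from .motility import (
    MotilityConfig,
    buffer_union_area,
    filter_tracks_by_speed,
    mean_speed,
    patrolled_area,
)
from .stats import anova_sidak, sidak_adjust, welch_t_test
from .synthetic import SimulationConfig, simulate_ct_table, simulate_plate, simulate_timelapse
from .tracking import TrackingConfig, close_gaps, link_frames, track_particles

#: detector threshold, in robust noise-floor sigmas of the LoG response
THRESHOLD_SIGMAS = 8.0


# ---------------------------------------------------------------------------
# Tracking vs exhaustive search
# ---------------------------------------------------------------------------

def tracking_oracle_check(n_instances: int = 50, base_seed: int = 0) -> dict:
    """Compare both LAP stages against exhaustive enumeration on random
    small instances (<= 5 spots/frame, <= 6 frames)."""
    cfg = TrackingConfig()
    agree = 0
    for k in range(n_instances):
        rng = np.random.default_rng(base_seed + k)
        n_frames = int(rng.integers(3, 7))
        spots = []
        for f in range(n_frames):
            for _ in range(int(rng.integers(0, 6))):
                x, y = rng.uniform(0.0, 40.0, size=2)
                spots.append(Spot(frame=f, x_um=float(x), y_um=float(y),
                                  quality=1.0, radius_um=3.5))
        segs, link_cost = link_frames(
            spots, cfg.max_link_distance_um, cfg.alt_cost_factor, return_cost=True
        )
        ref_link = exhaustive_linking_cost(spots, cfg.max_link_distance_um, cfg.alt_cost_factor)
        _, gap_cost = close_gaps(
            segs, cfg.max_gap_distance_um, cfg.max_frame_gap, cfg.alt_cost_factor,
            return_cost=True,
        )
        ref_gap = exhaustive_gap_cost(
            segs, cfg.max_gap_distance_um, cfg.max_frame_gap, cfg.alt_cost_factor
        )
        if math.isclose(link_cost, ref_link, rel_tol=1e-9, abs_tol=1e-9) and math.isclose(
            gap_cost, ref_gap, rel_tol=1e-9, abs_tol=1e-9
        ):
            agree += 1
    return {"agreement_rate": agree / n_instances, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# Detection + tracking on simulated movies
# ---------------------------------------------------------------------------

def analyze_timelapse(
    stack: np.ndarray,
    pixel_size_um: float,
    frame_interval_s: float,
    roi,
    detection: DetectionConfig | None = None,
    tracking: TrackingConfig | None = None,
    motility: MotilityConfig | None = None,
) -> dict:
    """Full pipeline on one movie: detect -> track -> speed filter ->
    patrolled area.  ``stack`` is (C, T, H, W); the T-cell label channel
    (index 2, or the only channel) is analyzed."""
    frames = stack[2] if stack.ndim == 4 and stack.shape[0] >= 3 else np.atleast_3d(stack)
    tracking = tracking or TrackingConfig()
    motility = motility or MotilityConfig(frame_interval_s=frame_interval_s)
    if detection is None:
        thr = suggest_threshold(
            log_response(frames[0], pixel_size_um, 7.0), k=THRESHOLD_SIGMAS
        )
        detection = DetectionConfig(diameter_um=7.0, quality_threshold=thr, subpixel=True)
    spots = detect_stack(frames, pixel_size_um, detection)
    tracks = track_particles(spots, tracking)
    retained = filter_tracks_by_speed(tracks, motility.min_speed_um_s, frame_interval_s)
    speeds = [mean_speed(t, frame_interval_s) for t in retained if len(t.spots) >= 2]
    patrol = patrolled_area(retained, roi, motility)
    return {
        "spots": spots,
        "tracks": tracks,
        "retained_tracks": retained,
        "mean_speeds_um_s": speeds,
        "patrol": patrol,
    }


def speed_recovery_experiment(seed: int = 0) -> dict:
    """Detection + tracking fidelity on 20 confined walkers at 0.1 um/s.

    The scene gives every cell its own patrol territory (anchor separation
    well above the 15 um link distance) so ground-truth identities are
    unambiguous and identity preservation is measurable.
    """
    cfg = SimulationConfig(
        image_width_px=384, image_height_px=384, organoid_center_um=(192.0, 192.0),
        outer_radius_um=150.0, lumen_radius_um=60.0,
        n_nuclei=300, dead_fraction=0.1,
        n_tcells=20, mean_speed_um_s=0.1, confinement_radius_um=10.0,
        min_tcell_separation_um=40.0, seed=seed,
    )
    stack, truth = simulate_timelapse(cfg)
    out = analyze_timelapse(stack, cfg.pixel_size_um, cfg.frame_interval_s, truth.roi)
    speeds = out["mean_speeds_um_s"]
    median_speed = float(np.median(speeds)) if speeds else 0.0
    match = match_tracks_to_truth(out["tracks"], truth.true_positions, match_radius_um=5.0)
    return {
        "median_track_speed_um_s": median_speed,
        "true_speed_um_s": cfg.mean_speed_um_s,
        "speed_relative_error_pct": 100.0 * abs(median_speed - cfg.mean_speed_um_s)
        / cfg.mean_speed_um_s,
        "track_recovery_rate": match["recovery_rate"],
        "n_cells": match["n_cells"],
        "n_tracks": len(out["tracks"]),
    }


def patrol_contrast_experiment(seed: int = 0, n_pairs: int = 20) -> dict:
    """Confined (10 um) vs free walkers at equal speed, full pipeline.

    Runs ``n_pairs`` seed-matched movie pairs and compares the patrolled
    epithelial fraction between conditions (Welch t on the two samples of
    fractions).  Restricted patrolling should cover less epithelium.

    The scene keeps total coverage well below ROI saturation (5 cells whose
    expected individual territories sum to ~<25% of the epithelial area):
    when buffered territories overlap heavily or fill the ROI, the union
    compresses exactly the differences this read-out measures.
    """
    base = SimulationConfig(
        outer_radius_um=100.0, lumen_radius_um=35.0,
        n_tcells=5, mean_speed_um_s=0.1, min_tcell_separation_um=30.0, seed=seed,
    )
    confined_fracs, free_fracs = [], []
    for k in range(n_pairs):
        for conf_radius, sink in ((10.0, confined_fracs), (math.inf, free_fracs)):
            cfg = replace(base, confinement_radius_um=conf_radius,
                          seed=(seed * 1009 + k) % (2**31))
            stack, truth = simulate_timelapse(cfg)
            out = analyze_timelapse(stack, cfg.pixel_size_um, cfg.frame_interval_s, truth.roi)
            sink.append(out["patrol"].patrolled_fraction)
    confined_fracs = np.array(confined_fracs)
    free_fracs = np.array(free_fracs)
    res = welch_t_test(confined_fracs, free_fracs, names=("confined", "free"))
    return {
        "n_pairs": n_pairs,
        "patrolled_fraction_confined_mean": float(confined_fracs.mean()),
        "patrolled_fraction_free_mean": float(free_fracs.mean()),
        "fraction_pairs_confined_smaller": float(np.mean(confined_fracs < free_fracs)),
        "welch_p": res.p_value,
        "confined_fractions": confined_fracs,
        "free_fractions": free_fracs,
    }


# ---------------------------------------------------------------------------
# Patrolled-area geometry checks
# ---------------------------------------------------------------------------

def buffer_geometry_check(seed: int = 0, n_sets: int = 20, buffer_um: float = 7.0) -> dict:
    """Closed-form and raster checks of the buffered-union geometry."""
    point_area = buffer_union_area([np.array([[0.0, 0.0]])], buffer_um)
    seg_len = 30.0
    stadium_area = buffer_union_area([np.array([[0.0, 0.0], [seg_len, 0.0]])], buffer_um)
    point_expected = math.pi * buffer_um**2
    stadium_expected = 2 * buffer_um * seg_len + math.pi * buffer_um**2

    rng = np.random.default_rng(seed)
    max_rel_err = 0.0
    for _ in range(n_sets):
        polylines = [
            rng.uniform(0.0, 30.0, size=(int(rng.integers(2, 7)), 2))
            for _ in range(int(rng.integers(1, 4)))
        ]
        exact = buffer_union_area(polylines, buffer_um)
        raster = raster_union_area(polylines, buffer_um, resolution_um=0.1)
        max_rel_err = max(max_rel_err, abs(exact - raster) / raster)
    return {
        "point_area_um2": point_area,
        "point_expected_um2": point_expected,
        "stadium_area_um2": stadium_area,
        "stadium_expected_um2": stadium_expected,
        "raster_max_rel_err_pct": 100.0 * max_rel_err,
        "n_sets": n_sets,
    }


# ---------------------------------------------------------------------------
# Cytotoxicity plate
# ---------------------------------------------------------------------------

PLATE_CONDITIONS = (
    ("organoid_only", "B6", 0.05, 6),
    ("organoid_only", "BALB/c", 0.05, 6),
    ("syngeneic", "B6", 0.10, 6),
    ("allogeneic", "BALB/c", 0.25, 6),
)


def plate_experiment(seed: int = 0) -> dict:
    """Simulated co-culture plate: baseline-corrected death scores and the
    control < syngeneic < allogeneic contrast with ANOVA + Sidak."""
    df, true_fracs = simulate_plate(list(PLATE_CONDITIONS), seed=seed)
    scores = plate_scores(df)
    summary = condition_summary(scores)
    mean_by = dict(zip(summary["condition"], summary["mean"]))
    groups = [
        scores.loc[scores["condition"] == c, "corrected"].to_numpy()
        for c in ("organoid_only", "syngeneic", "allogeneic")
    ]
    anova = anova_sidak(groups, labels=["organoid_only", "syngeneic", "allogeneic"])
    return {
        "scores": scores,
        "summary": summary,
        "mean_corrected_allogeneic": float(mean_by["allogeneic"]),
        "mean_corrected_syngeneic": float(mean_by["syngeneic"]),
        "mean_corrected_control": float(mean_by["organoid_only"]),
        "anova_p": anova[0].p_value,
        "sidak_allo_vs_syn_p": next(
            r.adjusted_p for r in anova[1:]
            if {r.group_a, r.group_b} == {"allogeneic", "syngeneic"}
        ),
        "true_dead_fractions": true_fracs,
    }


# ---------------------------------------------------------------------------
# ddCt round trips
# ---------------------------------------------------------------------------

TCELL_FOLDS = {"Ifng": 8.0, "Gzmb": 4.0, "Tnf": 2.0}
EPITHELIAL_FOLDS = {"Lgr5": 0.4}


def ddct_experiment(seed: int = 0, ct_noise_sigma: float = 0.1) -> dict:
    """Recover known fold changes through both normalization conventions.

    T-cell effector genes (folds 8 / 4 / 2) are normalized to the
    syngeneic condition; the stem-cell marker (fold 0.4) to the
    genotype-matched organoid-only control.  Also runs the zero-noise
    table, whose recovery must be exact.
    """
    recovered: dict[str, float] = {}
    for noise, store in ((0.0, None), (ct_noise_sigma, recovered)):
        tc = simulate_ct_table(
            list(TCELL_FOLDS), TCELL_FOLDS, n_replicates=3,
            ct_noise_sigma=noise, seed=seed,
        )
        ep = simulate_ct_table(
            list(EPITHELIAL_FOLDS), EPITHELIAL_FOLDS, n_replicates=3,
            ct_noise_sigma=noise, seed=seed + 1,
            reference_condition="organoid_only", test_condition="allogeneic",
            genotype_map={"organoid_only": "BALB/c", "allogeneic": "BALB/c"},
        )
        got = {}
        for gene in TCELL_FOLDS:
            folds = normalize_scheme(tc, gene, "vs_syngeneic")
            got[gene] = float(condition_folds(folds)["allogeneic"])
        for gene in EPITHELIAL_FOLDS:
            folds = normalize_scheme(ep, gene, "vs_organoid_only")
            got[gene] = float(condition_folds(folds)["allogeneic"])
        if store is None:
            truth = {**TCELL_FOLDS, **EPITHELIAL_FOLDS}
            zero_noise_max_err = max(abs(got[g] - truth[g]) / truth[g] for g in got)
        else:
            store.update(got)
    truth = {**TCELL_FOLDS, **EPITHELIAL_FOLDS}
    max_rel_err = max(abs(recovered[g] - truth[g]) / truth[g] for g in recovered)
    return {
        "true_folds": truth,
        "recovered_folds": recovered,
        "max_relative_error_pct": 100.0 * max_rel_err,
        "zero_noise_max_relative_error": zero_noise_max_err,
    }


# ---------------------------------------------------------------------------
# Statistical calibration
# ---------------------------------------------------------------------------

def type_i_error_experiment(seed: int = 0, n_reps: int = 2000, n_per_group: int = 7) -> dict:
    """Null rejection rates at alpha = 0.05: Welch t on two equal-mean
    normal groups and the one-way ANOVA F over three, 2000 replicates."""
    rng = np.random.default_rng(seed)
    welch_rej = anova_rej = 0
    for _ in range(n_reps):
        g = rng.normal(size=(3, n_per_group))
        if welch_t_test(g[0], g[1]).p_value < 0.05:
            welch_rej += 1
        if anova_sidak(list(g))[0].p_value < 0.05:
            anova_rej += 1
    return {
        "welch_type_i_rate": welch_rej / n_reps,
        "anova_type_i_rate": anova_rej / n_reps,
        "n_reps": n_reps,
        "sidak_adjusted_p_005_m3": sidak_adjust(0.05, 3),
    }
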