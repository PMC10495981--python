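"""Validation utilities: brute-force references and ground-truth matching.

These routines deliberately re-derive quantities by slow, transparent
methods that share no code path with the production implementations:

* ``exhaustive_matching_cost`` enumerates every feasible partial matching
  (usable up to ~6 items per side) — the reference for the LAP stages.
* ``exhaustive_linking_cost`` / ``exhaustive_gap_cost`` apply it to the
  frame-linking and gap-closing objectives.
* ``raster_union_area`` rasterizes buffered polylines on a fine grid —
  the reference for the exact polygon geometry.
* ``match_tracks_to_truth`` / ``detection_scores`` score pipeline output
  against simulator ground truth.
"""

from __future__ import annotations

import numpy as np

from .detection import Spot
from .tracking import Track


# ---------------------------------------------------------------------------
# Exhaustive assignment references
# ---------------------------------------------------------------------------

def exhaustive_matching_cost(cost: np.ndarray, alt_cost: float) -> float:
    """Minimum of ``sum(matched costs) + alt_cost * (#unmatched rows +
    #unmatched cols)`` over all partial matchings, by full enumeration.

    ``cost`` is (n, m) with ``np.inf`` marking forbidden pairs.
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape

    def recurse(i: int, used: frozenset) -> float:
        if i == n:
            return alt_cost * (m - len(used))
        best = alt_cost + recurse(i + 1, used)  # row i unmatched
        for j in range(m):
            if j in used or not np.isfinite(cost[i, j]):
                continue
            best = min(best, cost[i, j] + recurse(i + 1, used | {j}))
        return best

    return float(recurse(0, frozenset()))


def _sq_dist(a: Spot, b: Spot) -> float:
    return (a.x_um - b.x_um) ** 2 + (a.y_um - b.y_um) ** 2


def exhaustive_linking_cost(
    spots: list[Spot], max_link_distance_um: float, alt_cost_factor: float = 1.05
) -> float:
    """Optimal total frame-linking objective by enumeration, summed over
    consecutive frame pairs from the first to the last occupied frame."""
    b = alt_cost_factor * max_link_distance_um**2
    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)
    if not by_frame:
        return 0.0
    total = 0.0
    for f in range(min(by_frame), max(by_frame)):
        prev, cur = by_frame.get(f, []), by_frame.get(f + 1, [])
        if not prev and not cur:
            continue
        if not prev or not cur:
            total += b * (len(prev) + len(cur))
            continue
        cost = np.full((len(prev), len(cur)), np.inf)
        for i, p in enumerate(prev):
            for j, c in enumerate(cur):
                d2 = _sq_dist(p, c)
                if d2 <= max_link_distance_um**2:
                    cost[i, j] = d2
        total += exhaustive_matching_cost(cost, b)
    return total


def exhaustive_gap_cost(
    segments: list[list[Spot]],
    max_gap_distance_um: float,
    max_frame_gap: int,
    alt_cost_factor: float = 1.05,
) -> float:
    """Optimal gap-closing objective (ends x starts) by enumeration."""
    b = alt_cost_factor * max_gap_distance_um**2
    n = len(segments)
    if n == 0:
        return 0.0
    cost = np.full((n, n), np.inf)
    for e in range(n):
        for s in range(n):
            if e == s:
                continue
            dt = segments[s][0].frame - segments[e][-1].frame
            if not (2 <= dt <= max_frame_gap):
                continue
            d2 = _sq_dist(segments[e][-1], segments[s][0])
            if d2 <= max_gap_distance_um**2:
                cost[e, s] = d2
    return exhaustive_matching_cost(cost, b)


# ---------------------------------------------------------------------------
# Raster reference for buffered-track areas
# ---------------------------------------------------------------------------

def raster_union_area(polylines, buffer_radius_um: float, resolution_um: float = 0.1) -> float:
    """Buffered-union area by rasterization at a fixed grid resolution.

    A grid point counts as covered when its distance to any polyline
    segment (or isolated vertex) is <= the buffer radius; the area is the
    covered-cell count times the cell area.
    """
    polylines = [np.asarray(pl, dtype=float) for pl in polylines]
    if not polylines:
        return 0.0
    allpts = np.vstack(polylines)
    lo = allpts.min(axis=0) - buffer_radius_um - resolution_um
    hi = allpts.max(axis=0) + buffer_radius_um + resolution_um
    xs = np.arange(lo[0], hi[0], resolution_um) + resolution_um / 2
    ys = np.arange(lo[1], hi[1], resolution_um) + resolution_um / 2
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    covered = np.zeros(len(pts), dtype=bool)
    r2 = buffer_radius_um**2
    for pl in polylines:
        if len(pl) == 1:
            d2 = ((pts - pl[0]) ** 2).sum(axis=1)
            covered |= d2 <= r2
            continue
        for a, b in zip(pl[:-1], pl[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0.0:
                d2 = ((pts - a) ** 2).sum(axis=1)
            else:
                t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
                proj = a + t[:, None] * ab
                d2 = ((pts - proj) ** 2).sum(axis=1)
            covered |= d2 <= r2
    return float(covered.sum()) * resolution_um**2


# ---------------------------------------------------------------------------
# Ground-truth scoring
# ---------------------------------------------------------------------------

def detection_scores(
    spots: list[Spot], true_positions_um: np.ndarray, match_radius_um: float
) -> dict:
    """Per-frame detection recall / precision against true positions.

    ``true_positions_um`` has shape (n_cells, n_frames, 2).  A detection
    matches the nearest unclaimed true position within the match radius
    (greedy nearest-first matching).
    """
    n_cells, n_frames, _ = true_positions_um.shape
    tp = fp = 0
    for f in range(n_frames):
        dets = [(s.x_um, s.y_um) for s in spots if s.frame == f]
        truth = true_positions_um[:, f, :]
        claimed = np.zeros(n_cells, dtype=bool)
        pairs = []
        for di, (x, y) in enumerate(dets):
            d = np.linalg.norm(truth - np.array([x, y]), axis=1)
            for ci in np.argsort(d):
                pairs.append((d[ci], di, ci))
        pairs.sort()
        det_used = set()
        for d, di, ci in pairs:
            if d > match_radius_um or di in det_used or claimed[ci]:
                continue
            det_used.add(di)
            claimed[ci] = True
            tp += 1
        fp += len(dets) - len(det_used)
    fn = n_cells * n_frames - tp
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return {"tp": tp, "fp": fp, "fn": fn, "recall": recall, "precision": precision}


def match_tracks_to_truth(
    tracks: list[Track],
    true_positions_um: np.ndarray,
    match_radius_um: float = 5.0,
    min_coverage: float = 0.8,
) -> dict:
    """Identity-aware track recovery against ground-truth trajectories.

    A detected track is *pure* when every one of its spots lies within the
    match radius of the same true cell at the corresponding frame.  A true
    cell counts as recovered without identity swap when a pure track
    assigned to it covers at least ``min_coverage`` of the movie's frames.
    """
    n_cells, n_frames, _ = true_positions_um.shape
    best_coverage = np.zeros(n_cells)
    impure = 0
    for tr in tracks:
        cells = set()
        ok = True
        for s in tr.spots:
            d = np.linalg.norm(
                true_positions_um[:, s.frame, :] - np.array([s.x_um, s.y_um]), axis=1
            )
            ci = int(np.argmin(d))
            if d[ci] > match_radius_um:
                ok = False
                break
            cells.add(ci)
        if not ok or len(cells) != 1:
            impure += 1
            continue
        ci = cells.pop()
        best_coverage[ci] = max(best_coverage[ci], len(tr.spots) / n_frames)
    recovered = int(np.sum(best_coverage >= min_coverage))
    return {
        "n_cells": n_cells,
        "recovered": recovered,
        "recovery_rate": recovered / n_cells if n_cells else 1.0,
        "impure_tracks": impure,
    }
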