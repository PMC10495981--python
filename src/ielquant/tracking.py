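"""Simple LAP particle tracking: frame-to-frame linking, then gap closing.

The tracker follows the two-pass linear-assignment design of Jaqaman-style
"simple" trackers (no splitting or merging):

1. *Linking* — for every consecutive frame pair, a rectangular assignment
   between the spots of the two frames, cost = squared Euclidean distance,
   links beyond ``max_link_distance_um`` forbidden, and a per-spot "no
   link" alternative costing ``alt_cost_factor * max_link_distance^2``.
   Each frame pair is solved to global optimality.
2. *Gap closing* — one global assignment between segment ends and later
   segment starts separated by 2..``max_frame_gap`` frames and at most
   ``max_gap_distance_um``; accepted joins concatenate segments.
   (A frame difference of 1 is adjacent frames, which linking already
   handles, so ``max_frame_gap = 2`` permits exactly one missed frame.)

The minimized objective at each stage is::

    sum of squared link distances + b * (number of unmatched endpoints)

with ``b = alt_cost_factor * max_distance^2``, realized exactly via the
standard augmented square cost matrix and ``scipy.optimize.linear_sum_assignment``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Spot

_BIG = 1e9  # finite "forbidden" cost; far above any feasible total


@dataclass(frozen=True)
class TrackingConfig:
    max_link_distance_um: float = 15.0
    max_gap_distance_um: float = 15.0
    max_frame_gap: int = 2
    alt_cost_factor: float = 1.05

    def __post_init__(self) -> None:
        if self.max_link_distance_um <= 0 or self.max_gap_distance_um <= 0:
            raise ValueError("distances must be > 0")
        if self.max_frame_gap < 1:
            raise ValueError("max_frame_gap must be >= 1")
        if self.alt_cost_factor <= 1:
            raise ValueError("alt_cost_factor must be > 1")


@dataclass
class Track:
    """An ordered spot sequence, strictly increasing in frame."""

    track_id: int
    spots: list[Spot]
    source: str = "linked"  # "linked" or "gap-closed" (contains joins)

    @property
    def first(self) -> Spot:
        return self.spots[0]

    @property
    def last(self) -> Spot:
        return self.spots[-1]


def _solve_lap(cost: np.ndarray, alt_cost: float) -> list[tuple[int, int]]:
    """Min-cost partial matching with per-item opt-out cost ``alt_cost``.

    ``cost`` is an (n, m) matrix with ``np.inf`` marking forbidden pairs.
    Returns the matched (i, j) pairs of the assignment minimizing
    ``sum(matched costs) + alt_cost * (#unmatched rows + #unmatched cols)``,
    found exactly via the augmented (n+m) x (n+m) formulation: the
    lower-right block mirrors feasibility of the upper-left at zero cost,
    so every partial matching corresponds to a permutation of equal cost.
    """
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    C = np.full((n + m, n + m), _BIG)
    feas = np.isfinite(cost)
    C[:n, :m] = np.where(feas, cost, _BIG)
    C[np.arange(n), m + np.arange(n)] = alt_cost  # row opt-out (death)
    C[n + np.arange(m), np.arange(m)] = alt_cost  # col opt-out (birth)
    C[n:, m:][feas.T] = 0.0  # auxiliary mirror block
    rows, cols = linear_sum_assignment(C)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and feas[i, j]
    ]


def link_frames(
    spots: list[Spot],
    max_link_distance_um: float,
    alt_cost_factor: float = 1.05,
    return_cost: bool = False,
):
    """Frame-to-frame linking; returns maximal unbroken track segments.

    Each consecutive frame pair is solved independently; a frame with no
    spots terminates every active segment (gap closing may bridge it
    later).  Optionally also returns the total linking objective, i.e.
    ``sum(d^2 over links) + b * (#unlinked ends + #unlinked starts)``
    summed over frame pairs, for validation against exhaustive search.
    """
    b = alt_cost_factor * max_link_distance_um**2
    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        if s.frame < 0:
            raise ValueError("spot frames must be >= 0")
        by_frame.setdefault(s.frame, []).append(s)

    segments: list[list[Spot]] = []
    total_cost = 0.0
    if not by_frame:
        return ([], 0.0) if return_cost else []
    first_frame = min(by_frame)
    frames = range(first_frame, max(by_frame) + 1)
    prev_active: list[int] = []
    for f in frames:
        cur = by_frame.get(f, [])
        prev_spots = [segments[k][-1] for k in prev_active]
        if prev_spots and cur:
            pp = np.array([[s.x_um, s.y_um] for s in prev_spots])
            cc = np.array([[s.x_um, s.y_um] for s in cur])
            d2 = ((pp[:, None, :] - cc[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_link_distance_um**2, d2, np.inf)
            matches = _solve_lap(cost, b)
        else:
            matches = []
        matched_cur = {j for _, j in matches}
        if f > first_frame:
            # objective terms for the frame pair (f-1, f): every spot of
            # frame f-1 is the tail of exactly one active segment
            total_cost += sum(
                ((prev_spots[i].x_um - cur[j].x_um) ** 2 + (prev_spots[i].y_um - cur[j].y_um) ** 2)
                for i, j in matches
            )
            total_cost += b * (len(prev_spots) - len(matches))
            total_cost += b * (len(cur) - len(matches))
        next_active = []
        for i, j in matches:
            seg_idx = prev_active[i]
            segments[seg_idx].append(cur[j])
            next_active.append(seg_idx)
        for j, s in enumerate(cur):
            if j not in matched_cur:
                segments.append([s])
                next_active.append(len(segments) - 1)
        prev_active = next_active
    if return_cost:
        return segments, total_cost
    return segments


def close_gaps(
    segments: list[list[Spot]],
    max_gap_distance_um: float,
    max_frame_gap: int,
    alt_cost_factor: float = 1.05,
    return_cost: bool = False,
):
    """Join segment ends to later segment starts across missed frames.

    One global assignment over all (end, start) pairs with frame difference
    in ``{2, ..., max_frame_gap}`` and distance <= ``max_gap_distance_um``;
    cost = squared distance, opt-out cost ``alt_cost_factor * max_gap^2``.
    Final tracks are renumbered by (first frame, x, y) of their first spot.
    """
    b = alt_cost_factor * max_gap_distance_um**2
    n = len(segments)
    joined_any = [False] * n
    succ: dict[int, int] = {}
    if n and max_frame_gap >= 2:
        cost = np.full((n, n), np.inf)
        for e in range(n):
            end = segments[e][-1]
            for s in range(n):
                if e == s:
                    continue
                start = segments[s][0]
                dt = start.frame - end.frame
                if not (2 <= dt <= max_frame_gap):
                    continue
                d2 = (end.x_um - start.x_um) ** 2 + (end.y_um - start.y_um) ** 2
                if d2 <= max_gap_distance_um**2:
                    cost[e, s] = d2
        matches = _solve_lap(cost, b)
        total_cost = sum(cost[e, s] for e, s in matches) + b * 2 * (n - len(matches))
        for e, s in matches:
            succ[e] = s
            joined_any[e] = joined_any[s] = True
    else:
        total_cost = b * 2 * n if n else 0.0

    has_pred = set(succ.values())
    chains: list[list[Spot]] = []
    sources: list[str] = []
    for head in range(n):
        if head in has_pred:
            continue
        spots: list[Spot] = []
        k, closed = head, False
        while True:
            spots.extend(segments[k])
            if k in succ:
                closed = True
                k = succ[k]
            else:
                break
        chains.append(spots)
        sources.append("gap-closed" if closed else "linked")

    order = sorted(
        range(len(chains)),
        key=lambda i: (chains[i][0].frame, chains[i][0].x_um, chains[i][0].y_um),
    )
    tracks = [
        Track(track_id=tid, spots=chains[i], source=sources[i])
        for tid, i in enumerate(order)
    ]
    if return_cost:
        return tracks, total_cost
    return tracks


def track_particles(spots: list[Spot], config: TrackingConfig) -> list[Track]:
    """Full Simple LAP tracking: linking then gap closing."""
    segments = link_frames(spots, config.max_link_distance_um, config.alt_cost_factor)
    return close_gaps(
        segments, config.max_gap_distance_um, config.max_frame_gap, config.alt_cost_factor
    )
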