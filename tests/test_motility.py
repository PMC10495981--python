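"""Speeds, the speed-exclusion filter, and the patrolled-area geometry."""

import math

import numpy as np
import pytest

from ielquant.detection import Spot
from ielquant.evaluation import raster_union_area
from ielquant.motility import (
    MotilityConfig,
    buffer_union_area,
    filter_tracks_by_speed,
    mean_speed,
    patrolled_area,
    track_stats,
)
from ielquant.roi import RegionOfInterest, annulus_roi
from ielquant.tracking import Track


def make_track(points, frames=None, tid=0):
    frames = frames if frames is not None else range(len(points))
    spots = [
        Spot(frame=f, x_um=float(x), y_um=float(y), quality=1.0, radius_um=3.5)
        for f, (x, y) in zip(frames, points)
    ]
    return Track(track_id=tid, spots=spots)


class TestMeanSpeed:
    def test_stationary_track_zero_speed(self):
        t = make_track([(5, 5)] * 10)
        assert mean_speed(t, 30.0) == 0.0

    def test_three_um_steps_at_30s_give_point_one(self):
        t = make_track([(i * 3.0, 0.0) for i in range(5)])
        assert mean_speed(t, 30.0) == pytest.approx(0.1)

    def test_gap_spanning_link_uses_true_frame_difference(self):
        # 6 um across a 2-frame gap is still 0.1 um/s
        t = make_track([(0, 0), (3, 0), (9, 0)], frames=[0, 1, 3])
        assert mean_speed(t, 30.0) == pytest.approx(0.1)

    def test_single_spot_track_flagged_and_zero(self):
        t = make_track([(0, 0)])
        with pytest.warns(UserWarning, match="single spot"):
            assert mean_speed(t, 30.0) == 0.0

    def test_track_stats_fields(self):
        t = make_track([(0, 0), (3, 0), (3, 4)])
        st = track_stats(t, 30.0)
        assert st.path_length_um == pytest.approx(7.0)
        assert st.duration_s == pytest.approx(60.0)
        assert st.n_spots == 3


class TestSpeedFilter:
    def test_strictly_below_excluded_boundary_retained(self):
        slow = make_track([(0, 0), (1.47, 0)], tid=1)  # 0.049 um/s
        boundary = make_track([(0, 0), (1.5, 0)], tid=2)  # exactly 0.05
        fast = make_track([(0, 0), (3.0, 0)], tid=3)
        kept = filter_tracks_by_speed([slow, boundary, fast], 0.05, 30.0)
        assert [t.track_id for t in kept] == [2, 3]

    def test_empty_input_empty_output(self):
        assert filter_tracks_by_speed([], 0.05, 30.0) == []


class TestBufferUnionArea:
    def test_point_buffer_is_disk(self):
        area = buffer_union_area([np.array([[0.0, 0.0]])], 7.0)
        assert area == pytest.approx(49 * math.pi, rel=1e-3)

    def test_straight_segment_is_stadium(self):
        area = buffer_union_area([np.array([[0.0, 0.0], [30.0, 0.0]])], 7.0)
        assert area == pytest.approx(2 * 7 * 30 + 49 * math.pi, rel=1e-3)

    def test_crossing_segments_match_raster_oracle(self):
        polylines = [
            np.array([[0.0, 0.0], [30.0, 30.0]]),
            np.array([[0.0, 30.0], [30.0, 0.0]]),
        ]
        exact = buffer_union_area(polylines, 7.0)
        raster = raster_union_area(polylines, 7.0, resolution_um=0.1)
        assert exact == pytest.approx(raster, rel=0.01)

    def test_disjoint_buffers_areas_add(self):
        a = np.array([[0.0, 0.0], [10.0, 0.0]])
        b = a + [0.0, 100.0]
        both = buffer_union_area([a, b], 7.0)
        assert both == pytest.approx(2 * buffer_union_area([a], 7.0), rel=1e-6)

    def test_buffer_radius_monotonicity(self):
        pl = [np.array([[0.0, 0.0], [10.0, 5.0], [20.0, 0.0]])]
        areas = [buffer_union_area(pl, r) for r in (3.0, 5.0, 7.0, 9.0)]
        assert all(x < y for x, y in zip(areas, areas[1:]))

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            buffer_union_area([np.array([[0.0, 0.0]])], 0.0)


class TestPatrolledArea:
    CFG = MotilityConfig(frame_interval_s=30.0)

    def test_no_tracks_zero_fraction(self):
        roi = annulus_roi((0, 0), 50.0)
        res = patrolled_area([], roi, self.CFG)
        assert res.patrolled_fraction == 0.0
        assert res.roi_area_um2 == pytest.approx(roi.area_um2)

    def test_stationary_point_fraction_is_disk_over_roi(self):
        roi = annulus_roi((0, 0), 50.0)  # full disk epithelium, no lumen
        res = patrolled_area([make_track([(0.0, 0.0)] * 3)], roi, self.CFG)
        assert res.patrolled_fraction == pytest.approx(49 * math.pi / roi.area_um2, rel=1e-3)

    def test_fraction_clipped_to_roi_stays_below_one(self):
        roi = annulus_roi((0, 0), 10.0)
        track = make_track([(-40.0, 0.0), (40.0, 0.0)])  # buffer overshoots ROI
        res = patrolled_area([track], roi, self.CFG)
        assert 0.0 <= res.patrolled_fraction <= 1.0
        assert res.patrolled_area_um2 <= roi.area_um2 + 1e-9

    def test_adding_a_track_never_shrinks_area(self):
        roi = annulus_roi((0, 0), 60.0, 10.0)
        t1 = make_track([(30.0, 0.0), (35.0, 5.0)], tid=1)
        t2 = make_track([(0.0, 30.0), (-5.0, 35.0)], tid=2)
        a1 = patrolled_area([t1], roi, self.CFG).patrolled_area_um2
        a12 = patrolled_area([t1, t2], roi, self.CFG).patrolled_area_um2
        assert a12 >= a1

    def test_lumen_hole_reduces_roi_area(self):
        full = annulus_roi((0, 0), 50.0)
        holed = annulus_roi((0, 0), 50.0, 20.0)
        assert holed.area_um2 < full.area_um2


class TestRegionOfInterest:
    def test_geojson_round_trip(self, tmp_path):
        roi = annulus_roi((10.0, -5.0), 40.0, 15.0)
        p = tmp_path / "roi.geojson"
        roi.write(p)
        back = RegionOfInterest.read(p)
        assert back.area_um2 == pytest.approx(roi.area_um2, rel=1e-12)
        assert len(back.holes) == 1

    def test_hole_outside_outer_rejected(self):
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        far_hole = square + 100.0
        with pytest.raises(ValueError):
            RegionOfInterest(outer=square, holes=[far_hole])

    def test_self_intersecting_outer_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(ValueError):
            RegionOfInterest(outer=bowtie)
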