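import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import murretrax as mt
from murretrax.divetrip import Dive
from murretrax.hmm import BehaviorSequence


def seq(labels, dep_id="b0"):
    return BehaviorSequence(deployment_id=dep_id,
                            states=np.asarray(labels, dtype=object),
                            log_likelihood=0.0)


class TestDetectDives:
    def test_flat_zero_trace(self):
        assert mt.detect_dives(np.arange(100.0), np.zeros(100)) == []

    def test_v_excursion(self):
        depth = np.array([0, 2, 10, 18, 10, 2, 0], dtype=float)
        dives = mt.detect_dives(np.arange(7.0), depth, min_depth_m=1.0)
        assert len(dives) == 1
        assert dives[0].max_depth_m == 18.0
        assert dives[0].duration_min == pytest.approx(5 / 60)

    def test_one_surface_second_separates(self):
        depth = np.array([0, 5, 5, 0, 5, 5, 0], dtype=float)
        assert len(mt.detect_dives(np.arange(7.0), depth)) == 2

    def test_trace_gap_separates(self):
        # two excursions in a sparse trace with a time gap between them
        t = np.array([0, 1, 2, 100, 101, 102], dtype=float)
        depth = np.array([3, 8, 3, 3, 8, 3], dtype=float)
        assert len(mt.detect_dives(t, depth)) == 2

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            mt.detect_dives(np.arange(3.0), np.array([0.0, -1.0, 0.0]))


def _dives_with_gaps(gaps_min, dur_s=60.0):
    """Build consecutive 1-minute dives separated by the given gaps."""
    dives, t = [], 0.0
    for g in [None] + list(gaps_min):
        if g is not None:
            t += g * 60.0
        dives.append(Dive(start_t=t, end_t=t + dur_s, max_depth_m=10.0))
        t += dur_s
    return dives


class TestGroupBouts:
    def test_printed_gap_pattern(self):
        bouts = mt.group_bouts(_dives_with_gaps([2, 3, 10]), pdi_min=5.0)
        assert [b.n_dives for b in bouts] == [3, 1]

    def test_single_dive(self):
        bouts = mt.group_bouts(_dives_with_gaps([]))
        assert len(bouts) == 1 and bouts[0].n_dives == 1

    def test_gap_exactly_at_interval_stays_in_bout(self):
        bouts = mt.group_bouts(_dives_with_gaps([5.0]), pdi_min=5.0)
        assert len(bouts) == 1

    def test_overlapping_dives_rejected(self):
        d = [Dive(0, 100, 5.0), Dive(50, 150, 5.0)]
        with pytest.raises(ValueError):
            mt.group_bouts(d)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gaps=st.lists(st.floats(0.1, 30.0), max_size=12),
           pdis=st.tuples(st.floats(0.5, 20.0), st.floats(0.5, 20.0)))
    def test_partition_and_monotonicity(self, gaps, pdis):
        """Bouts partition the dives; bout count never increases with pdi."""
        dives = _dives_with_gaps(gaps)
        lo, hi = sorted(pdis)
        b_lo = mt.group_bouts(dives, pdi_min=lo)
        b_hi = mt.group_bouts(dives, pdi_min=hi)
        assert sum(b.n_dives for b in b_lo) == len(dives)
        assert len(b_hi) <= len(b_lo)


class TestSegmentTrips:
    def test_all_colony(self, make_dep):
        dep = make_dep(t=np.arange(10) * 60.0, lon=[-82.01] * 10, lat=[62.95] * 10)
        assert mt.segment_trips(seq(["COLONY"] * 10), dep) == []

    def test_single_block_duration(self, make_dep):
        n = 8
        t = np.arange(n) * 3600.0
        dep = make_dep(t=t, lon=[-82.01] * n, lat=[62.95] * n)
        labels = ["COLONY"] + ["FLY"] * 6 + ["COLONY"]
        trips = mt.segment_trips(seq(labels), dep)
        assert len(trips) == 1
        assert trips[0].duration_h == pytest.approx(7.0)  # last colony fix bound
        assert not trips[0].truncated

    def test_out_and_back_distances(self, make_dep, config):
        # ride due north 50 km and back along a meridian
        lat0 = config.colony_lon_lat[1]
        dlat = 50.0 / 111.1949
        lats = [lat0, lat0 + dlat / 2, lat0 + dlat, lat0 + dlat / 2, lat0]
        dep = make_dep(t=np.arange(5) * 600.0, lon=[config.colony_lon_lat[0]] * 5,
                       lat=lats)
        trips = mt.segment_trips(seq(["COLONY", "FLY", "SWIM", "FLY", "COLONY"]), dep)
        assert trips[0].max_dist_km == pytest.approx(50.0, rel=1e-3)
        assert trips[0].total_dist_km == pytest.approx(100.0, rel=1e-3)

    def test_edge_blocks_truncated(self, make_dep):
        n = 6
        dep = make_dep(t=np.arange(n) * 60.0, lon=[-82.0] * n, lat=[62.95] * n)
        trips = mt.segment_trips(seq(["FLY"] * 3 + ["COLONY"] * 3), dep)
        assert trips[0].truncated

    def test_concatenated_deployments_do_not_merge(self, make_dep):
        """A trip never spans a deployment boundary: segmentation is per bird."""
        n = 4
        dep_a = make_dep(t=np.arange(n) * 60.0, lon=[-82.0] * n, lat=[62.95] * n,
                         bird_id="a")
        dep_b = make_dep(t=(n + np.arange(n)) * 60.0, lon=[-82.0] * n,
                         lat=[62.95] * n, bird_id="b")
        ta = mt.segment_trips(seq(["COLONY", "FLY", "FLY", "FLY"]), dep_a)
        tb = mt.segment_trips(seq(["FLY", "FLY", "COLONY", "COLONY"]), dep_b)
        assert len(ta) == 1 and len(tb) == 1
        assert ta[0].truncated and tb[0].truncated


class TestClassifyForaging:
    def _trip(self, dives):
        return mt.Trip(depart_t=0.0, return_t=3600.0, max_dist_km=1.0,
                       total_dist_km=2.0, dives=dives)

    def test_two_shallow_dives_forage(self):
        t = self._trip([Dive(0, 60, 3.0), Dive(600, 660, 3.0)])
        assert mt.classify_foraging(t) is True

    def test_one_deep_dive_forages(self):
        assert mt.classify_foraging(self._trip([Dive(0, 60, 20.0)])) is True

    def test_one_shallow_dive_does_not(self):
        assert mt.classify_foraging(self._trip([Dive(0, 60, 5.0)])) is False

    def test_threshold_is_strict(self, config):
        t = self._trip([Dive(0, 60, config.single_dive_trip_threshold_m)])
        assert mt.classify_foraging(t, config) is False


class TestSummarizeDeployment:
    def test_trip_arithmetic(self, make_dep):
        dep = make_dep(t=[0.0, 48 * 3600.0], lon=[-82.01] * 2, lat=[62.95] * 2)
        trips = [mt.Trip(depart_t=0, return_t=4 * 3600, max_dist_km=10,
                         total_dist_km=20, is_foraging=True),
                 mt.Trip(depart_t=10 * 3600, return_t=16 * 3600, max_dist_km=30,
                         total_dist_km=40, is_foraging=True)]
        s = mt.summarize_deployment(dep, trips)
        assert s.trips_per_day == pytest.approx(1.0)
        assert s.mean_trip_dur_h == pytest.approx(5.0)
        assert s.max_dist_km == 30
        assert s.mean_trip_dist_km == pytest.approx(30.0)

    def test_dive_arithmetic(self, make_dep):
        dep = make_dep(t=[0.0, 24 * 3600.0], lon=[-82.01] * 2, lat=[62.95] * 2)
        dives = [Dive(0, 60, 10.0), Dive(400, 580, 20.0)]
        trip = mt.Trip(depart_t=0, return_t=3600, max_dist_km=1, total_dist_km=2,
                       dives=dives, bouts=mt.group_bouts(dives), is_foraging=True,
                       truncated=True)
        s = mt.summarize_deployment(dep, [trip])
        assert s.max_dive_depth_m == 20 and s.mean_dive_depth_m == 15
        assert s.max_dive_dur_min == pytest.approx(3.0)
        assert s.mean_dive_dur_min == pytest.approx(2.0)
        assert np.isnan(s.mean_trip_dur_h)       # only truncated trips

    def test_diving_over_all_includes_nonforaging_dives(self, make_dep):
        dep = make_dep(t=[0.0, 24 * 3600.0], lon=[-82.01] * 2, lat=[62.95] * 2)
        deep = [Dive(0, 60, 10.0), Dive(120, 180, 30.0)]
        shallow = [Dive(7200, 7260, 4.0)]
        trips = [mt.Trip(0, 3600, 1, 2, dives=deep, bouts=mt.group_bouts(deep),
                         is_foraging=True),
                 mt.Trip(7000, 7400, 1, 2, dives=shallow,
                         bouts=mt.group_bouts(shallow), is_foraging=False)]
        only_foraging = mt.summarize_deployment(dep, trips)
        everything = mt.summarize_deployment(dep, trips, diving_over="all")
        assert only_foraging.dives_per_day == pytest.approx(2.0)
        assert everything.dives_per_day == pytest.approx(3.0)

    def test_no_dives_missing_not_zero(self, make_dep):
        dep = make_dep(t=[0.0, 24 * 3600.0], lon=[-82.01] * 2, lat=[62.95] * 2)
        s = mt.summarize_deployment(dep, [])
        assert s.trips_per_day == 0.0
        assert np.isnan(s.max_dive_depth_m) and np.isnan(s.dives_per_day)


class TestSexFromAttendance:
    def _schedule(self, make_dep, colony_windows):
        """48 h at 10-min fixes; bird at colony only inside given solar windows."""
        from murretrax.geodesy import solar_hour
        n = 48 * 6
        t = np.arange(n) * 600.0
        lon = -82.01
        sh = solar_hour(t, lon)
        labels = np.full(n, "SWIM", dtype=object)
        for lo, hi in colony_windows:
            m = (sh >= lo) | (sh < hi) if lo > hi else (sh >= lo) & (sh < hi)
            labels[m] = "COLONY"
        dep = make_dep(t=t, lon=[lon] * n, lat=[62.95] * n)
        return seq(labels), dep

    def test_female_schedule(self, make_dep):
        s, d = self._schedule(make_dep, [(23.5, 3.5)])
        assert mt.sex_from_attendance(s, d) == "F"

    def test_male_schedule(self, make_dep):
        s, d = self._schedule(make_dep, [(11.5, 15.5)])
        assert mt.sex_from_attendance(s, d) == "M"

    def test_always_at_colony_ambiguous(self, make_dep):
        s, d = self._schedule(make_dep, [(0.0, 24.0)])
        assert mt.sex_from_attendance(s, d) == "UNDETERMINED"

    def test_short_deployment_warns(self, make_dep):
        n = 12
        dep = make_dep(t=np.arange(n) * 600.0, lon=[-82.01] * n, lat=[62.95] * n)
        with pytest.warns(UserWarning):
            assert mt.sex_from_attendance(seq(["COLONY"] * n), dep) == "UNDETERMINED"

    def test_simulated_birds_sexed_correctly(self, small_sim):
        hits = sum(mt.sex_from_attendance(tr, d) == d.sex
                   for d, tr in zip(small_sim.deployments, small_sim.truth))
        assert hits >= 4    # of 5; attendance windows are planted by sex
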