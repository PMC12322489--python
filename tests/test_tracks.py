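import numpy as np
import pytest

from conftest import make_fixes
from cpforage.geometry import GeoPoint, PolygonRegion, StudyArea
from cpforage.tracks import (
    Trip,
    delineate_trips,
    exclude_land_trips,
    filter_incomplete,
    individual_max_range,
    process_deployments,
    subsample,
    trip_metrics,
    trips_to_frame,
)

COLONY = GeoPoint(0.0, 0.0)


def lon_at(km):
    """Longitude at the equator for a given eastward distance in km."""
    return km / 111.195


def fixes_at_distances(times_min, dists_km, **kw):
    return make_fixes(times_min, [(lon_at(d), 0.0) for d in dists_km], **kw)


class TestSubsample:
    def test_two_minute_cadence_keeps_every_tenth_minute(self):
        fixes = fixes_at_distances(list(range(0, 21, 2)), [1.0] * 11)
        out = subsample(fixes, 10)
        mins = (out["timestamp"] - out["timestamp"].iloc[0]) / np.timedelta64(1, "m")
        assert list(mins) == [0.0, 10.0, 20.0]

    def test_already_at_interval_unchanged(self):
        fixes = fixes_at_distances([0, 10, 20, 30], [1, 2, 3, 4])
        assert len(subsample(fixes, 10)) == 4

    def test_single_fix(self):
        fixes = fixes_at_distances([0], [1.0])
        assert len(subsample(fixes, 10)) == 1

    def test_unsorted_rejected(self):
        fixes = fixes_at_distances([0, 20, 10], [1, 1, 1])
        with pytest.raises(ValueError):
            subsample(fixes, 10)

    def test_gap_and_subset_properties(self, rng):
        times = np.cumsum(rng.integers(1, 9, 60))
        fixes = fixes_at_distances(times, rng.random(60))
        out = subsample(fixes, 10)
        gaps = np.diff(out["timestamp"]) / np.timedelta64(1, "m")
        assert (gaps >= 10).all()
        merged = fixes.merge(out, on=["timestamp", "lon", "lat", "bird_id"])
        assert len(merged) == len(out)  # output is a subset, order preserved


class TestDelineate:
    def test_fifty_minute_run_is_one_complete_trip(self):
        dists = [0.0, 1, 2, 3, 2, 1, 1, 0.0]
        fixes = fixes_at_distances(list(range(0, 80, 10)), dists)
        trips = delineate_trips(fixes, COLONY)
        assert len(trips) == 1
        assert trips[0].complete
        assert trips[0].n_fixes == 6

    def test_forty_minute_run_is_discarded(self):
        dists = [0.0, 1, 2, 3, 2, 1, 0.0]
        fixes = fixes_at_distances([0, 10, 20, 30, 40, 50, 60], dists)
        # away run spans fixes at 10..50 min = 40 min elapsed
        assert delineate_trips(fixes, COLONY, min_duration_min=50) == []

    def test_all_fixes_at_colony(self):
        fixes = fixes_at_distances([0, 10, 20], [0.05, 0.1, 0.15])
        assert delineate_trips(fixes, COLONY) == []

    def test_truncated_final_run_marked_incomplete(self):
        fixes = fixes_at_distances(list(range(0, 70, 10)), [0.0, 1, 2, 3, 4, 5, 6])
        trips = delineate_trips(fixes, COLONY)
        assert len(trips) == 1 and not trips[0].complete

    def test_empty_input(self):
        assert delineate_trips(fixes_at_distances([], []), COLONY) == []


def _trip_at(dists_km, complete, times=None):
    times = times if times is not None else list(range(0, 10 * len(dists_km), 10))
    fixes = fixes_at_distances(times, dists_km)
    t = Trip(
        bird_id="b1",
        colony_id="c",
        year=2018,
        t=fixes["timestamp"].to_numpy(),
        lon=fixes["lon"].to_numpy(),
        lat=fixes["lat"].to_numpy(),
        complete=complete,
    )
    t.max_range_km, t.duration_h = trip_metrics(t, COLONY)
    return t


class TestFilters:
    def area_with_land(self):
        # land strip north of the equator line
        land = PolygonRegion(
            ring=tuple(GeoPoint(*p) for p in [(-1, 0.5), (2, 0.5), (2, 1.5), (-1, 1.5), (-1, 0.5)]),
            label="land",
        )
        fjord = PolygonRegion(
            ring=tuple(GeoPoint(*p) for p in [(-2, -2), (3, -2), (3, 2), (-2, 2), (-2, -2)]),
        )
        return StudyArea(fjord=fjord, land=(land,), colonies={"c": COLONY})

    def _trip_with_land(self, n_land, n_total):
        pts = [(lon_at(5), 0.0)] * (n_total - n_land) + [(lon_at(5), 1.0)] * n_land
        fixes = make_fixes(list(range(0, 10 * n_total, 10)), pts)
        t = Trip(
            bird_id="b1", colony_id="c", year=2018,
            t=fixes["timestamp"].to_numpy(), lon=fixes["lon"].to_numpy(),
            lat=fixes["lat"].to_numpy(), complete=True,
        )
        t.max_range_km, t.duration_h = trip_metrics(t, COLONY)
        return t

    def test_majority_on_land_excluded(self):
        trips = [self._trip_with_land(6, 10)]
        assert exclude_land_trips(trips, self.area_with_land()) == []

    def test_exactly_half_on_land_retained(self):
        trips = [self._trip_with_land(5, 10)]
        kept = exclude_land_trips(trips, self.area_with_land())
        assert len(kept) == 1 and kept[0].land_fraction == 0.5

    def test_no_land_retained(self):
        trips = [self._trip_with_land(0, 10)]
        assert len(exclude_land_trips(trips, self.area_with_land())) == 1

    def test_incomplete_returned_trip_retained(self):
        trip = _trip_at([1, 50, 100, 50, 10], complete=False)
        assert filter_incomplete([trip], {"c": COLONY}) == [trip]

    def test_incomplete_far_from_colony_dropped(self):
        trip = _trip_at([1, 50, 100, 80], complete=False)
        assert filter_incomplete([trip], {"c": COLONY}) == []

    def test_exactly_25_percent_retained(self):
        trip = _trip_at([1, 50, 100, 25.0], complete=False)
        assert filter_incomplete([trip], {"c": COLONY}) == [trip]

    def test_complete_always_retained(self):
        trip = _trip_at([1, 50, 100], complete=True)
        assert filter_incomplete([trip], {"c": COLONY}) == [trip]

    def test_filter_order_independence(self, rng):
        area = self.area_with_land()
        trips = []
        for i in range(20):
            n_land = int(rng.integers(0, 8))
            t = self._trip_with_land(n_land, 10)
            t.complete = bool(rng.random() < 0.5)
            trips.append(t)
        a = filter_incomplete(exclude_land_trips(list(trips), area), {"c": COLONY})
        for t in trips:
            t.land_fraction = np.nan
        b = exclude_land_trips(filter_incomplete(list(trips), {"c": COLONY}), area)
        assert [id(t) for t in a] == [id(t) for t in b]


class TestMetrics:
    def test_max_of_distances(self):
        trip = _trip_at([1, 7, 3], complete=True)
        assert trip.max_range_km == pytest.approx(7.0, rel=1e-6)

    def test_single_fix_trip(self):
        trip = _trip_at([5.0], complete=False)
        assert trip.max_range_km == pytest.approx(5.0, rel=1e-6)
        assert trip.duration_h == 0.0

    def test_generator_apex_recovered(self, clean_study):
        from cpforage.geometry import haversine_km_vec

        truth = clean_study.ground_truth["birds"]
        dep = clean_study.deployments.iloc[0]
        colony = clean_study.area.colonies[dep["colony_id"]]
        fx = clean_study.fixes[clean_study.fixes["bird_id"] == dep["bird_id"]]
        d = haversine_km_vec(fx["lon"], fx["lat"], colony.lon, colony.lat)
        expected = max(t["range_km"] for t in truth[dep["bird_id"]]["trips"])
        assert np.max(d) == pytest.approx(expected, abs=1e-6)


class TestIndividualMaxRange:
    def _mk(self, bird, year, rng_km, dep_start, dep_id):
        t = _trip_at([rng_km], complete=True)
        t.bird_id, t.year = bird, year
        t.deployment_start = np.datetime64(dep_start)
        t.deployment_id = dep_id
        return t

    def test_max_over_trips(self):
        trips = [self._mk("b1", 2018, 5.2, "2018-07-01", "d1"),
                 self._mk("b1", 2018, 118.0, "2018-07-01", "d1")]
        out = individual_max_range(trips)
        assert out["max_range_km"].iloc[0] == pytest.approx(118.0, rel=1e-4)

    def test_first_deployment_only(self):
        trips = [self._mk("b1", 2018, 10.0, "2018-07-01", "d1"),
                 self._mk("b1", 2018, 200.0, "2018-07-20", "d2")]
        out = individual_max_range(trips, first_deployment_only=True)
        assert out["max_range_km"].iloc[0] == pytest.approx(10.0, rel=1e-4)
        out2 = individual_max_range(trips, first_deployment_only=False)
        assert out2["max_range_km"].iloc[0] == pytest.approx(200.0, rel=1e-4)

    def test_single_trip(self):
        trips = [self._mk("b2", 2016, 7.0, "2016-07-01", "d1")]
        assert individual_max_range(trips)["max_range_km"].iloc[0] == pytest.approx(7.0, rel=1e-4)


class TestRoundTrip:
    def test_clean_study_recovers_generated_trips(self, clean_study):
        trips, counts = process_deployments(
            clean_study.fixes, clean_study.deployments, clean_study.area
        )
        truth = clean_study.ground_truth["birds"]
        n_true = sum(len(b["trips"]) for b in truth.values())
        assert counts["delineated"] == n_true
        assert counts["after_incomplete_filter"] == n_true
        df = trips_to_frame(trips)
        for bird_id, b in truth.items():
            got = df[df["bird_id"] == bird_id].sort_values("start")
            assert len(got) == len(b["trips"])
            for row, tr in zip(got.itertuples(), b["trips"]):
                assert np.datetime64(tr["start"]) == row.start
                assert np.datetime64(tr["end"]) == row.end
                want = "outside" if tr["kind"] == "outside" else "inside"
                assert row.label == want
                assert row.max_range_km == pytest.approx(tr["range_km"], abs=1e-6)
        # retained trips always exceed the attendance radius
        assert (df["max_range_km"] > 0.2).all()
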