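import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrelbio.config import AnalysisConfig
from petrelbio.errors import ParameterError, SchemaError
from petrelbio.io import GpsTrack
from petrelbio.trips import (
    Trip,
    bimodality_coefficient,
    estimate_modes,
    filter_speed,
    haversine_km,
    interpolate,
    mcp_area,
    segment_trips,
    trip_metrics,
)


def _track(lats, lons, step_s=60, t0="2017-08-12"):
    ts = pd.date_range(t0, periods=len(lats), freq=f"{step_s}s", tz="UTC")
    return GpsTrack(pd.DataFrame({"timestamp": ts, "lat": lats, "lon": lons}), "t")


class TestSpeedFilter:
    def test_slow_track_unchanged(self):
        # ~0.002 deg / 60 s ~ 3.7 m/s, well under the filter
        track = _track(np.linspace(-42.0, -42.02, 11), np.full(11, 171.3))
        assert len(filter_speed(track, 25.0)) == 11

    def test_planted_fast_fix_removed(self):
        lats = np.full(6, -42.0)
        lons = np.full(6, 171.3)
        # jump of 0.02 deg longitude in 60 s: 0.02*111.195*cos(42) km ~ 1.65 km
        # => ~27.6 m/s, above the 25 m/s filter; hand-checked haversine
        lons[3] += 0.02
        d_km = haversine_km(-42.0, 171.3, -42.0, 171.32)
        assert d_km * 1000 / 60 > 25
        out = filter_speed(_track(lats, lons), 25.0)
        assert len(out) == 5
        assert not np.any(np.abs(out.fixes["lon"] - 171.32) < 1e-9)

    def test_single_fix_unchanged(self):
        track = _track([-42.0], [171.3])
        assert len(filter_speed(track, 25.0)) == 1

    def test_idempotent(self):
        lats = np.full(8, -42.0)
        lons = np.linspace(171.3, 171.34, 8)
        lons[4] += 0.05
        once = filter_speed(_track(lats, lons), 25.0)
        twice = filter_speed(once, 25.0)
        pd.testing.assert_frame_equal(once.fixes, twice.fixes)


class TestSegmentation:
    COLONY = (-42.146, 171.341)

    def _cfg(self):
        return AnalysisConfig(colony=self.COLONY, colony_radius_km=1.0)

    def test_two_excursions_two_trips(self):
        # at colony, away (5 fixes), back, away (4 fixes), back
        away = self.COLONY[0] + 0.2  # ~22 km north
        lats = [self.COLONY[0]] + [away] * 5 + [self.COLONY[0]] + [away] * 4 + [self.COLONY[0]]
        trips = segment_trips(_track(lats, [self.COLONY[1]] * len(lats)), self._cfg())
        assert len(trips) == 2
        assert trips[0].fixes["lat"].iloc[0] == pytest.approx(self.COLONY[0])
        assert trips[0].fixes["lat"].iloc[-1] == pytest.approx(self.COLONY[0])

    def test_never_leaving_radius(self):
        lats = np.full(10, self.COLONY[0])
        assert segment_trips(_track(lats, [self.COLONY[1]] * 10), self._cfg()) == []

    def test_short_runs_discarded(self):
        away = self.COLONY[0] + 0.2
        lats = [self.COLONY[0], away, away, self.COLONY[0]]  # only 2 outside fixes
        assert segment_trips(_track(lats, [self.COLONY[1]] * 4), self._cfg()) == []


class TestTripMetrics:
    def _trip(self, lats, lons, step_s=3600):
        t = _track(lats, lons, step_s=step_s)
        return Trip("t", t.fixes, t.fixes["timestamp"].iloc[0], t.fixes["timestamp"].iloc[-1])

    def test_stationary(self):
        m = trip_metrics(self._trip([-42.0, -42.0], [171.3, 171.3]), (-42.0, 171.3))
        assert m.total_distance_km == 0
        assert m.mean_speed_kmh == 0

    def test_one_degree_latitude_leg(self):
        m = trip_metrics(self._trip([0.0, 1.0], [0.0, 0.0]), (0.0, 0.0))
        assert m.total_distance_km == pytest.approx(111.19, abs=0.01)

    def test_total_equals_brute_force_leg_sum(self):
        rng = np.random.default_rng(4)
        lats = -42 + np.cumsum(rng.normal(0, 0.01, 20))
        lons = 171 + np.cumsum(rng.normal(0, 0.01, 20))
        m = trip_metrics(self._trip(lats, lons), (-42.0, 171.0))
        brute = sum(
            float(haversine_km(lats[i], lons[i], lats[i + 1], lons[i + 1]))
            for i in range(19)
        )
        assert m.total_distance_km == pytest.approx(brute, rel=1e-12)
        assert m.mean_speed_kmh == pytest.approx(m.total_distance_km / m.duration_h, rel=1e-9)

    def test_zero_duration_errors(self):
        trip = self._trip([-42.0, -42.1], [171.3, 171.3])
        trip.end = trip.start
        with pytest.raises(SchemaError):
            trip_metrics(trip, (-42.0, 171.3))

    def test_max_distance_triangle_bound(self):
        # for a colony round trip: max range <= half total distance + radius
        rng = np.random.default_rng(7)
        colony = (-42.146, 171.341)
        for _ in range(5):
            n = 30
            lats = colony[0] + np.concatenate([np.cumsum(rng.normal(0, 0.01, n)), [0]])
            lons = colony[1] + np.concatenate([np.cumsum(rng.normal(0, 0.01, n)), [0]])
            lats[0] = colony[0]
            lons[0] = colony[1]
            m = trip_metrics(self._trip(lats, lons), colony)
            assert m.max_distance_km <= m.total_distance_km / 2 + 1e-9


class TestInterpolate:
    def _trip(self, lats, lons, step_s):
        t = _track(lats, lons, step_s=step_s)
        return Trip("t", t.fixes, t.fixes["timestamp"].iloc[0], t.fixes["timestamp"].iloc[-1])

    def test_midpoint_is_mean(self):
        dense = interpolate(self._trip([-42.0, -42.1], [171.0, 171.2], 100), interval_s=50)
        assert dense["lat"].iloc[1] == pytest.approx(-42.05)
        assert dense["lon"].iloc[1] == pytest.approx(171.1)

    def test_length_formula_and_endpoints(self):
        dense = interpolate(self._trip([-42.0, -42.1, -42.2], [171.0] * 3, 90), interval_s=1)
        assert len(dense) == 180 + 1
        assert dense["lat"].iloc[0] == -42.0
        assert dense["lat"].iloc[-1] == -42.2

    def test_within_parent_bounding_box(self):
        rng = np.random.default_rng(1)
        lats = -42 + np.cumsum(rng.normal(0, 0.02, 10))
        lons = 171 + np.cumsum(rng.normal(0, 0.02, 10))
        dense = interpolate(self._trip(lats, lons, 120), interval_s=7)
        assert dense["lat"].between(lats.min() - 1e-12, lats.max() + 1e-12).all()
        assert dense["lon"].between(lons.min() - 1e-12, lons.max() + 1e-12).all()


class TestMcpArea:
    def test_equatorial_degree_square(self):
        area = mcp_area([0, 0, 1, 1], [0, 1, 0, 1])
        assert area == pytest.approx(12364, abs=5)

    def test_identical_points_error(self):
        with pytest.raises(ParameterError):
            mcp_area([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        lat = rng.uniform(-43, -42, 12)
        lon = rng.uniform(171, 172, 12)
        a1 = mcp_area(lat, lon)
        perm = rng.permutation(12)
        assert mcp_area(lat[perm], lon[perm]) == pytest.approx(a1, rel=1e-12)

    def test_monotone_in_points(self):
        lat = [-42.0, -42.5, -42.2]
        lon = [171.0, 171.4, 171.9]
        a1 = mcp_area(lat, lon)
        a2 = mcp_area(lat + [-43.0], lon + [172.5])
        assert a2 >= a1


class TestModality:
    def test_uniform_limit(self):
        rng = np.random.default_rng(0)
        bc = bimodality_coefficient(rng.uniform(0, 1, 20000))
        assert bc == pytest.approx(5 / 9, abs=0.02)

    def test_normal_limit(self):
        rng = np.random.default_rng(0)
        bc = bimodality_coefficient(rng.normal(0, 1, 20000))
        assert bc == pytest.approx(1 / 3, abs=0.02)

    def test_separated_mixture_flags_bimodal(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(24, 6, 100), rng.normal(240, 24, 100)])
        assert bimodality_coefficient(x) > 5 / 9

    def test_small_sample_edge(self):
        assert np.isfinite(bimodality_coefficient([1.0, 2.0, 3.5, 9.0]))
        with pytest.raises(ParameterError):
            bimodality_coefficient([1.0, 2.0, 3.0])

    @given(st.lists(st.floats(1, 500), min_size=5, max_size=60, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_bc_bounded(self, xs):
        bc = bimodality_coefficient(xs)
        assert 0 < bc <= 1 + 1e-9

    def test_unimodal_recovery(self):
        rng = np.random.default_rng(5)
        modes = estimate_modes(rng.normal(72, 10, 200), seed=0)
        assert len(modes) == 1
        assert modes[0][0] == pytest.approx(72, abs=3)

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(24, 6, 100), rng.normal(240, 24, 100)])
        modes = estimate_modes(x, seed=0)
        assert len(modes) == 2
        assert modes[0][0] == pytest.approx(24, abs=5)
        assert modes[1][0] == pytest.approx(240, abs=15)

    def test_constant_vector_single_mode(self):
        modes = estimate_modes(np.full(20, 42.0), seed=0)
        assert modes == [(42.0, 1.0)]
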