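import numpy as np
import pandas as pd
import pytest

from petrelbio.config import AnalysisConfig
from petrelbio.errors import ParameterError, SchemaError
from petrelbio.ethogram import (
    EthogramClassifier,
    StaticDynamic,
    body_pitch,
    classify_behaviour,
    cluster_flapping,
    decompose,
    detect_foraging,
    foraging_rate,
    heave_spectral_features,
    segment_events,
    vedba,
)
from petrelbio.io import AccelTrace


def _trace(ax, ay, az, rate=25.0):
    return AccelTrace(
        start_time=pd.Timestamp("2017-08-12T00:00:00Z"),
        rate_hz=rate,
        ax=np.asarray(ax, float),
        ay=np.asarray(ay, float),
        az=np.asarray(az, float),
    )


def _static(ax, ay, az, rate=25.0):
    return StaticDynamic(
        rate, {"ax": np.atleast_1d(np.asarray(ax, float)),
               "ay": np.atleast_1d(np.asarray(ay, float)),
               "az": np.atleast_1d(np.asarray(az, float))},
        {"ax": np.atleast_1d(np.asarray(ax, float)),
         "ay": np.atleast_1d(np.asarray(ay, float)),
         "az": np.atleast_1d(np.asarray(az, float))},
    )


class TestDecompose:
    def test_constant_signal(self):
        tr = _trace(np.full(100, 0.2), np.zeros(100), np.ones(100))
        sd = decompose(tr)
        assert np.allclose(sd.static["ax"], 0.2)
        assert np.allclose(sd.dynamic["ax"], 0.0)
        assert np.allclose(sd.static["az"], 1.0)

    def test_pure_sine_interior_static_near_zero(self):
        t = np.arange(250) / 25.0
        az = np.sin(2 * np.pi * 5 * t)  # 5 Hz: integer cycles per 1 s window
        sd = decompose(_trace(np.zeros(250), np.zeros(250), az))
        assert np.all(np.abs(sd.static["az"][25:-25]) < 0.05)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        az = rng.normal(1, 0.3, 300)
        sd = decompose(_trace(np.zeros(300), np.zeros(300), az))
        assert np.allclose(sd.static["az"] + sd.dynamic["az"], az, atol=1e-12)

    def test_short_trace_errors(self):
        with pytest.raises(SchemaError):
            decompose(_trace(np.zeros(10), np.zeros(10), np.zeros(10)))


class TestPitch:
    @pytest.mark.parametrize(
        "axayaz,expected",
        [((0.0, 0.0, 1.0), 0.0), ((1.0, 0.0, 0.0), 90.0), ((-0.5, 0.0, 0.866), -30.0)],
    )
    def test_closed_forms(self, axayaz, expected):
        ax, ay, az = axayaz
        pitch = body_pitch(_static(ax, ay, az))
        assert pitch[0] == pytest.approx(expected, abs=0.01)

    def test_all_zero_is_missing(self):
        assert np.isnan(body_pitch(_static(0.0, 0.0, 0.0))[0])


class TestVedba:
    def test_zero_and_345(self):
        sd = _static([0.0, 0.3], [0.0, 0.4], [0.0, 0.0])
        v = vedba(sd)
        assert v[0] == 0.0
        assert v[1] == pytest.approx(0.5)


class TestSpectralFeatures:
    def test_wingbeat_sine(self):
        t = np.arange(25 * 30) / 25.0
        az = 1.0 * np.sin(2 * np.pi * t / 0.3)  # 0.3 s cycle
        f = heave_spectral_features(az, 25.0)
        assert np.allclose(f["dominant_cycle_s"], 0.3, atol=0.05)
        assert np.all(f["cycle_amplitude_g"] > 0.7)

    def test_noise_floor(self):
        rng = np.random.default_rng(0)
        f = heave_spectral_features(rng.normal(0, 0.01, 25 * 60), 25.0)
        assert np.all(f["cycle_amplitude_g"] < 0.05)

    def test_constant_signal_amplitude_zero(self):
        f = heave_spectral_features(np.full(250, 0.8), 25.0)
        assert np.allclose(f["cycle_amplitude_g"], 0.0, atol=1e-12)

    def test_low_rate_rejected(self):
        with pytest.raises(ParameterError):
            heave_spectral_features(np.zeros(100), 5.0)


class TestClusterFlapping:
    def _features(self, n=50):
        rng = np.random.default_rng(0)
        flap = pd.DataFrame(
            {"dominant_cycle_s": rng.normal(0.3, 0.02, n),
             "cycle_amplitude_g": rng.normal(1.0, 0.05, n)}
        )
        quiet = pd.DataFrame(
            {"dominant_cycle_s": rng.normal(0.3, 0.02, n),
             "cycle_amplitude_g": rng.normal(0.05, 0.01, n)}
        )
        return pd.concat([flap, quiet], ignore_index=True)

    def test_separable_clusters_fully_recovered(self):
        f = self._features()
        flags = cluster_flapping(f, seed=0)
        assert flags[:50].all() and not flags[50:].any()

    def test_identical_features_warns_no_flapping(self):
        f = pd.DataFrame({"dominant_cycle_s": [0.3] * 10, "cycle_amplitude_g": [0.1] * 10})
        with pytest.warns(UserWarning):
            flags = cluster_flapping(f, seed=0)
        assert not flags.any()

    def test_order_invariance(self):
        f = self._features()
        flags = cluster_flapping(f, seed=0)
        perm = np.random.default_rng(1).permutation(len(f))
        flags_p = cluster_flapping(f.iloc[perm].reset_index(drop=True), seed=0)
        assert np.array_equal(flags[perm], flags_p)


class TestClassify:
    def test_all_flapping(self):
        cfg = AnalysisConfig()
        labels = classify_behaviour(
            np.ones(20, bool), np.full(20, 0.3), np.full(20, 1.0), cfg
        )
        assert (labels == "flap").all()

    def test_water_band_separates_raft_from_glide(self):
        cfg = AnalysisConfig()
        flags = np.zeros(12, bool)
        sd = np.full(12, 0.03)
        static = np.array([1.0] * 6 + [0.85] * 6)  # air vs water static heave
        labels = classify_behaviour(flags, sd, static, cfg)
        assert (labels[:6] == "glide").all()
        assert (labels[6:] == "raft").all()

    def test_smoothing_removes_single_second_flicker(self):
        cfg = AnalysisConfig()
        flags = np.zeros(11, bool)
        flags[5] = True  # lone flap second inside a raft bout
        labels = classify_behaviour(flags, np.full(11, 0.03), np.full(11, 0.85), cfg)
        assert (labels == "raft").all()


class TestForagingRules:
    @pytest.mark.parametrize(
        "label,pitch,expected",
        [("raft", -30.0, True), ("flap", -30.0, False), ("raft", -20.0, False)],
    )
    def test_pitch_rule(self, label, pitch, expected):
        out = detect_foraging(np.array([label]), np.array([pitch]), AnalysisConfig())
        assert bool(out[0]) is expected

    def test_dive_seconds_count_as_foraging(self):
        out = detect_foraging(
            np.array(["raft"]), np.array([0.0]), AnalysisConfig(),
            dive_seconds=np.array([True]),
        )
        assert out[0]


class TestEvents:
    def _flags(self, seconds, n=30):
        f = np.zeros(n, bool)
        f[list(seconds)] = True
        return f

    def test_contiguous_block_is_one_event(self):
        ev = segment_events(self._flags({10, 11, 12}))
        assert len(ev) == 1
        assert ev[0].duration_s == 3

    def test_gap_above_threshold_splits(self):
        assert len(segment_events(self._flags({10, 17}), gap_s=5)) == 2

    def test_gap_at_threshold_merges(self):
        ev = segment_events(self._flags({10, 15}), gap_s=5)
        assert len(ev) == 1
        assert ev[0].start_s == 10 and ev[0].end_s == 15

    def test_no_foraging_empty(self):
        assert segment_events(np.zeros(10, bool)) == []

    def test_dive_event_typed_and_located(self):
        track = pd.DataFrame(
            {"timestamp": pd.date_range("2017-08-12", periods=30, freq="s", tz="UTC"),
             "lat": np.linspace(-42, -42.29, 30), "lon": 171.3}
        )
        dive = np.zeros(30, bool)
        dive[11] = True
        ev = segment_events(self._flags({10, 11, 12}), dive_seconds=dive, track=track)
        assert ev[0].type == "dive"
        assert ev[0].lat == pytest.approx(-42.1, abs=0.01)


class TestForagingRate:
    def test_simple_rate(self):
        ev = segment_events(np.ones(10, bool))
        out = foraging_rate(ev, 5.0)
        assert out["events_per_h"] == pytest.approx(1 / 5)

    def test_reference_scale(self):
        # 130 events on a 48 h, 780 km trip: 2.708 events/h, 6 km per event
        class E:
            pass

        events = [E() for _ in range(130)]
        out = foraging_rate(events, 48.0, 780.0)
        assert out["events_per_h"] == pytest.approx(2.708, abs=0.001)
        assert out["km_per_event"] == pytest.approx(6.0)

    def test_zero_events_and_zero_duration(self):
        out = foraging_rate([], 5.0, 100.0)
        assert out["events_per_h"] == 0
        assert np.isnan(out["km_per_event"])
        with pytest.raises(ParameterError):
            foraging_rate([], 0.0)


class TestEstimatorInterface:
    def test_fit_predict_and_params(self):
        rng = np.random.default_rng(0)
        n_sec = 60
        t = np.arange(n_sec * 25) / 25.0
        flap = np.repeat(np.arange(n_sec) < 30, 25)
        az = np.where(flap, 1.0 + 0.4 * np.sin(2 * np.pi * t / 0.3), 0.85)
        az = az + rng.normal(0, 0.03, len(t))
        tr = _trace(rng.normal(0, 0.02, len(t)), rng.normal(0, 0.02, len(t)), az)
        clf = EthogramClassifier(AnalysisConfig(), seed=0)
        assert clf.get_params()["seed"] == 0
        labels = clf.fit(tr).predict(tr)
        truth = np.where(np.arange(n_sec) < 30, "flap", "raft")
        # short traces give the clusterer few seconds; allow a little slack
        assert np.mean(labels == truth) >= 0.95

    def test_unfitted_predict_errors(self):
        with pytest.raises(ParameterError):
            EthogramClassifier().predict(None)
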