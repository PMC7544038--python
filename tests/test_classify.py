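import numpy as np
import pytest

from wheezekit import (
    FileDecision,
    Label,
    RuleThresholds,
    TrackFeatures,
    WheezeType,
    classify_track,
    compute_features,
    decide_file,
    fit_tree,
)
from wheezekit.detection import CandidateTrack, PeakPoint

from conftest import BIN_WIDTH, SAMPLE_RATE

HOP_S = 128 / SAMPLE_RATE


def features(**overrides) -> TrackFeatures:
    base = dict(
        duration_ms=300.0, mean_freq_hz=400.0, freq_cv=0.02,
        mean_margin_db=15.0, env_minus_lung_db=-12.0, gap_fraction=0.0,
        level_sd_db=2.0, peak_crowding=0.0,
    )
    base.update(overrides)
    return TrackFeatures(**base)


def make_track(frames, bin_=200, level=-20.0, margin=10.0):
    pts = tuple(
        PeakPoint(frame=t, bin=bin_, freq_hz=bin_ * BIN_WIDTH,
                  level_db=level, margin_db=margin)
        for t in frames
    )
    return CandidateTrack(points=pts, hop_seconds=HOP_S)


class TestComputeFeatures:
    def make_series_pair(self, lung_level, env_level):
        from wheezekit.spectral import SpectralConfig, SpectralSeries

        def series(level):
            return SpectralSeries(
                power_db=np.full((30, 2049), -60.0),
                frame_times_s=np.arange(30) * HOP_S,
                bin_freqs_hz=np.arange(2049) * BIN_WIDTH,
                sample_rate=SAMPLE_RATE,
                config=SpectralConfig(),
            )

        lung, env = series(lung_level), series(env_level)
        lung.power_db[:, 200] = lung_level
        env.power_db[:, 200] = env_level
        return lung, env

    def test_env_minus_lung_for_lung_only_track(self):
        lung, env = self.make_series_pair(-20.0, -60.0)
        f = compute_features(make_track(range(10)), lung, env)
        assert f.env_minus_lung_db == pytest.approx(-40.0)

    def test_identical_channels_give_zero_difference(self):
        lung, env = self.make_series_pair(-20.0, -20.0)
        f = compute_features(make_track(range(10)), lung, env)
        assert f.env_minus_lung_db == pytest.approx(0.0)

    def test_misaligned_channels_rejected(self):
        from wheezekit.spectral import SpectralConfig, SpectralSeries

        lung, env = self.make_series_pair(-20.0, -20.0)
        short_env = SpectralSeries(
            power_db=env.power_db[:10], frame_times_s=env.frame_times_s[:10],
            bin_freqs_hz=env.bin_freqs_hz, sample_rate=SAMPLE_RATE,
            config=SpectralConfig(),
        )
        with pytest.raises(ValueError):
            compute_features(make_track(range(5)), lung, short_env)

    def test_crying_fixture_has_higher_freq_cv_than_wheeze(self):
        import warnings

        from wheezekit import SceneEvent, SceneSpec, analyze_recording, render_scene

        def max_strong_cv(kind, freq):
            spec = SceneSpec(duration_s=4.0, seed=33, events=(
                SceneEvent(kind=kind, onset_s=1.0, duration_ms=1200.0,
                           freq_hz=freq, snr_db=25.0),
            ))
            rec, _ = render_scene(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = analyze_recording(rec)
            return max(f.freq_cv for tr, f in zip(res.tracks, res.features)
                       if f.mean_margin_db > 6.0)

        assert max_strong_cv("crying", 450.0) > max_strong_cv("wheeze", 450.0)

    def test_crowding_counts_comparable_neighbors_only(self):
        from wheezekit.spectral import SpectralConfig, SpectralSeries

        lung = SpectralSeries(
            power_db=np.full((10, 2049), -60.0),
            frame_times_s=np.arange(10) * HOP_S,
            bin_freqs_hz=np.arange(2049) * BIN_WIDTH,
            sample_rate=SAMPLE_RATE, config=SpectralConfig(),
        )
        track = make_track(range(10), bin_=200, level=-20.0)
        nearby_similar = PeakPoint(frame=0, bin=210, freq_hz=210 * BIN_WIDTH,
                                   level_db=-25.0, margin_db=5.0)
        nearby_faint = PeakPoint(frame=0, bin=190, freq_hz=190 * BIN_WIDTH,
                                 level_db=-60.0, margin_db=0.1)
        far_similar = PeakPoint(frame=0, bin=400, freq_hz=400 * BIN_WIDTH,
                                level_db=-20.0, margin_db=40.0)
        frame_peaks = {0: [track.points[0], nearby_similar, nearby_faint, far_similar]}
        f = compute_features(track, lung, lung, frame_peaks=frame_peaks)
        # one qualifying neighbor in 1 of 10 core frames
        assert f.peak_crowding == pytest.approx(0.1)


class TestDefaultRules:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            (dict(), Label.WHEEZE),
            (dict(duration_ms=80.0), Label.HEARTBEAT),
            (dict(duration_ms=100.0), Label.HEARTBEAT),          # boundary: <= 100
            (dict(env_minus_lung_db=6.0), Label.AMBIENT_VOICE),
            (dict(env_minus_lung_db=0.0), Label.AMBIENT_VOICE),  # boundary: >= 0
            (dict(freq_cv=0.2), Label.CRYING),
            (dict(gap_fraction=0.4), Label.CRYING),
            (dict(peak_crowding=3.0), Label.CRYING),
            (dict(mean_freq_hz=60.0), Label.OTHER_NOISE),
            (dict(mean_freq_hz=5200.0), Label.OTHER_NOISE),
            (dict(mean_margin_db=2.0), Label.OTHER_NOISE),       # faint floor excursion
        ],
    )
    def test_rule_outcomes(self, overrides, expected):
        result = classify_track(features(**overrides))
        assert result.label == expected
        assert result.rule_path  # audit trail always present

    def test_rule_order_heartbeat_before_voice(self):
        # short AND env-dominant: the duration rule fires first
        result = classify_track(features(duration_ms=50.0, env_minus_lung_db=10.0))
        assert result.label == Label.HEARTBEAT

    def test_rules_invariant_to_global_gain(self):
        # all features are relative or temporal; a gain change leaves them fixed
        f = features()
        assert classify_track(f) == classify_track(f)

    def test_custom_thresholds(self):
        th = RuleThresholds(min_intensity_db=3.0)
        assert classify_track(features(mean_margin_db=4.0), th).label == Label.WHEEZE


class TestDecideFile:
    def wheeze_label(self):
        return classify_track(features())

    def noise_label(self):
        return classify_track(features(mean_margin_db=1.0))

    def test_no_tracks_is_no_wheeze(self):
        d = decide_file([], [], BIN_WIDTH)
        assert d.verdict == "no_wheeze"
        assert d.wheeze_type == WheezeType.NONE

    def test_single_wheeze_is_monophonic(self):
        tr = make_track(range(10))
        d = decide_file([self.wheeze_label()], [tr], BIN_WIDTH)
        assert d.verdict == "wheeze"
        assert d.wheeze_type == WheezeType.MONOPHONIC

    def test_overlapping_distinct_frequencies_are_polyphonic(self):
        t1 = make_track(range(10), bin_=149)
        t2 = make_track(range(10), bin_=297)
        d = decide_file([self.wheeze_label()] * 2, [t1, t2], BIN_WIDTH)
        assert d.wheeze_type == WheezeType.POLYPHONIC

    def test_sequential_wheezes_stay_monophonic(self):
        t1 = make_track(range(10), bin_=149)
        t2 = make_track(range(20, 30), bin_=297)
        d = decide_file([self.wheeze_label()] * 2, [t1, t2], BIN_WIDTH)
        assert d.wheeze_type == WheezeType.MONOPHONIC

    def test_same_frequency_overlap_stays_monophonic(self):
        t1 = make_track(range(10), bin_=149)
        t2 = make_track(range(5, 15), bin_=149)
        d = decide_file([self.wheeze_label()] * 2, [t1, t2], BIN_WIDTH)
        assert d.wheeze_type == WheezeType.MONOPHONIC

    def test_monotone_in_wheeze_tracks(self):
        """Adding a wheeze-labeled track never flips wheeze -> no_wheeze."""
        tracks = [make_track(range(10), bin_=200)]
        labels = [self.noise_label()]
        assert decide_file(labels, tracks, BIN_WIDTH).verdict == "no_wheeze"
        tracks.append(make_track(range(30, 40), bin_=300))
        labels.append(self.wheeze_label())
        assert decide_file(labels, tracks, BIN_WIDTH).verdict == "wheeze"
        tracks.append(make_track(range(50, 60), bin_=400))
        labels.append(self.wheeze_label())
        assert decide_file(labels, tracks, BIN_WIDTH).verdict == "wheeze"

    def test_invariant_enforced_on_construction(self):
        with pytest.raises(ValueError):
            FileDecision("wheeze", (), WheezeType.NONE)
        with pytest.raises(ValueError):
            FileDecision("no_wheeze", (), WheezeType.MONOPHONIC)


class TestFitTree:
    def corpus(self, rng, n=60):
        feats, labels = [], []
        for _ in range(n):
            is_voice = rng.random() < 0.5
            feats.append(features(
                env_minus_lung_db=rng.uniform(3, 15) if is_voice else rng.uniform(-15, -3),
                duration_ms=rng.uniform(150, 1000),
                mean_freq_hz=rng.uniform(200, 1200),
                freq_cv=rng.uniform(0, 0.1),
                mean_margin_db=rng.uniform(8, 40),
            ))
            labels.append(Label.AMBIENT_VOICE if is_voice else Label.WHEEZE)
        return feats, labels

    def test_perfectly_separating_feature_is_the_root_split(self):
        rng = np.random.default_rng(4)
        feats, labels = self.corpus(rng)
        tree = fit_tree(feats, labels, seed=0)
        assert tree.root_feature == "env_minus_lung_db"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        feats, labels = self.corpus(rng)
        t1 = fit_tree(feats, labels, seed=3)
        t2 = fit_tree(feats, labels, seed=3)
        assert t1.feature == t2.feature and t1.threshold == t2.threshold

    def test_single_class_rejected(self):
        feats = [features() for _ in range(5)]
        with pytest.raises(ValueError):
            fit_tree(feats, [Label.WHEEZE] * 5, seed=0)

    def test_conflicting_labels_resolve_to_majority(self):
        feats = [features()] * 4
        labels = [Label.WHEEZE, Label.WHEEZE, Label.WHEEZE, Label.CRYING]
        tree = fit_tree(feats, labels, seed=0)
        assert tree.classify(features()).label == Label.WHEEZE

    def test_classify_exposes_rule_path(self):
        rng = np.random.default_rng(4)
        feats, labels = self.corpus(rng)
        tree = fit_tree(feats, labels, seed=0)
        result = tree.classify(features(env_minus_lung_db=8.0))
        assert result.label == Label.AMBIENT_VOICE
        assert any("env_minus_lung_db" in step for step in result.rule_path)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        feats, labels = self.corpus(rng)
        tree = fit_tree(feats, labels, seed=0)
        path = tmp_path / "tree.json"
        tree.to_json(path)
        from wheezekit import FittedRuleTree

        back = FittedRuleTree.from_json(path)
        for f in feats[:10]:
            assert back.classify(f).label == tree.classify(f).label


class TestTrackFeaturesInvariants:
    @pytest.mark.parametrize(
        "overrides",
        [dict(duration_ms=0.0), dict(freq_cv=-0.1), dict(gap_fraction=1.5)],
    )
    def test_invalid_features_rejected(self, overrides):
        with pytest.raises(ValueError):
            features(**overrides)
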