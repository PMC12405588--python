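import numpy as np
import pandas as pd
import pytest

from larvaction import kinematics as kin
from larvaction.synth import GenerationConfig, gen_track


def _static_spine(n=60, spacing=0.4):
    spine = np.zeros((n, 11, 2))
    for i in range(11):
        spine[:, i, 0] = -spacing * i
    return spine


class TestPreprocess:
    def test_static_larva_survives_resampling_unchanged(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.08, 0.12, 60))
        track = kin.SpineTrack("a", t, _static_spine(60))
        out = kin.preprocess(track)
        assert out.regular
        assert np.allclose(np.diff(out.times), kin.DT)
        np.testing.assert_allclose(out.midline, _static_spine(out.n_samples), atol=1e-9)

    def test_filter_response_passband_and_stopband(self):
        # sinusoidal midline-length modulation at 1.4 Hz (passband) and
        # 5 Hz jitter (stopband) through the 2 Hz zero-phase filter
        t = np.arange(0, 30, 0.05)
        for freq, check in ((1.4, lambda g: g > 0.75), (5.0, lambda g: g < 0.5)):
            spine = np.zeros((t.size, 11, 2))
            stretch = 1 + 0.1 * np.sin(2 * np.pi * freq * t)
            for i in range(11):
                spine[:, i, 0] = -0.4 * i * stretch
            out = kin.preprocess(kin.SpineTrack("a", t, spine))
            lengths = np.linalg.norm(np.diff(out.midline, axis=1), axis=2).sum(axis=1)
            interior = slice(20, -20)
            gain = (lengths[interior].max() - lengths[interior].min()) / (0.1 * 4.0 * 2)
            assert check(gain), f"gain {gain:.2f} at {freq} Hz"

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError, match="span"):
            kin.preprocess(kin.SpineTrack("a", [0.0, 0.5], _static_spine(2)))


class TestBodyLengthAndSpeeds:
    def test_collinear_spacing_gives_exact_length(self, static_track):
        assert kin.body_length(static_track) == pytest.approx(4.0)

    def test_median_of_alternating_lengths(self):
        n = 40
        spine = _static_spine(n)
        stretch = np.where(np.arange(n) % 2 == 0, 3.8 / 4.0, 4.2 / 4.0)
        spine[:, :, 0] *= stretch[:, None]
        track = kin.SpineTrack("a", np.arange(n) * kin.DT, spine, regular=True)
        assert kin.body_length(track) == pytest.approx(4.0)

    def test_rigid_translation_speed_is_quarter_bl(self, straight_track):
        sp = kin.scaled_speeds(straight_track)
        inner = sp.iloc[2:-2]
        for col in sp.columns:
            np.testing.assert_allclose(inner[col], 0.25, rtol=1e-6)

    def test_static_track_has_zero_speeds(self, static_track):
        assert np.allclose(kin.scaled_speeds(static_track), 0.0)

    def test_head_sweep_moves_head_much_faster_than_tail(self):
        cfg = GenerationConfig(seed=7, duration=12.0, stimulus_onset=10.0,
                               coord_noise_sd=0.001)
        tr, _ = gen_track(cfg, [("stop", 0, 2), ("head_cast", 2, 10), ("stop", 10, 12)])
        p = kin.preprocess(tr)
        sp = kin.scaled_speeds(p)
        m = (p.times >= 3) & (p.times < 9)
        assert sp["speed_head"][m].mean() / (sp["speed_tail"][m].mean() + 1e-9) > 3


class TestNematicOrder:
    def test_straight_spine_is_one(self, static_track):
        np.testing.assert_allclose(kin.nematic_order(static_track), 1.0, atol=1e-12)

    def test_perpendicular_segments_reach_lower_bound(self):
        n = 5
        spine = np.zeros((n, 11, 2))
        for i in range(11):
            spine[:, i, 0] = i * 1e-8
            spine[:, i, 1] = i % 2
        track = kin.SpineTrack("zig", np.arange(n) * kin.DT, spine, regular=True)
        np.testing.assert_allclose(kin.nematic_order(track), -0.5, atol=1e-6)

    def test_semicircular_arc_matches_direct_summation(self):
        # brute-force S over the 10 segments of a constructed semicircle
        ang = np.linspace(0, np.pi, 11)
        pts = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        spine = np.repeat(pts[None], 3, axis=0)
        track = kin.SpineTrack("arc", np.arange(3) * kin.DT, spine, regular=True)
        seg = pts[:-1] - pts[1:]
        axis = pts[0] - pts[10]
        axis = axis / np.linalg.norm(axis)
        cos2 = [(s @ axis / np.linalg.norm(s)) ** 2 for s in seg]
        expected = 0.5 * (3 * np.mean(cos2) - 1)
        np.testing.assert_allclose(kin.nematic_order(track), expected, atol=1e-12)


class TestShapeFactor:
    def test_straight_spine_is_one(self, static_track):
        np.testing.assert_allclose(kin.shape_factor(static_track), 1.0, atol=1e-9)

    def test_circular_points_are_isotropic(self):
        ang = np.linspace(0, 2 * np.pi, 11, endpoint=False)
        pts = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        track = kin.SpineTrack("c", np.arange(9) * kin.DT,
                               np.repeat(pts[None], 9, axis=0), regular=True)
        np.testing.assert_allclose(kin.shape_factor(track), 0.0, atol=1e-12)

    def test_two_to_one_ellipse_gives_point_six(self):
        ang = np.linspace(0, 2 * np.pi, 11, endpoint=False)
        pts = np.stack([2 * np.cos(ang), np.sin(ang)], axis=-1)
        track = kin.SpineTrack("e", np.arange(9) * kin.DT,
                               np.repeat(pts[None], 9, axis=0), regular=True)
        np.testing.assert_allclose(kin.shape_factor(track), 0.6, atol=1e-12)


class TestAxisRatio:
    def test_symmetric_straight_larva_is_one(self, static_track):
        np.testing.assert_allclose(kin.axis_ratio(static_track), 1.0, atol=1e-12)

    def test_hunch_contraction_pulls_head_in(self):
        cfg = GenerationConfig(seed=5, duration=20.0, stimulus_onset=10.0,
                               coord_noise_sd=0.0)
        tr, _ = gen_track(cfg, [("crawl", 0, 10), ("hunch", 10, 11), ("crawl", 11, 20)])
        p = kin.preprocess(tr)
        ar = kin.axis_ratio(p)
        m = (p.times >= 10.2) & (p.times < 10.8)
        assert np.nanmin(ar[m]) < 0.9

    def test_tail_on_centroid_is_flagged(self):
        # five points at +1, five at -1, tail at the origin: G = tail exactly
        spine = np.zeros((3, 11, 2))
        spine[:, 0:5, 0] = 1.0
        spine[:, 5:10, 0] = -1.0
        track = kin.SpineTrack("d", np.arange(3) * kin.DT, spine, regular=True)
        assert np.isnan(kin.axis_ratio(track)).all()


class TestVelocityAlignment:
    @pytest.mark.parametrize("direction,expected_cos", [
        ((1.0, 0.0), 1.0),        # along the head-outward segment
        ((0.0, 1.0), 0.0),        # perpendicular
        ((np.sqrt(0.5), np.sqrt(0.5)), np.sqrt(0.5)),  # 45 degrees
    ])
    def test_head_velocity_projection_geometry(self, direction, expected_cos):
        n = 30
        spine = _static_spine(n)
        v = np.array(direction)  # mm/s
        spine += (np.arange(n) * kin.DT)[:, None, None] * v[None, None, :]
        track = kin.SpineTrack("a", np.arange(n) * kin.DT, spine, regular=True)
        va = kin.velocity_alignment(track)
        inner = slice(2, -2)
        np.testing.assert_allclose(va["cos_head"].iloc[inner], expected_cos, atol=1e-9)
        np.testing.assert_allclose(
            va["proj_head"].iloc[inner], expected_cos * 1.0 / 4.0, atol=1e-9
        )

    def test_zero_velocity_cosine_flagged(self, static_track):
        va = kin.velocity_alignment(static_track)
        assert va["cos_head"].isna().all()


class TestFeatureWindow:
    def test_constant_features_give_identical_blocks(self):
        df = pd.DataFrame(np.ones((20, 3)))
        W = kin.feature_window(df)
        assert W.shape == (20, 21)
        assert np.allclose(W, 1.0)

    def test_window_length_is_seven_times_features(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 12)))
        assert kin.feature_window(df).shape == (30, 84)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="short"):
            kin.feature_window(pd.DataFrame(np.ones((6, 2))))


class TestPathMetrics:
    def test_straight_run(self, straight_track):
        pm = kin.path_metrics(straight_track)
        assert pm["pathlength"].iloc[-1] == pytest.approx(30.0, rel=1e-6)
        assert pm["dispersal"].iloc[-1] == pytest.approx(30.0, rel=1e-6)

    def test_out_and_back_ends_at_zero_dispersal(self):
        n = 101
        x = np.concatenate([np.linspace(0, 5, 51), np.linspace(5, 0, 51)[1:]])
        spine = _static_spine(n)
        spine[:, :, 0] += x[:, None]
        track = kin.SpineTrack("a", np.arange(n) * kin.DT, spine, regular=True)
        pm = kin.path_metrics(track)
        assert pm["dispersal"].iloc[-1] == pytest.approx(0.0, abs=1e-9)
        assert pm["pathlength"].iloc[-1] == pytest.approx(10.0, rel=1e-9)

    def test_dispersal_never_exceeds_pathlength_on_random_walks(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 200
            steps = rng.normal(0, 0.05, size=(n, 2)).cumsum(axis=0)
            spine = _static_spine(n) + steps[:, None, :]
            track = kin.SpineTrack("w", np.arange(n) * kin.DT, spine, regular=True)
            pm = kin.path_metrics(track)
            assert np.all(pm["dispersal"] <= pm["pathlength"] + 1e-12)


class TestStraightnessIndex:
    def test_straight_run_is_one(self, straight_track):
        si = kin.straightness_index(straight_track)
        np.testing.assert_allclose(si, 1.0, atol=1e-9)

    def test_stationary_track_is_zero(self):
        n = 250
        track = kin.SpineTrack("s", np.arange(n) * kin.DT, _static_spine(n),
                               regular=True)
        assert np.all(kin.straightness_index(track) == 0.0)

    def test_short_span_rejected(self, static_track):
        with pytest.raises(ValueError, match="window"):
            kin.straightness_index(static_track, window=20.0)


class TestCrawlFrequencyAndStrides:
    def test_recovers_generator_frequency(self, crawl_track):
        track, _ = crawl_track
        f, cycle = kin.crawl_frequency(track)
        assert f == pytest.approx(1.4, abs=0.15)
        assert cycle == pytest.approx(1 / f)

    def test_noisy_one_hz_recovered(self):
        cfg = GenerationConfig(seed=8, duration=20.0, crawl_freq=1.0,
                               coord_noise_sd=0.02)
        tr, _ = gen_track(cfg, [("crawl", 0.0, 20.0)])
        f, _ = kin.crawl_frequency(kin.preprocess(tr))
        assert f == pytest.approx(1.0, abs=0.1)

    def test_constant_speed_has_no_dominant_frequency(self, straight_track):
        with pytest.raises(ValueError, match="flat|dominant"):
            kin.crawl_frequency(straight_track)

    def test_stride_count_matches_cycles(self, crawl_track):
        track, _ = crawl_track
        assert len(kin.detect_strides(track)) in (13, 14, 15)

    def test_subthreshold_amplitude_yields_no_strides(self):
        cfg = GenerationConfig(seed=3, duration=10.0, crawl_speed_amp=0.1,
                               coord_noise_sd=0.0)
        tr, _ = gen_track(cfg, [("crawl", 0.0, 10.0)])
        assert kin.detect_strides(kin.preprocess(tr)) == []

    def test_epoch_duration_rule_rejects_long_epochs(self):
        # min-to-min epoch lasting 2 cycles must be discarded
        t = np.arange(0, 12, kin.DT)
        speed_template = 0.5 * (1 - np.cos(2 * np.pi * t / 2.0))  # 0.5 Hz epochs
        spine = _static_spine(t.size)
        x = np.cumsum(speed_template * 4.0 * kin.DT)
        spine[:, :, 0] += x[:, None]
        track = kin.SpineTrack("slow", t, spine, regular=True)
        strides = kin.detect_strides(track, annotation_freq=(1.0, 1.0))
        assert strides == []


class TestRunsAndPauses:
    def test_continuous_crawl_is_one_run_no_pauses(self, crawl_track):
        track, _ = crawl_track
        ann = kin.annotate_runs_pauses(track)
        assert len(ann.runs) == 1
        assert ann.pauses == []

    def test_crawl_freeze_crawl_script_recovered(self):
        cfg = GenerationConfig(seed=9, duration=30.0, coord_noise_sd=0.002)
        tr, _ = gen_track(cfg, [("crawl", 0, 10), ("stop", 10, 18), ("crawl", 18, 30)])
        ann = kin.annotate_runs_pauses(kin.preprocess(tr))
        assert len(ann.runs) == 2
        assert len(ann.pauses) == 1
        a, b = ann.pauses[0]
        assert a == pytest.approx(10.0, abs=0.3)
        assert b == pytest.approx(18.0, abs=0.3)

    def test_no_stride_overlaps_a_pause(self, crawl_track):
        track, _ = crawl_track
        ann = kin.annotate_runs_pauses(track)
        for sa, sb in ann.strides:
            for pa, pb in ann.pauses:
                assert sb < pa or sa > pb


class TestInvariances:
    def test_rigid_rotation_preserves_all_features(self, crawl_track):
        track, _ = crawl_track
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = kin.SpineTrack(
            track.larva_id, track.times, track.midline @ R.T, regular=True
        )
        f0 = kin.compute_features(track)
        f1 = kin.compute_features(rotated)
        for col in f0.columns:
            np.testing.assert_allclose(
                f0[col].to_numpy(), f1[col].to_numpy(), atol=1e-8, err_msg=col
            )

    def test_rigid_translation_preserves_shape_features(self, crawl_track):
        track, _ = crawl_track
        shifted = kin.SpineTrack(
            track.larva_id, track.times, track.midline + np.array([3.0, -2.0]),
            regular=True,
        )
        np.testing.assert_allclose(kin.nematic_order(track), kin.nematic_order(shifted))
        np.testing.assert_allclose(kin.shape_factor(track), kin.shape_factor(shifted))
        np.testing.assert_allclose(kin.axis_ratio(track), kin.axis_ratio(shifted))

    def test_pipeline_is_deterministic(self, crawl_track):
        track, _ = crawl_track
        f0 = kin.compute_features(track)
        f1 = kin.compute_features(track)
        pd.testing.assert_frame_equal(f0, f1)
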