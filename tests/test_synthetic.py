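"""Synthetic-data generator: determinism, label soundness, distributional fidelity."""

import numpy as np
import pytest

from somnoscope.synthetic import (
    EYE_CLOSURE,
    YAWN,
    BehaviorScript,
    DatasetConfig,
    RenderParams,
    StreamSimParams,
    generate_behavior_script,
    make_dataset,
    render_clip,
    simulate_symptom_streams,
)


class TestBehaviorScript:
    def test_zero_rates_yield_empty_script(self):
        script = generate_behavior_script(64, {EYE_CLOSURE: 0.0, YAWN: 0.0}, seed=3)
        assert script.events == []
        assert np.all(script.frame_labels() == 0)

    def test_same_seed_same_script(self):
        kwargs = dict(
            total_frames=500, episode_rates={EYE_CLOSURE: 0.01, YAWN: 0.005}, seed=11
        )
        a = generate_behavior_script(**kwargs)
        b = generate_behavior_script(**kwargs)
        assert a.events == b.events

    def test_rejects_tiny_and_negative_inputs(self):
        with pytest.raises(ValueError):
            generate_behavior_script(8, {EYE_CLOSURE: 0.01}, seed=0)
        with pytest.raises(ValueError):
            generate_behavior_script(64, {EYE_CLOSURE: -0.1}, seed=0)

    def test_event_counts_match_analytic_rates(self):
        """Monte-Carlo over seeds: mean counts within 3 standard errors of
        rate * total_frames (20 eye, 10 yawn at these settings)."""
        rates = {EYE_CLOSURE: 0.02, YAWN: 0.01}
        # short durations keep occupancy low enough that no draw is dropped
        durations = {EYE_CLOSURE: (4, 10), YAWN: (4, 10)}
        counts = np.array(
            [
                [
                    sum(1 for *_, t in generate_behavior_script(
                        1000, rates, seed=s, durations=durations
                    ).events if t == etype)
                    for etype in (EYE_CLOSURE, YAWN)
                ]
                for s in range(100)
            ]
        )
        for j, expected in enumerate((20.0, 10.0)):
            se = np.sqrt(expected / 100)  # Poisson SE of the mean over 100 seeds
            assert abs(counts[:, j].mean() - expected) < 3 * se

    def test_no_overlap_within_event_type(self, random_script):
        for etype in (EYE_CLOSURE, YAWN):
            spans = sorted(
                (o, o + d) for o, d, t in random_script.events if t == etype
            )
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                assert e0 <= s1

    def test_invalid_events_rejected(self):
        with pytest.raises(ValueError):
            BehaviorScript(events=[(90, 20, EYE_CLOSURE)], total_frames=96)
        with pytest.raises(ValueError):
            BehaviorScript(
                events=[(0, 10, YAWN), (5, 10, YAWN)], total_frames=96
            )

    def test_window_labels_agree_with_frame_counting_oracle(self, random_script):
        """Label soundness: clip labels recomputed by an independent
        per-frame tally agree exactly."""
        labels = np.zeros((random_script.total_frames, 2), dtype=int)
        for onset, dur, etype in random_script.events:  # independent tally
            labels[onset : onset + dur, 0 if etype == EYE_CLOSURE else 1] = 1
        for start in range(0, random_script.total_frames - 16, 16):
            le, lm = random_script.window_labels(start, start + 16, 0.5)
            assert le == int(labels[start : start + 16, 0].mean() >= 0.5)
            assert lm == int(labels[start : start + 16, 1].mean() >= 0.5)
            state = random_script.window_state(start, start + 16, 0.5)
            assert state == max(le, lm)


class TestRenderClip:
    def test_window_inside_yawn_is_mouth_only(self, small_script, render_params):
        sample = render_clip(small_script, (55, 71), render_params)
        assert (sample.label_eye, sample.label_mouth) == (0, 1)

    def test_determinism_without_noise(self, small_script):
        params = RenderParams(noise_sd=0.0, seed=5)
        a = render_clip(small_script, (10, 26), params)
        b = render_clip(small_script, (10, 26), params)
        assert np.array_equal(a.frames, b.frames)

    def test_partial_coverage_below_threshold_is_negative(self, render_params):
        # eye closure covering 40% of a 20-frame window
        script = BehaviorScript(events=[(0, 8, EYE_CLOSURE)], total_frames=40)
        sample = render_clip(script, (0, 20), render_params, label_coverage=0.5)
        assert sample.label_eye == 0
        covered = render_clip(script, (0, 10), render_params, label_coverage=0.5)
        assert covered.label_eye == 1  # 80% coverage

    def test_eye_closure_changes_pixels_in_face_box(self, render_params):
        script = BehaviorScript(events=[(0, 16, EYE_CLOSURE)], total_frames=32)
        params = RenderParams(noise_sd=0.0, face_center_jitter=0, seed=1)
        closed = render_clip(script, (0, 16), params).frames[0].astype(int)
        open_ = render_clip(script, (16, 32), params).frames[0].astype(int)
        assert np.abs(closed - open_).sum() > 0

    def test_out_of_range_window_raises(self, small_script, render_params):
        with pytest.raises(ValueError):
            render_clip(small_script, (90, 106), render_params)

    def test_invalid_render_params(self):
        with pytest.raises(ValueError):
            RenderParams(frame_height=16)
        with pytest.raises(ValueError):
            RenderParams(noise_sd=-1)
        with pytest.raises(ValueError):
            RenderParams(face_center_jitter=40)


class TestSimulateSymptomStreams:
    def test_degenerate_sigma_pins_scores_to_means(self):
        params = StreamSimParams(
            sigma=np.full((2, 2), 1e-9), n_windows=200, seed=0
        )
        obs, states = simulate_symptom_streams(params)
        expected = params.mu[:, states].T
        assert np.allclose(obs, expected, atol=1e-6)

    def test_zero_prior_gives_all_normal(self):
        obs, states = simulate_symptom_streams(
            StreamSimParams(prior_fatigued=0.0, n_windows=500, seed=2)
        )
        assert np.all(states == 0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            StreamSimParams(sigma=np.array([[0.1, 0.0], [0.1, 0.1]]))

    def test_sample_moments_match_parameters(self):
        """Distributional fidelity: sample mean/SD within 4 standard errors
        at n = 5000 per state."""
        params = StreamSimParams(prior_fatigued=0.5, n_windows=10000, seed=9)
        obs, states = simulate_symptom_streams(params)
        for s in (0, 1):
            block = obs[states == s]
            n = len(block)
            for attr in (0, 1):
                mu, sd = params.mu[attr, s], params.sigma[attr, s]
                assert abs(block[:, attr].mean() - mu) < 4 * sd / np.sqrt(n)
                sd_se = sd / np.sqrt(2 * (n - 1))
                assert abs(block[:, attr].std(ddof=1) - sd) < 4 * sd_se

    def test_determinism(self):
        p = StreamSimParams(n_windows=100, seed=33)
        a = simulate_symptom_streams(p)
        b = simulate_symptom_streams(p)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestMakeDataset:
    def test_splits_are_subject_disjoint_and_counted(self, tmp_path):
        cfg = DatasetConfig(
            n_subjects=10,
            clips_per_subject=4,
            splits={"train": 0.8, "test": 0.2},
            seed=5,
        )
        manifest = make_dataset(cfg, tmp_path, write_frames=False)
        assert len(manifest) == cfg.n_clips == 40
        by_split = manifest.groupby("split")["subject_id"].unique()
        assert set(by_split["train"]).isdisjoint(by_split["test"])

    def test_manifest_regeneration_is_byte_identical(self, tmp_path):
        cfg = DatasetConfig(
            n_subjects=4, clips_per_subject=3,
            splits={"train": 0.5, "test": 0.5}, seed=8,
        )
        make_dataset(cfg, tmp_path / "a", write_frames=False)
        make_dataset(cfg, tmp_path / "b", write_frames=False)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()

    def test_bad_split_fractions_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(splits={"train": 0.5, "test": 0.4})

    def test_written_clips_round_trip(self, tmp_path):
        from somnoscope.io import read_clip_source, read_clip_metadata

        cfg = DatasetConfig(
            n_subjects=4, clips_per_subject=2,
            splits={"train": 0.5, "test": 0.5}, seed=3,
        )
        manifest = make_dataset(cfg, tmp_path)
        row = manifest.iloc[0]
        frames, fps = read_clip_source(tmp_path / row["path"])
        assert frames.shape == (cfg.clip_len, 64, 64)
        meta = read_clip_metadata(tmp_path / row["path"])
        assert len(meta["face_box"]) == 4
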