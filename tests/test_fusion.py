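"""Gaussian naive-Bayes MAP fusion: oracle equivalence, constraint, recovery."""

import json

import numpy as np
import pytest
from scipy.stats import norm

from somnoscope.fusion import (
    FatigueDecision,
    FusionConfig,
    GaussianNBModel,
    SymptomObservation,
    apply_constraint,
    compute_window_scores,
    fit_gnb,
    gnb_posterior,
    infer_state,
)
from somnoscope.model import SymptomStream
from somnoscope.synthetic import StreamSimParams, simulate_symptom_streams


def _posterior_oracle(model: GaussianNBModel, obs: SymptomObservation) -> np.ndarray:
    """Brute force: enumerate both states, multiply densities, normalize."""
    unnorm = np.array(
        [
            model.prior[s]
            * norm.pdf(obs.a_e, model.mu[0, s], model.sigma[0, s])
            * norm.pdf(obs.a_m, model.mu[1, s], model.sigma[1, s])
            for s in (0, 1)
        ]
    )
    return unnorm / unnorm.sum()


def _stream(p_eye, p_mouth) -> SymptomStream:
    idx = np.arange(len(p_eye))
    return SymptomStream(idx, idx * 0.64, np.asarray(p_eye, float), np.asarray(p_mouth, float))


class TestComputeWindowScores:
    def test_saturated_probabilities_give_unit_frequency(self):
        cfg = FusionConfig(window_clips=5)
        obs = compute_window_scores(_stream([1.0] * 6, [0.0] * 6), cfg)
        assert all(o.a_e == 1.0 and o.a_m == 0.0 for o in obs)

    def test_hand_counted_exceedances(self):
        cfg = FusionConfig(window_clips=4, frame_threshold=0.5)
        obs = compute_window_scores(
            _stream([0.0, 0.0, 0.0, 0.0], [0.9, 0.1, 0.9, 0.1]), cfg
        )
        assert len(obs) == 1
        assert obs[0].a_m == 0.5 and obs[0].a_e == 0.0

    def test_window_count_identity(self):
        cfg = FusionConfig(window_clips=4)
        for length in (4, 7, 12):
            obs = compute_window_scores(
                _stream(np.linspace(0, 1, length), np.zeros(length)), cfg
            )
            assert len(obs) == length - cfg.window_clips + 1

    def test_mean_probability_mode(self):
        cfg = FusionConfig(window_clips=2, score_mode="mean_probability")
        obs = compute_window_scores(_stream([0.2, 0.4, 0.8], [0, 0, 0]), cfg)
        assert obs[0].a_e == pytest.approx(0.3) and obs[1].a_e == pytest.approx(0.6)

    def test_window_longer_than_stream_rejected(self):
        with pytest.raises(ValueError):
            compute_window_scores(_stream([0.5], [0.5]), FusionConfig(window_clips=2))


class TestFitGnb:
    def test_balanced_labels_give_even_prior(self):
        obs = np.array([[0.1, 0.1]] * 4 + [[0.8, 0.8]] * 4)
        labels = np.array([0] * 4 + [1] * 4)
        model = fit_gnb(obs, labels, sigma_floor=1e-6)
        assert np.allclose(model.prior, [0.5, 0.5])

    def test_constant_attribute_floored_with_warning(self):
        obs = np.array([[0.2, 0.3], [0.2, 0.5], [0.7, 0.1], [0.9, 0.4]])
        labels = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_gnb(obs, labels, sigma_floor=1e-6)
        assert model.mu[0, 0] == pytest.approx(0.2)
        assert model.sigma[0, 0] == 1e-6

    def test_population_variance_used(self):
        obs = np.array([[0.0, 0.0], [1.0, 1.0], [0.4, 0.2], [0.6, 0.8]])
        labels = np.array([0, 0, 1, 1])
        model = fit_gnb(obs, labels, sigma_floor=1e-6)
        assert model.sigma[0, 0] == pytest.approx(0.5)  # /n, not /(n-1)

    def test_missing_state_rejected(self):
        obs = np.random.default_rng(0).random((6, 2))
        with pytest.raises(ValueError):
            fit_gnb(obs, np.zeros(6, dtype=int))

    def test_parameter_recovery_from_simulated_streams(self):
        """fit_gnb on model-generated data recovers the generating
        parameters: mu within 3*sigma/sqrt(n), sigma within 10% relative,
        prior within 0.03 (fixed seeds)."""
        params = StreamSimParams(prior_fatigued=0.5, n_windows=4000, seed=21)
        obs, states = simulate_symptom_streams(params)
        model = fit_gnb(obs, states, sigma_floor=1e-6)
        assert abs(model.prior[1] - 0.5) < 0.03
        for attr in (0, 1):
            for s in (0, 1):
                n_s = int((states == s).sum())
                mu, sd = params.mu[attr, s], params.sigma[attr, s]
                assert abs(model.mu[attr, s] - mu) < 3 * sd / np.sqrt(n_s)
                assert abs(model.sigma[attr, s] - sd) / sd < 0.10

    def test_json_round_trip(self, tmp_path):
        obs = np.array([[0.1, 0.2], [0.15, 0.1], [0.7, 0.9], [0.8, 0.7]])
        model = fit_gnb(obs, np.array([0, 0, 1, 1]), sigma_floor=0.05)
        path = tmp_path / "gnb.json"
        model.to_json(path)
        back = GaussianNBModel.from_json(path)
        assert np.allclose(back.prior, model.prior)
        assert np.allclose(back.mu, model.mu)
        assert np.allclose(back.sigma, model.sigma)
        assert json.loads(path.read_text())["states"] == ["normal", "fatigued"]


class TestGnbPosterior:
    def test_symmetric_model_gives_even_posterior(self):
        model = GaussianNBModel(
            prior=[0.5, 0.5], mu=[[0.3, 0.3], [0.3, 0.3]], sigma=[[0.1, 0.1], [0.1, 0.1]]
        )
        post = gnb_posterior(model, SymptomObservation(0.9, -0.2))
        assert np.allclose(post, [0.5, 0.5])

    def test_degenerate_prior_is_preserved(self):
        model = GaussianNBModel(
            prior=[1.0, 0.0], mu=[[0.1, 0.8], [0.1, 0.8]], sigma=[[0.1, 0.1], [0.1, 0.1]]
        )
        post = gnb_posterior(model, SymptomObservation(0.8, 0.8))
        assert np.allclose(post, [1.0, 0.0])

    def test_spec_worked_example_matches_oracle(self):
        model = GaussianNBModel(
            prior=[0.7, 0.3],
            mu=[[0.1, 0.8], [0.1, 0.7]],
            sigma=[[0.15, 0.15], [0.15, 0.15]],
        )
        obs = SymptomObservation(0.75, 0.65)
        got = gnb_posterior(model, obs)
        want = _posterior_oracle(model, obs)
        assert np.allclose(got, want, atol=1e-10)

    def test_normalization_and_oracle_agreement_on_random_models(self, rng):
        for _ in range(300):
            prior1 = rng.uniform(0.05, 0.95)
            model = GaussianNBModel(
                prior=[1 - prior1, prior1],
                mu=rng.uniform(-0.5, 1.5, size=(2, 2)),
                sigma=rng.uniform(0.05, 0.6, size=(2, 2)),
            )
            obs = SymptomObservation(*rng.uniform(-0.5, 1.5, size=2))
            post = gnb_posterior(model, obs)
            assert abs(post.sum() - 1.0) < 1e-12
            assert np.allclose(post, _posterior_oracle(model, obs), atol=1e-10)

    def test_monotonicity_in_symptom_scores(self):
        """With fatigued means above normal means, raising either score
        never lowers the fatigued posterior."""
        model = GaussianNBModel(
            prior=[0.6, 0.4],
            mu=[[0.1, 0.7], [0.05, 0.6]],
            sigma=[[0.2, 0.2], [0.2, 0.2]],
        )
        grid = np.linspace(0, 1, 21)
        for a_m in (0.0, 0.3, 0.8):
            post1 = [gnb_posterior(model, SymptomObservation(a, a_m))[1] for a in grid]
            assert np.all(np.diff(post1) >= -1e-12)
        for a_e in (0.0, 0.3, 0.8):
            post1 = [gnb_posterior(model, SymptomObservation(a_e, a))[1] for a in grid]
            assert np.all(np.diff(post1) >= -1e-12)


class TestConstraintAndDecision:
    def test_constraint_forces_fatigued_state(self):
        cfg = FusionConfig()
        state, fired = apply_constraint(SymptomObservation(0.9, 0.9), 0, cfg)
        assert (state, fired) == (1, True)

    def test_single_symptom_passes_map_state_through(self):
        cfg = FusionConfig()
        state, fired = apply_constraint(SymptomObservation(0.9, 0.0), 0, cfg)
        assert (state, fired) == (0, False)
        state, fired = apply_constraint(SymptomObservation(0.9, 0.9), 1, cfg)
        assert (state, fired) == (1, False)  # no override happened

    def test_no_coactive_window_is_ever_normal(self, rng):
        """Constraint dominance on a simulated decision set: zero windows
        with both binarized symptoms active end up labelled normal."""
        params = StreamSimParams(prior_fatigued=0.4, n_windows=3000, seed=17)
        obs_arr, states = simulate_symptom_streams(params)
        model = fit_gnb(obs_arr, states, sigma_floor=1e-6)
        cfg = FusionConfig()
        decisions = [
            infer_state(model, SymptomObservation(a, b), cfg) for a, b in obs_arr
        ]
        for (a, b), d in zip(obs_arr, decisions):
            if a > cfg.constraint_threshold and b > cfg.constraint_threshold:
                assert d.state == 1
            # contract invariants
            assert abs(d.posterior.sum() - 1.0) < 1e-12
            if d.constraint_fired:
                assert d.state == 1

    def test_exact_tie_breaks_to_configured_state(self):
        model = GaussianNBModel(
            prior=[0.5, 0.5], mu=[[0.2, 0.2], [0.2, 0.2]], sigma=[[0.1, 0.1], [0.1, 0.1]]
        )
        obs = SymptomObservation(0.3, 0.1)
        assert infer_state(model, obs, FusionConfig(tie_break=0)).state == 0
        assert infer_state(model, obs, FusionConfig(tie_break=1)).state == 1

    def test_observation_at_fatigued_mean_is_fatigued(self):
        model = GaussianNBModel(
            prior=[0.7, 0.3],
            mu=[[0.1, 0.8], [0.1, 0.7]],
            sigma=[[0.15, 0.15], [0.15, 0.15]],
        )
        d = infer_state(model, SymptomObservation(0.8, 0.7), FusionConfig())
        assert d.state == 1 and d.posterior[1] > 0.99

    def test_decision_invariants_rejected_when_violated(self):
        with pytest.raises(ValueError):
            FatigueDecision(state=0, posterior=[0.5, 0.5], constraint_fired=True, window=(0, 1))
        with pytest.raises(ValueError):
            FatigueDecision(state=1, posterior=[0.7, 0.7], constraint_fired=False, window=(0, 1))


def test_well_separated_streams_classify_below_one_percent_error():
    """6-sigma mean separation: downstream GNB error far below 1%."""
    params = StreamSimParams(
        mu=np.array([[0.0, 0.6], [0.0, 0.6]]),
        sigma=np.full((2, 2), 0.1),
        prior_fatigued=0.5,
        n_windows=10000,
        seed=3,
    )
    obs, states = simulate_symptom_streams(params)
    model = fit_gnb(obs, states, sigma_floor=1e-6)
    pred = np.array(
        [gnb_posterior(model, SymptomObservation(a, b))[1] > 0.5 for a, b in obs]
    ).astype(int)
    assert (pred != states).mean() < 0.01
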