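"""Behavior/activity generator: switch logic, bias correction, statistics."""

import numpy as np
import pytest

from ymaze.population import noise_correlations
from ymaze.synthetic import (
    generate_population_activity,
    simulate_running,
    simulate_task_session,
)
from ymaze.types import AgentConfig, NeuralGenConfig, TaskConfig, correct_side_for


def replay_switches(session, min_trials=75, window=30, threshold=0.85):
    """Independent brute-force replay of the three rule-switch criteria."""
    correct = session.correct
    switches, last = [], 0
    for t in range(1, session.n_trials):
        if (
            t - last >= min_trials
            and t >= window
            and correct[t - window : t].mean() >= threshold
            and correct[t - 1]
        ):
            switches.append(t)
            last = t
    return switches


class TestTaskSimulation:
    def test_perfect_agent_switching_defaults(self):
        session = simulate_task_session(
            TaskConfig(task_kind="switching", n_trials=225),
            AgentConfig(p_correct=1.0),
            seed=0,
        )
        assert session.rule_switch_trials() == [75, 150]

    @pytest.mark.parametrize("seed", range(5))
    def test_switch_times_match_brute_force_replay(self, seed):
        session = simulate_task_session(
            TaskConfig(task_kind="switching", n_trials=400),
            AgentConfig(p_correct=0.92, post_switch_relearn_trials=15),
            seed=seed,
        )
        assert session.rule_switch_trials() == replay_switches(session)

    def test_always_left_agent_triggers_bias_correction(self):
        session = simulate_task_session(
            TaskConfig(task_kind="simple", n_trials=40),
            AgentConfig(p_correct=0.0, lapse_rate=1.0, side_bias=1.0),
            seed=1,
        )
        forced = [t for t in session.trials if t.forced_by_bias_correction]
        assert [t.index for t in forced] == [5, 11, 17, 23, 29, 35]
        assert all(t.correct_side == "right" for t in forced)

    def test_perfect_simple_agent_degenerate(self):
        session = simulate_task_session(
            TaskConfig(task_kind="simple", n_trials=100), AgentConfig(p_correct=1.0), seed=2
        )
        assert session.correct.all()
        assert all(t.rule == "A" for t in session.trials)
        # bias correction keys on choices irrespective of correctness, so a
        # perfect agent is still forced after five same-side cues in a row
        forced = [t.index for t in session.trials if t.forced_by_bias_correction]
        choices = [t.choice for t in session.trials]
        for idx in forced:
            run = choices[idx - 5 : idx]
            assert len(set(run)) == 1

    def test_expected_fraction_correct_with_guided(self):
        g, p, n = 0.3, 0.7, 8000
        session = simulate_task_session(
            TaskConfig(task_kind="simple", n_trials=n, guided_fraction=g),
            AgentConfig(p_correct=p),
            seed=3,
        )
        expected = g + (1 - g) * p
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(session.correct.mean() - expected) < 4 * se
        assert all(t.correct for t in session.trials if t.guided)

    def test_rule_maps_cue_to_side(self):
        session = simulate_task_session(
            TaskConfig(task_kind="switching", n_trials=200), AgentConfig(p_correct=1.0), seed=4
        )
        for t in session.trials:
            assert t.correct_side == correct_side_for(t.cue, t.rule)
            assert t.correct == (t.choice == t.correct_side)

    def test_same_seed_bit_identical(self):
        task = TaskConfig(task_kind="switching", n_trials=150)
        agent = AgentConfig(p_correct=0.85, lapse_rate=0.05)
        a = simulate_task_session(task, agent, seed=7)
        b = simulate_task_session(task, agent, seed=7)
        assert a.to_frame().equals(b.to_frame())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(n_trials=0)
        with pytest.raises(ValueError):
            TaskConfig(task_kind="simple", switch_min_trials=40)
        with pytest.raises(ValueError):
            AgentConfig(p_correct=1.5)


class TestRunning:
    def test_divergence_sets_lateral_choice_difference(self, simple_session):
        profile = np.concatenate([np.zeros(10), np.full(10, 5.0)])
        running = simulate_running(simple_session, profile, noise_sd=0.5, seed=5)
        choices = np.array([t.choice for t in simple_session.trials])
        diff = (
            running.lateral[choices == "right"].mean(axis=0)
            - running.lateral[choices == "left"].mean(axis=0)
        )
        assert np.allclose(diff[:10], 0.0, atol=0.5)
        assert np.allclose(diff[10:], 5.0, atol=0.5)

    def test_zero_divergence_null(self, simple_session):
        running = simulate_running(simple_session, np.zeros(8), noise_sd=1.0, seed=6)
        choices = np.array([t.choice for t in simple_session.trials])
        diff = (
            running.lateral[choices == "right"].mean(axis=0)
            - running.lateral[choices == "left"].mean(axis=0)
        )
        assert np.all(np.abs(diff) < 0.5)

    def test_length_mismatch_rejected(self, simple_session):
        with pytest.raises(ValueError):
            simulate_running(simple_session, np.zeros((2, 4)), noise_sd=1.0, seed=0)


class TestPopulationGenerator:
    def test_ground_truth_means_ordered(self, small_population):
        binned, truth = small_population
        cue = binned.trial_meta["cue"].to_numpy()
        for i in np.nonzero(truth.is_selective)[0][:10]:
            pref = cue == truth.preferred_cue[i]
            b = truth.preferred_bin[i]
            assert (
                binned.activity[i, pref, b].mean()
                > binned.activity[i, ~pref, b].mean()
            )

    def test_nonselective_neurons_have_equal_type_means(self, simple_session):
        cfg = NeuralGenConfig(
            n_neurons_per_area={"V1": 20}, n_bins=10, fraction_selective=0.0,
            private_noise_sd=0.5, seed=30,
        )
        binned, truth = generate_population_activity(simple_session, cfg)
        assert not truth.is_selective.any()
        cue = binned.trial_meta["cue"].to_numpy()
        diff = (
            binned.activity[:, cue == "vertical", :].mean(axis=1)
            - binned.activity[:, cue == "horizontal", :].mean(axis=1)
        )
        # no built-in selectivity: differences are pure sampling noise
        assert np.abs(diff).max() < 0.5

    def test_closed_form_noise_correlation_unclipped(self, simple_session):
        # lambda^2 / (lambda^2 + sigma^2) = 0.2
        cfg = NeuralGenConfig(
            n_neurons_per_area={"V1": 30}, n_bins=12, shared_noise_loading=0.5,
            private_noise_sd=1.0, clip=False, baseline_rate=1.0, seed=31,
        )
        binned, truth = generate_population_activity(simple_session, cfg)
        assert truth.expected_noise_correlation == pytest.approx(0.2)
        labels = (binned.trial_meta["cue"] == "vertical").to_numpy()
        measured = noise_correlations(binned, labels).mean_r
        assert measured == pytest.approx(0.2, abs=0.05)

    def test_zero_loading_gives_null_correlations(self, simple_session):
        cfg = NeuralGenConfig(
            n_neurons_per_area={"V1": 30}, n_bins=12, shared_noise_loading=0.0,
            clip=False, seed=32,
        )
        binned, _ = generate_population_activity(simple_session, cfg)
        labels = (binned.trial_meta["cue"] == "vertical").to_numpy()
        assert abs(noise_correlations(binned, labels).mean_r) < 0.02

    def test_correlation_monotone_in_loading(self, simple_session):
        labels = None
        means = []
        for lam in (0.0, 0.3, 0.6):
            cfg = NeuralGenConfig(
                n_neurons_per_area={"V1": 25}, n_bins=10, shared_noise_loading=lam,
                clip=False, seed=33,
            )
            binned, _ = generate_population_activity(simple_session, cfg)
            labels = (binned.trial_meta["cue"] == "vertical").to_numpy()
            means.append(noise_correlations(binned, labels).mean_r)
        assert means[0] < means[1] < means[2]

    def test_activity_nonnegative_when_clipped(self, small_population):
        binned, _ = small_population
        assert (binned.activity >= 0).all()

    def test_determinism(self, simple_session):
        cfg = NeuralGenConfig(n_neurons_per_area={"V1": 10}, n_bins=8, seed=34)
        a, _ = generate_population_activity(simple_session, cfg)
        b, _ = generate_population_activity(simple_session, cfg)
        np.testing.assert_array_equal(a.activity, b.activity)

    def test_too_few_trials_rejected(self):
        session = simulate_task_session(
            TaskConfig(n_trials=3), AgentConfig(p_correct=1.0), seed=35
        )
        cfg = NeuralGenConfig(n_neurons_per_area={"V1": 5}, n_bins=4, seed=36)
        with pytest.raises(ValueError, match="2 trials"):
            generate_population_activity(session, cfg)
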