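"""auROC selectivity, permutation significance, segments, categories."""

import numpy as np
import pytest

from ymaze.selectivity import (
    auroc_per_bin,
    categorize_across_rules,
    compute_selectivity_profile,
    segment_summaries,
    selectivity_index,
    shuffle_significance,
)
from ymaze.synthetic import generate_population_activity, simulate_task_session
from ymaze.types import (
    AgentConfig,
    NeuralGenConfig,
    SegmentSpec,
    SelectivityProfile,
    TaskConfig,
)


def pair_count_auroc(pos, neg):
    """Exhaustive all-pairs oracle with half credit for ties."""
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        act = np.array([4.0, 5, 6, 1, 2, 3]).reshape(1, 6, 1)
        labels = [True] * 3 + [False] * 3
        assert auroc_per_bin(act, labels)[0, 0] == 1.0

    def test_identical_distributions(self):
        act = np.array([1.0, 2, 3, 1, 2, 3]).reshape(1, 6, 1)
        labels = [True] * 3 + [False] * 3
        assert auroc_per_bin(act, labels)[0, 0] == 0.5

    def test_interleaved_example(self):
        act = np.array([2.0, 4, 1, 3]).reshape(1, 4, 1)
        labels = [True, True, False, False]
        assert auroc_per_bin(act, labels)[0, 0] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        n_pos = rng.integers(2, n - 1)
        # integer values force ties, exercising the half-credit convention
        act = rng.integers(0, 4, size=(3, n, 2)).astype(float)
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, n_pos, replace=False)] = True
        out = auroc_per_bin(act, labels)
        for i in range(3):
            for b in range(2):
                expected = pair_count_auroc(act[i, labels, b], act[i, ~labels, b])
                assert out[i, b] == pytest.approx(expected)

    def test_label_swap_reflects(self):
        rng = np.random.default_rng(5)
        act = rng.normal(size=(4, 20, 3))
        labels = np.arange(20) % 2 == 0
        a = auroc_per_bin(act, labels)
        b = auroc_per_bin(act, ~labels)
        np.testing.assert_allclose(a, 1.0 - b)
        np.testing.assert_allclose(selectivity_index(a), selectivity_index(b))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_per_bin(np.ones((1, 4, 1)), [True] * 4)


class TestSelectivityIndex:
    @pytest.mark.parametrize(
        "auroc,expected", [(0.5, 0.0), (1.0, 1.0), (0.0, 1.0), (0.75, 0.5)]
    )
    def test_formula(self, auroc, expected):
        assert selectivity_index(auroc) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            selectivity_index(1.2)


class TestShuffleSignificance:
    def test_noiseless_selective_neuron_significant(self):
        labels = np.arange(40) % 2 == 0
        act = np.where(labels, 2.0, 0.0).reshape(1, 40, 1)
        p, sig = shuffle_significance(act, labels, seed=0)
        assert sig[0, 0]
        assert p[0, 0] == pytest.approx(1 / 101)

    def test_constant_neuron_p_one(self):
        labels = np.arange(20) % 2 == 0
        act = np.ones((1, 20, 1))
        p, sig = shuffle_significance(act, labels, seed=1)
        assert p[0, 0] == 1.0
        assert not sig[0, 0]

    def test_p_in_valid_range_and_add_one(self):
        rng = np.random.default_rng(2)
        act = rng.normal(size=(5, 30, 4))
        labels = np.arange(30) % 2 == 0
        p, sig = shuffle_significance(act, labels, n_shuffles=50, seed=3)
        assert (p > 0).all() and (p <= 1).all()
        assert p.min() >= 1 / 51
        np.testing.assert_array_equal(sig, p < 0.01)

    def test_shared_and_per_neuron_modes_agree_on_strong_signal(self):
        labels = np.arange(60) % 2 == 0
        rng = np.random.default_rng(4)
        act = np.where(labels, 3.0, 0.0).reshape(1, 60, 1) + rng.normal(
            0, 0.1, (6, 60, 2)
        )
        _, sig_shared = shuffle_significance(act, labels, seed=5)
        _, sig_per = shuffle_significance(act, labels, seed=5, per_neuron=True)
        assert sig_shared.all() and sig_per.all()


class TestSegments:
    def _toy_profile(self):
        # 3 neurons x 6 bins, bins 20 cm wide -> centers 10..110
        sel = np.array(
            [
                [0.0, 0.0, 0.2, 0.2, 0.4, 0.4],
                [0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
                [0.0, 0.5, 0.0, 0.5, 0.0, 0.5],
            ]
        )
        sig = sel >= 0.4
        return SelectivityProfile(
            auroc=0.5 + sel / 2,
            selectivity=sel,
            p_shuffle=np.where(sig, 0.005, 0.5),
            significant=sig,
            alpha=0.01,
            mean_activity=np.ones_like(sel),
            area=np.array(["V1", "V1", "PPC"]),
        )

    def test_toy_arithmetic(self):
        profile = self._toy_profile()
        edges = np.arange(7) * 20.0
        spec = SegmentSpec({"early": (0.0, 60.0), "late": (60.0, 120.0)})
        summary = segment_summaries(profile, edges, spec)
        row = summary.per_neuron.query("neuron == 0 and segment == 'early'")
        assert row["mean_selectivity"].item() == pytest.approx((0 + 0 + 0.2) / 3)
        row = summary.per_neuron.query("neuron == 0 and segment == 'late'")
        assert row["mean_selectivity"].item() == pytest.approx((0.2 + 0.4 + 0.4) / 3)
        # fraction selective: per-bin share of neurons, averaged over bins
        v1_late = summary.per_area.query("area == 'V1' and segment == 'late'")
        assert v1_late["fraction_selective"].item() == pytest.approx((0 + 0.5 + 0.5) / 3)

    def test_constant_selectivity_constant_segments(self):
        sel = np.full((2, 6), 0.3)
        profile = SelectivityProfile(
            auroc=np.full((2, 6), 0.65), selectivity=sel,
            p_shuffle=np.full((2, 6), 0.5), significant=np.zeros((2, 6), bool),
            alpha=0.01, mean_activity=sel,
        )
        edges = np.arange(7) * 20.0
        spec = SegmentSpec({"a": (0.0, 40.0), "b": (40.0, 120.0)})
        summary = segment_summaries(profile, edges, spec)
        assert np.allclose(summary.per_neuron["mean_selectivity"], 0.3)

    def test_empty_segment_rejected(self):
        profile = self._toy_profile()
        edges = np.arange(7) * 20.0
        with pytest.raises(ValueError, match="no bins"):
            segment_summaries(profile, edges, SegmentSpec({"off": (500.0, 600.0)}))


class TestCategorization:
    @staticmethod
    @pytest.fixture(scope="class")
    def switching_behavior():
        return simulate_task_session(
            TaskConfig(task_kind="switching", n_trials=400),
            AgentConfig(p_correct=1.0),
            seed=40,
        )

    @pytest.mark.parametrize(
        "mode,expected",
        [("single", "single_trial_type"), ("choice", "choice"), ("cue", "cue")],
    )
    def test_generator_modes_recovered(self, switching_behavior, mode, expected):
        cfg = NeuralGenConfig(
            n_neurons_per_area={"PPC": 12},
            n_bins=10,
            tuning_width_bins=4.0,
            selectivity_strength=4.0,
            fraction_selective=1.0,
            shared_noise_loading=0.0,
            private_noise_sd=0.3,
            selectivity_mode=mode,
            seed=41,
        )
        binned, truth = generate_population_activity(switching_behavior, cfg)
        table = categorize_across_rules(binned, seed=42)
        recovered = table["category"].to_numpy()
        assert (recovered == expected).mean() > 0.8

    def test_null_neurons_mostly_none(self, switching_behavior):
        cfg = NeuralGenConfig(
            n_neurons_per_area={"PPC": 15}, n_bins=10, fraction_selective=0.0,
            shared_noise_loading=0.0, seed=43,
        )
        binned, _ = generate_population_activity(switching_behavior, cfg)
        table = categorize_across_rules(binned, seed=44)
        assert (table["category"] == "none").mean() > 0.8

    def test_missing_trial_types_rejected(self, simple_session, small_population):
        binned, _ = small_population
        with pytest.raises(ValueError, match="four"):
            categorize_across_rules(binned, seed=45)
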