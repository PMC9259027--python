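import numpy as np
import pytest

from ymaze.synthetic import generate_population_activity, simulate_task_session
from ymaze.types import AgentConfig, NeuralGenConfig, TaskConfig


@pytest.fixture(scope="session")
def simple_session():
    """A well-performing simple-task session."""
    return simulate_task_session(
        TaskConfig(task_kind="simple", n_trials=200),
        AgentConfig(p_correct=0.9),
        seed=11,
    )


@pytest.fixture(scope="session")
def switching_session():
    """A switching-task session with relearning dips after rule switches."""
    return simulate_task_session(
        TaskConfig(task_kind="switching", n_trials=300),
        AgentConfig(p_correct=0.95, post_switch_relearn_trials=20),
        seed=13,
    )


@pytest.fixture(scope="session")
def small_population(simple_session):
    """A small selective population with shared noise, plus ground truth."""
    cfg = NeuralGenConfig(
        n_neurons_per_area={"V1": 15, "PPC": 15, "RSC": 15},
        n_bins=16,
        selectivity_strength=1.5,
        fraction_selective=0.4,
        shared_noise_loading=0.4,
        seed=21,
    )
    binned, truth = generate_population_activity(simple_session, cfg)
    return binned, truth


@pytest.fixture(scope="session")
def population_labels(small_population):
    binned, _ = small_population
    return (binned.trial_meta["cue"] == "vertical").to_numpy()
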