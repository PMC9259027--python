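"""Synthetic Y-maze sessions, running kinematics, and population activity.

The generator reproduces the statistical structure the downstream analyses
assume, with ground-truth labels for parameter-recovery tests:

* behavioral sessions with the training protocol's rule-switch criteria
  (75 trials minimum block length, 85% correct over the last 30 trials,
  correct preceding trial) and the 5-in-a-row bias-correction rule;
* running traces whose left/right lateral divergence is set per spatial bin;
* deconvolved-like population activity with transient Gaussian spatial
  tuning (sequences), configurable trial-type selectivity, and a shared
  per-trial latent controlling pairwise noise correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    AgentConfig,
    BinnedActivity,
    GroundTruth,
    InhibitionConfig,
    NeuralGenConfig,
    RunningTrace,
    SessionBehavior,
    TaskConfig,
    TrialRecord,
    correct_side_for,
    cue_for_side,
    other_rule,
    other_side,
)

__all__ = [
    "simulate_task_session",
    "simulate_running",
    "generate_population_activity",
]


def simulate_task_session(
    task: TaskConfig,
    agent: AgentConfig,
    seed: int | None = None,
    *,
    session_id: str = "sim",
    mouse_id: str = "m0",
    inhibition: InhibitionConfig | None = None,
) -> SessionBehavior:
    """Simulate one behavioral session.

    Cues are drawn i.i.d. uniform unless overridden by bias correction: if
    the agent made the same choice on the last five non-forced trials, the
    next trial's rewarded side is forced to the opposite side (and the cue
    set accordingly), after which the run counter restarts. In the switching
    task the rule-switch criteria are evaluated once before each trial; at
    most one switch occurs per trial boundary. Guided trials occur with
    probability ``task.guided_fraction`` and are always correct.

    With ``inhibition`` set, every trial receives a laser target (control
    with probability ``control_fraction``, else uniform over the cortical
    targets) and the agent's effective accuracy is reduced by the target's
    entry in ``p_correct_drop``.
    """
    rng = np.random.default_rng(seed)
    rule = task.initial_rule
    last_switch = 0  # first trial of the current rule block
    any_switch = False
    correct_hist: list[bool] = []
    run_side: str | None = None
    run_len = 0
    trials: list[TrialRecord] = []

    for t in range(task.n_trials):
        if task.task_kind == "switching" and t >= 1:
            if (
                t - last_switch >= task.switch_min_trials
                and len(correct_hist) >= task.switch_window
                and float(np.mean(correct_hist[-task.switch_window :]))
                >= task.switch_perf_threshold
                and correct_hist[-1]
            ):
                rule = other_rule(rule)
                last_switch = t
                any_switch = True

        forced = run_len >= task.bias_correction_run
        if forced:
            correct_side = other_side(run_side)  # type: ignore[arg-type]
            cue = cue_for_side(correct_side, rule)
        else:
            cue = "horizontal" if rng.random() < 0.5 else "vertical"
            correct_side = correct_side_for(cue, rule)

        laser_target = "none"
        drop = 0.0
        if inhibition is not None:
            if rng.random() < inhibition.control_fraction:
                laser_target = "control"
            else:
                laser_target = inhibition.targets[rng.integers(len(inhibition.targets))]
            drop = float(inhibition.p_correct_drop.get(laser_target, 0.0))

        # Accuracy ramps back from chance after each rule switch.
        if any_switch and agent.post_switch_relearn_trials > 0:
            frac = min((t - last_switch) / agent.post_switch_relearn_trials, 1.0)
            p_eff = 0.5 + (agent.p_correct - 0.5) * frac
        else:
            p_eff = agent.p_correct
        p_eff = min(max(p_eff - drop, 0.0), 1.0)

        guided = rng.random() < task.guided_fraction
        if guided:
            choice = correct_side
        elif rng.random() < agent.lapse_rate:
            choice = "left" if rng.random() < (1.0 + agent.side_bias) / 2.0 else "right"
        else:
            choice = correct_side if rng.random() < p_eff else other_side(correct_side)

        correct = choice == correct_side
        correct_hist.append(correct)
        if forced:
            run_side, run_len = None, 0
        elif choice == run_side:
            run_len += 1
        else:
            run_side, run_len = choice, 1

        trials.append(
            TrialRecord(
                index=t,
                cue=cue,
                rule=rule,
                correct_side=correct_side,
                choice=choice,
                correct=correct,
                guided=guided,
                laser_target=laser_target,
                forced_by_bias_correction=forced,
            )
        )

    return SessionBehavior(session_id=session_id, mouse_id=mouse_id, trials=trials)


def simulate_running(
    behavior: SessionBehavior,
    divergence_profile: np.ndarray,
    noise_sd: float,
    seed: int | None = None,
    *,
    bin_size_cm: float = 5.0,
    base_pitch: float = 20.0,
) -> RunningTrace:
    """Generate spatially binned running kinematics for a session.

    The lateral-position mean differs between right- and left-choice trials
    by ``divergence_profile[b]`` at bin ``b``; all four channels carry
    additive Gaussian noise of standard deviation ``noise_sd``. Pitch sits
    on a constant forward-running offset; roll and yaw are pure noise.
    """
    profile = np.asarray(divergence_profile, dtype=float)
    if profile.ndim != 1:
        raise ValueError("divergence_profile must be 1-D (one value per bin)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    n_bins = len(profile)
    n_trials = behavior.n_trials
    sign = np.array(
        [0.5 if t.choice == "right" else -0.5 for t in behavior.trials]
    )
    shape = (n_trials, n_bins)
    lateral = sign[:, None] * profile[None, :] + rng.normal(0.0, noise_sd, shape)
    pitch = base_pitch + rng.normal(0.0, noise_sd, shape)
    roll = rng.normal(0.0, noise_sd, shape)
    yaw = rng.normal(0.0, noise_sd, shape)
    bin_edges = np.arange(n_bins + 1, dtype=float) * bin_size_cm
    return RunningTrace(pitch=pitch, roll=roll, yaw=yaw, lateral=lateral, bin_edges=bin_edges)


def _preferred_type_match(
    mode: str,
    cue: np.ndarray,
    rule: np.ndarray,
    choice: np.ndarray,
    pref_cue: str,
    pref_rule: str,
    pref_choice: str,
) -> np.ndarray:
    if mode == "single":
        return (cue == pref_cue) & (rule == pref_rule)
    if mode == "cue":
        return cue == pref_cue
    if mode == "choice":
        return choice == pref_choice
    raise ValueError(f"unknown selectivity_mode {mode!r}")


def generate_population_activity(
    behavior: SessionBehavior,
    cfg: NeuralGenConfig,
    *,
    bin_size_cm: float = 5.0,
) -> tuple[BinnedActivity, GroundTruth]:
    """Generate multi-area population activity for a simulated session.

    Each neuron has a Gaussian tuning bump of height ``peak_rate`` at a
    uniformly drawn preferred bin. Selective neurons (a ``fraction_selective``
    share) get the bump raised by ``selectivity_strength`` on their preferred
    trial type, where "trial type" is a cue-rule pair (``single`` mode), a
    cue across rules (``cue``), or a choice across rules (``choice``). The
    per-trial response adds a shared standard-normal latent times the
    neuron's loading plus private Gaussian noise, then clips at zero unless
    ``cfg.clip`` is off (the unclipped variant keeps the closed-form
    expected pairwise correlation lambda^2 / (lambda^2 + sigma^2) exact).

    With ``noise_alignment='signal'`` the loading's sign follows the
    neuron's preferred side, so the shared latent fluctuates along the
    population's discrimination axis (information-limiting correlations).
    """
    meta = behavior.trial_meta()
    cue = meta["cue"].to_numpy()
    rule = meta["rule"].to_numpy()
    choice = meta["choice"].to_numpy()
    rules_present = sorted(set(rule))
    for r in rules_present:
        for c in ("horizontal", "vertical"):
            if int(np.sum((cue == c) & (rule == r))) < 2:
                raise ValueError(
                    f"need >= 2 trials of each trial type; cue={c!r} rule={r!r} is short"
                )

    rng = np.random.default_rng(cfg.seed)
    areas = np.concatenate(
        [np.repeat(a, n) for a, n in cfg.n_neurons_per_area.items()]
    )
    n_neurons = len(areas)
    n_trials = behavior.n_trials
    n_bins = cfg.n_bins

    preferred_bin = rng.integers(0, n_bins, size=n_neurons)
    is_selective = rng.random(n_neurons) < cfg.fraction_selective
    pref_cue = np.array(["horizontal", "vertical"])[rng.integers(0, 2, n_neurons)]
    pref_rule = np.array(rules_present)[rng.integers(0, len(rules_present), n_neurons)]
    pref_choice = np.array(
        [correct_side_for(c, r) for c, r in zip(pref_cue, pref_rule)]
    )
    pref_type = np.array(
        [
            f"{c}|{r}" if sel else ""
            for c, r, sel in zip(pref_cue, pref_rule, is_selective)
        ]
    )

    bins = np.arange(n_bins)
    tuning = np.exp(
        -((bins[None, :] - preferred_bin[:, None]) ** 2)
        / (2.0 * cfg.tuning_width_bins**2)
    )  # [neurons, bins]

    boost = np.zeros((n_neurons, n_trials), dtype=bool)
    for i in range(n_neurons):
        if is_selective[i]:
            boost[i] = _preferred_type_match(
                cfg.selectivity_mode, cue, rule, choice,
                pref_cue[i], pref_rule[i], pref_choice[i],
            )

    amp = cfg.peak_rate + cfg.selectivity_strength * boost  # [neurons, trials]
    mean = cfg.baseline_rate + amp[:, :, None] * tuning[:, None, :]

    if cfg.noise_alignment == "signal":
        # information-limiting construction: the latent lives exactly in the
        # signal subspace — selective neurons only, signed by preference and
        # scaled by each neuron's tuning curve, so no combination of neurons
        # can estimate and cancel the shared fluctuation
        direction = np.where(pref_choice == "right", 1.0, -1.0)
        direction[~is_selective] = 0.0
        loadings = cfg.shared_noise_loading * direction
    else:
        loadings = np.full(n_neurons, cfg.shared_noise_loading)

    if cfg.per_area_latents:
        area_names = list(cfg.n_neurons_per_area)
        z_by_area = rng.standard_normal((len(area_names), n_trials))
        area_idx = np.array([area_names.index(a) for a in areas])
        z = z_by_area[area_idx]  # [neurons, trials]
    else:
        z = np.broadcast_to(rng.standard_normal(n_trials), (n_neurons, n_trials))

    shared = (loadings[:, None] * z)[:, :, None]
    if cfg.noise_alignment == "signal":
        shared = shared * tuning[:, None, :]
    activity = (
        mean
        + shared
        + rng.normal(0.0, cfg.private_noise_sd, size=(n_neurons, n_trials, n_bins))
    )
    if cfg.clip:
        activity = np.maximum(activity, 0.0)

    bin_edges = np.arange(n_bins + 1, dtype=float) * bin_size_cm
    binned = BinnedActivity(
        activity=activity, area=areas, bin_edges=bin_edges, trial_meta=meta
    )
    truth = GroundTruth(
        is_selective=is_selective,
        preferred_trial_type=pref_type,
        preferred_bin=preferred_bin,
        preferred_cue=pref_cue,
        preferred_rule=pref_rule,
        preferred_choice=pref_choice,
        noise_loadings=loadings,
        expected_noise_correlation=cfg.expected_noise_correlation,
    )
    return binned, truth
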