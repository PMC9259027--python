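"""Core data containers for Y-maze behavior and population-imaging analyses.

The task is a two-alternative visual discrimination in a virtual Y-maze:
a wall cue (horizontal or vertical grating) instructs a left or right arm
choice. Under Rule A, horizontal gratings reward a left choice and vertical
gratings a right choice; Rule B reverses both associations. In the switching
task the rule alternates in unsignaled blocks within a session.

Neural data enter the pipeline as deconvolved activity spatially binned
along the long maze axis (``activity[neurons, trials, bins]``), tagged with
a cortical area per neuron and per-trial task variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CUES = ("horizontal", "vertical")
RULES = ("A", "B")
SIDES = ("left", "right")
LASER_TARGETS = ("none", "control", "S1", "RSC", "PPC")
TASK_KINDS = ("simple", "delay", "switching", "run_to_target")
AREAS = ("V1", "PPC", "RSC")

#: Rule A: horizontal -> left, vertical -> right.  Rule B reverses both.
_RULE_MAP = {
    ("horizontal", "A"): "left",
    ("vertical", "A"): "right",
    ("horizontal", "B"): "right",
    ("vertical", "B"): "left",
}


def correct_side_for(cue: str, rule: str) -> str:
    """Rewarded side for a cue under a rule."""
    return _RULE_MAP[(cue, rule)]


def cue_for_side(side: str, rule: str) -> str:
    """The cue whose rewarded side under ``rule`` is ``side``."""
    for (cue, r), s in _RULE_MAP.items():
        if r == rule and s == side:
            return cue
    raise KeyError((side, rule))


def other_side(side: str) -> str:
    return "right" if side == "left" else "left"


def other_rule(rule: str) -> str:
    return "B" if rule == "A" else "A"


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class TaskConfig:
    """Structure of one behavioral session.

    The switching-task block criteria follow the training protocol: a rule
    switch requires at least ``switch_min_trials`` trials since the previous
    switch (or session start), at least ``switch_perf_threshold`` fraction
    correct over the last ``switch_window`` trials, and a correct choice on
    the immediately preceding trial.
    """

    task_kind: str = "simple"
    n_trials: int = 200
    guided_fraction: float = 0.0
    switch_min_trials: int = 75
    switch_window: int = 30
    switch_perf_threshold: float = 0.85
    bias_correction_run: int = 5
    initial_rule: str = "A"
    delay_onset_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        _check_prob("guided_fraction", self.guided_fraction)
        _check_prob("switch_perf_threshold", self.switch_perf_threshold)
        if self.switch_min_trials < self.switch_window:
            raise ValueError("switch_min_trials must be >= switch_window")
        if self.initial_rule not in RULES:
            raise ValueError(f"unknown rule {self.initial_rule!r}")
        if self.task_kind != "switching":
            defaults = TaskConfig.__dataclass_fields__
            for name in ("switch_min_trials", "switch_window", "switch_perf_threshold"):
                if getattr(self, name) != defaults[name].default:
                    raise ValueError(
                        f"{name} customized but task_kind={self.task_kind!r} never switches rules"
                    )
        if self.delay_onset_fraction is not None:
            if self.task_kind != "delay":
                raise ValueError("delay_onset_fraction only applies to the delay task")
            _check_prob("delay_onset_fraction", self.delay_onset_fraction)


@dataclass
class AgentConfig:
    """Stochastic choice policy standing in for the mouse.

    The agent picks the rewarded side with probability ``p_correct``; after
    each (unsignaled) rule switch its effective accuracy ramps linearly back
    up from chance over ``post_switch_relearn_trials`` trials, reproducing
    the drop-and-recovery dynamics around switches. On lapse trials the
    choice ignores the cue and goes left with probability
    ``(1 + side_bias) / 2``.
    """

    p_correct: float = 0.9
    side_bias: float = 0.0
    lapse_rate: float = 0.0
    post_switch_relearn_trials: int = 0

    def __post_init__(self) -> None:
        _check_prob("p_correct", self.p_correct)
        _check_prob("lapse_rate", self.lapse_rate)
        if not -1.0 <= self.side_bias <= 1.0:
            raise ValueError("side_bias must be in [-1, 1]")
        if self.post_switch_relearn_trials < 0:
            raise ValueError("post_switch_relearn_trials must be >= 0")


@dataclass
class InhibitionConfig:
    """Per-trial laser-target assignment and its behavioral effect.

    Mirrors the interleaved-inhibition design: roughly half the laser trials
    go to an off-cortex control spot, the rest uniformly to cortical
    targets. ``p_correct_drop`` maps a target to the drop in the agent's
    effective accuracy on trials with that target.
    """

    targets: tuple[str, ...] = ("S1", "RSC", "PPC")
    control_fraction: float = 0.5
    p_correct_drop: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.targets:
            if t not in LASER_TARGETS or t in ("none", "control"):
                raise ValueError(f"invalid cortical target {t!r}")
        _check_prob("control_fraction", self.control_fraction)


@dataclass
class TrialRecord:
    index: int
    cue: str
    rule: str
    correct_side: str
    choice: str
    correct: bool
    guided: bool
    laser_target: str = "none"
    forced_by_bias_correction: bool = False

    def __post_init__(self) -> None:
        if self.cue not in CUES:
            raise ValueError(f"unknown cue {self.cue!r}")
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.correct_side not in SIDES or self.choice not in SIDES:
            raise ValueError("sides must be 'left' or 'right'")
        if self.laser_target not in LASER_TARGETS:
            raise ValueError(f"unknown laser_target {self.laser_target!r}")
        if self.correct != (self.choice == self.correct_side):
            raise ValueError("correct flag inconsistent with choice vs correct_side")


@dataclass
class SessionBehavior:
    """Ordered trial records for one session."""

    session_id: str
    mouse_id: str
    trials: list[TrialRecord]

    def __post_init__(self) -> None:
        for i, tr in enumerate(self.trials):
            if tr.index != i:
                raise ValueError("trial indices must be consecutive from 0")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def correct(self) -> np.ndarray:
        return np.array([t.correct for t in self.trials], dtype=bool)

    @property
    def guided(self) -> np.ndarray:
        return np.array([t.guided for t in self.trials], dtype=bool)

    def rule_switch_trials(self) -> list[int]:
        """Indices of the first trial of each new rule block."""
        return [
            t.index
            for prev, t in zip(self.trials, self.trials[1:])
            if t.rule != prev.rule
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "session_id": self.session_id,
                    "mouse_id": self.mouse_id,
                    "trial_index": t.index,
                    "cue": t.cue,
                    "rule": t.rule,
                    "correct_side": t.correct_side,
                    "choice": t.choice,
                    "correct": t.correct,
                    "guided": t.guided,
                    "laser_target": t.laser_target,
                    "forced_by_bias_correction": t.forced_by_bias_correction,
                }
                for t in self.trials
            ]
        )

    def trial_meta(self) -> pd.DataFrame:
        """Per-trial task variables in the layout used by neural analyses."""
        df = self.to_frame()
        return df[
            ["cue", "rule", "correct_side", "choice", "correct", "guided", "laser_target"]
        ].reset_index(drop=True)


@dataclass
class RunningTrace:
    """Spatially binned running kinematics, one row per trial.

    Channels are treadmill pitch, roll, and yaw velocities (arbitrary
    velocity units) plus lateral maze position (maze-width units), each of
    shape ``[n_trials, n_bins]``.
    """

    pitch: np.ndarray
    roll: np.ndarray
    yaw: np.ndarray
    lateral: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.pitch, self.roll, self.yaw, self.lateral)}
        if len(shapes) != 1:
            raise ValueError("running channels must share one [n_trials, n_bins] shape")
        if len(self.bin_edges) != self.pitch.shape[1] + 1:
            raise ValueError("bin_edges must have n_bins + 1 entries")

    @property
    def n_trials(self) -> int:
        return self.pitch.shape[0]

    @property
    def n_bins(self) -> int:
        return self.pitch.shape[1]


@dataclass
class NeuralGenConfig:
    """Parameters of the synthetic population-activity generator.

    Each neuron carries a Gaussian spatial tuning bump (a transient place
    field, so the population forms a sequence along the maze). Selective
    neurons get their bump amplitude raised by ``selectivity_strength``
    event-rate units on their preferred trial type. A shared standard-normal
    latent per trial, entering every neuron with loading
    ``shared_noise_loading``, generates pairwise noise correlations of
    expected magnitude lambda^2 / (lambda^2 + sigma^2) before clipping.
    """

    n_neurons_per_area: Mapping[str, int] = field(
        default_factory=lambda: {"V1": 40, "PPC": 40, "RSC": 40}
    )
    n_bins: int = 46
    tuning_width_bins: float = 3.0
    peak_rate: float = 1.0
    selectivity_strength: float = 1.0
    fraction_selective: float = 0.35
    shared_noise_loading: float = 0.3
    private_noise_sd: float = 1.0
    baseline_rate: float = 0.05
    selectivity_mode: str = "single"  # single | cue | choice
    noise_alignment: str = "uniform"  # uniform | signal
    per_area_latents: bool = False
    clip: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.n_neurons_per_area:
            raise ValueError("n_neurons_per_area must not be empty")
        for area, n in self.n_neurons_per_area.items():
            if n <= 0:
                raise ValueError(f"neuron count for {area!r} must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")
        if self.tuning_width_bins <= 0:
            raise ValueError("tuning_width_bins must be positive")
        if self.selectivity_strength < 0:
            raise ValueError("selectivity_strength must be >= 0")
        _check_prob("fraction_selective", self.fraction_selective)
        if self.shared_noise_loading < 0:
            raise ValueError("shared_noise_loading must be >= 0")
        if self.private_noise_sd <= 0:
            raise ValueError("private_noise_sd must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.selectivity_mode not in ("single", "cue", "choice"):
            raise ValueError(f"unknown selectivity_mode {self.selectivity_mode!r}")
        if self.noise_alignment not in ("uniform", "signal"):
            raise ValueError(f"unknown noise_alignment {self.noise_alignment!r}")

    @property
    def expected_noise_correlation(self) -> float:
        lam2 = self.shared_noise_loading**2
        return lam2 / (lam2 + self.private_noise_sd**2)


@dataclass
class GroundTruth:
    """Generator assignments, kept for parameter-recovery tests."""

    is_selective: np.ndarray
    preferred_trial_type: np.ndarray  # strings like "horizontal|A", "" if none
    preferred_bin: np.ndarray
    preferred_cue: np.ndarray
    preferred_rule: np.ndarray
    preferred_choice: np.ndarray
    noise_loadings: np.ndarray
    expected_noise_correlation: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.expected_noise_correlation <= 1.0:
            raise ValueError("expected_noise_correlation must be in [-1, 1]")


@dataclass
class BinnedActivity:
    """Deconvolved activity binned along the long maze axis.

    ``activity`` is ``[neurons, trials, bins]`` and nonnegative;
    ``trial_meta`` has one row per trial with at least cue/rule/choice/
    correct/guided columns.
    """

    activity: np.ndarray
    area: np.ndarray
    bin_edges: np.ndarray
    trial_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.area = np.asarray(self.area)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.activity.ndim != 3:
            raise ValueError("activity must be [neurons, trials, bins]")
        n, t, b = self.activity.shape
        if len(self.area) != n:
            raise ValueError("area labels must match the neuron axis")
        if len(self.bin_edges) != b + 1:
            raise ValueError("bin_edges must have n_bins + 1 entries")
        if len(self.trial_meta) != t:
            raise ValueError("trial_meta rows must match the trials axis")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_trials(self) -> int:
        return self.activity.shape[1]

    @property
    def n_bins(self) -> int:
        return self.activity.shape[2]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def select_trials(self, idx: np.ndarray) -> "BinnedActivity":
        idx = np.asarray(idx)
        return BinnedActivity(
            activity=self.activity[:, idx, :],
            area=self.area,
            bin_edges=self.bin_edges,
            trial_meta=self.trial_meta.iloc[idx].reset_index(drop=True),
        )

    def select_area(self, area: str) -> "BinnedActivity":
        mask = self.area == area
        if not mask.any():
            raise ValueError(f"no neurons with area {area!r}")
        return BinnedActivity(
            activity=self.activity[mask],
            area=self.area[mask],
            bin_edges=self.bin_edges,
            trial_meta=self.trial_meta,
        )


@dataclass
class FluorescenceTrace:
    """Raw somatic and neuropil fluorescence for one neuron."""

    F: np.ndarray
    F_neuropil: np.ndarray
    fs: float
    dff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.F_neuropil = np.asarray(self.F_neuropil, dtype=float)
        if self.F.shape != self.F_neuropil.shape:
            raise ValueError("F and F_neuropil must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")


#: Maze segments used for summary statistics, in cm along the long axis:
#: first half of the Y-stem, second half of the Y-stem, and the Y-arms.
DEFAULT_SEGMENTS: dict[str, tuple[float, float]] = {
    "stem_first": (15.0, 75.0),
    "stem_second": (75.0, 150.0),
    "arms": (150.0, 220.0),
}


@dataclass
class SegmentSpec:
    """Named, non-overlapping cm ranges along the maze's long axis."""

    segments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS)
    )

    def __post_init__(self) -> None:
        ranges = sorted(self.segments.values())
        for (lo, hi) in ranges:
            if hi <= lo:
                raise ValueError("segment ranges must be increasing")
        for (_, hi), (lo, _) in zip(ranges, ranges[1:]):
            if lo < hi:
                raise ValueError("segment ranges must not overlap")

    def bin_mask(self, name: str, bin_edges: np.ndarray) -> np.ndarray:
        """Boolean mask over bins whose centers fall in the segment."""
        lo, hi = self.segments[name]
        centers = 0.5 * (np.asarray(bin_edges)[:-1] + np.asarray(bin_edges)[1:])
        mask = (centers >= lo) & (centers < hi)
        if not mask.any():
            raise ValueError(f"segment {name!r} contains no bins")
        return mask


@dataclass
class SelectivityProfile:
    """Per-neuron, per-bin trial-type selectivity statistics."""

    auroc: np.ndarray
    selectivity: np.ndarray
    p_shuffle: np.ndarray
    significant: np.ndarray
    alpha: float
    mean_activity: np.ndarray | None = None
    area: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.auroc.shape == self.selectivity.shape == self.p_shuffle.shape):
            raise ValueError("auroc/selectivity/p arrays must share one shape")


@dataclass
class SegmentSummary:
    """Selectivity statistics reduced to maze segments."""

    per_neuron: pd.DataFrame
    per_area: pd.DataFrame


@dataclass
class DecodingCurve:
    """Cross-validated decoding accuracy versus population size."""

    population_sizes: list[int]
    accuracy: dict[int, float]
    n_repetitions: dict[int, int]
    n_folds: int
    per_bin_accuracy: dict[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for size, acc in self.accuracy.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy for size {size} outside [0, 1]")


@dataclass
class NoiseCorrelationSummary:
    """Pairwise noise correlations averaged across trial types."""

    pairwise_r: np.ndarray
    area_pair_means: dict[tuple[str, str], float]
    area_pair_counts: dict[tuple[str, str], int]
    n_skipped_pairs: int = 0

    @property
    def mean_r(self) -> float:
        iu = np.triu_indices_from(self.pairwise_r, k=1)
        return float(np.nanmean(self.pairwise_r[iu]))


@dataclass
class BootstrapResult:
    """Bootstrap distribution of a statistic.

    ``sem`` is the standard deviation of the resampled means, the
    dispersion reported as the SEM throughout the pipeline.
    """

    statistic_name: str
    point_estimate: float
    boot_means: np.ndarray
    levels: str

    @property
    def n_boot(self) -> int:
        return len(self.boot_means)

    @property
    def sem(self) -> float:
        return float(np.std(self.boot_means, ddof=1)) if self.n_boot > 1 else 0.0
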