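"""End-to-end synthetic-cohort experiments.

``run_experiment`` simulates two cohorts of sessions — a "simple-only"
cohort and a "switching-experience" cohort that differ only in the
generator's selectivity and shared-noise parameters — and pushes each
session through the full analysis chain: high-performance trial selection,
per-type subsampling, single-neuron selectivity, population decoding,
noise correlations, correlation disruption, and hierarchical-bootstrap
cohort comparisons. Every stochastic stage draws its seed from a named
substream of the root seed, so adding a stage never perturbs earlier
stages' randomness and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import hb
from . import population as pop
from . import preprocess as pre
from . import selectivity as sel
from .io import write_session_csv
from .synthetic import generate_population_activity, simulate_task_session
from .types import AgentConfig, BinnedActivity, NeuralGenConfig, TaskConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_experiment", "analyze_session"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed and a name."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a two-cohort synthetic experiment."""

    seed: int = 0
    n_sessions: int = 3
    out_dir: str = "ymaze_out"
    task: dict = field(default_factory=lambda: {"task_kind": "simple", "n_trials": 250})
    agent: dict = field(default_factory=lambda: {"p_correct": 0.9})
    cohorts: dict = field(
        default_factory=lambda: {
            "simple_only": {
                "selectivity_strength": 0.6,
                "shared_noise_loading": 0.5,
            },
            "switching_experience": {
                "selectivity_strength": 1.2,
                "shared_noise_loading": 0.25,
            },
        }
    )
    neural: dict = field(default_factory=dict)  # shared generator overrides
    hp_window: int = 10
    hp_threshold: float = 0.8
    n_per_type: int = 30
    n_shuffles: int = 100
    alpha: float = 0.01
    sizes: list = field(default_factory=lambda: [5, 10, 25])
    n_repetitions: int | None = 5
    disruption_size: int | None = None  # default: all neurons
    n_boot: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def analyze_session(
    binned: BinnedActivity,
    *,
    hp_window: int = 10,
    hp_threshold: float = 0.8,
    n_per_type: int = 30,
    n_shuffles: int = 100,
    alpha: float = 0.01,
    sizes=(5, 10, 25),
    n_repetitions: int | None = 5,
    disruption_size: int | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run the neural analysis chain for one session.

    Restricts to correct trials from high-performance periods, subsamples
    to ``n_per_type`` trials per cue type, then computes the selectivity
    profile, the decoding curve, mean pairwise noise correlations, and the
    intact-minus-disrupted decoding difference.
    """
    rng = np.random.default_rng(seed)
    meta = binned.trial_meta
    correct = meta["correct"].to_numpy().astype(bool)
    hp = pre.select_high_performance_trials(correct, hp_window, hp_threshold)
    hp = hp[~meta["guided"].to_numpy().astype(bool)[hp]]
    cues = meta["cue"].to_numpy()[hp]
    keep = hp[pre.subsample_trials(cues, n_per_type, seed=int(rng.integers(2**31)))]
    sub = binned.select_trials(keep)
    labels = (sub.trial_meta["cue"] == "vertical").to_numpy()

    profile = sel.compute_selectivity_profile(
        sub, labels, n_shuffles=n_shuffles, alpha=alpha,
        seed=int(rng.integers(2**31)),
    )
    curve = pop.decode_trial_type(
        sub, labels, sizes=sizes, seed=int(rng.integers(2**31)),
        n_repetitions=n_repetitions,
    )
    corr = pop.noise_correlations(sub, labels)
    dsize = disruption_size or sub.n_neurons
    delta = pop.correlation_impact_on_decoding(
        sub, labels, size=min(dsize, sub.n_neurons),
        seed=int(rng.integers(2**31)), n_repetitions=n_repetitions,
    )
    return {
        "profile": profile,
        "decoding": curve,
        "correlations": corr,
        "disruption_delta": delta,
        "n_trials_used": int(sub.n_trials),
    }


def run_experiment(config: RunConfig) -> dict[str, Any]:
    """Simulate and analyze two synthetic cohorts; write a report bundle.

    Outputs under ``config.out_dir``: per-session behavior CSVs, tidy
    ``selectivity.csv`` / ``decoding.csv`` / ``correlations.csv``,
    ``summary.json`` with cohort means and bootstrap comparisons, and
    ``manifest.json`` with the config, its hash, and all stage seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    try:
        sel_rows, dec_rows, corr_rows = [], [], []
        cohort_stats: dict[str, dict[str, Any]] = {}
        for cohort, overrides in config.cohorts.items():
            per_session = {
                "mean_selectivity": [],
                "fraction_selective": [],
                "mean_noise_corr": [],
                "disruption_delta": [],
                "selectivity_by_neuron": [],
            }
            decoding_by_size: dict[int, list[float]] = {}
            for s in range(config.n_sessions):
                stage = f"simulate:{cohort}:{s}"
                task = TaskConfig(**config.task)
                agent = AgentConfig(**config.agent)
                session = simulate_task_session(
                    task, agent,
                    seed=stage_seed(config.seed, stage),
                    session_id=f"{cohort}_s{s}", mouse_id=f"{cohort}_m{s % 3}",
                )
                write_session_csv(session, out / f"behavior_{cohort}_s{s}.csv")
                gen_kwargs = {**config.neural, **overrides}
                cfg = NeuralGenConfig(
                    **gen_kwargs, seed=stage_seed(config.seed, f"neural:{cohort}:{s}")
                )
                binned, _truth = generate_population_activity(session, cfg)

                stage = f"analyze:{cohort}:{s}"
                res = analyze_session(
                    binned,
                    hp_window=config.hp_window,
                    hp_threshold=config.hp_threshold,
                    n_per_type=config.n_per_type,
                    n_shuffles=config.n_shuffles,
                    alpha=config.alpha,
                    sizes=config.sizes,
                    n_repetitions=config.n_repetitions,
                    disruption_size=config.disruption_size,
                    seed=stage_seed(config.seed, stage),
                )
                profile = res["profile"]
                neuron_sel = profile.selectivity.mean(axis=1)
                per_session["selectivity_by_neuron"].append(neuron_sel)
                per_session["mean_selectivity"].append(float(neuron_sel.mean()))
                # per-bin share of significant neurons, averaged over bins
                per_session["fraction_selective"].append(
                    float(profile.significant.mean())
                )
                per_session["mean_noise_corr"].append(res["correlations"].mean_r)
                per_session["disruption_delta"].append(res["disruption_delta"])
                for size, acc in res["decoding"].accuracy.items():
                    decoding_by_size.setdefault(size, []).append(acc)
                    dec_rows.append(
                        {"cohort": cohort, "session": s, "size": size, "accuracy": acc}
                    )
                sel_rows.append(
                    {
                        "cohort": cohort,
                        "session": s,
                        "mean_selectivity": per_session["mean_selectivity"][-1],
                        "fraction_selective": per_session["fraction_selective"][-1],
                    }
                )
                corr_rows.append(
                    {
                        "cohort": cohort,
                        "session": s,
                        "mean_noise_corr": per_session["mean_noise_corr"][-1],
                        "disruption_delta": per_session["disruption_delta"][-1],
                    }
                )
            cohort_stats[cohort] = {
                **{
                    k: float(np.mean(v))
                    for k, v in per_session.items()
                    if k != "selectivity_by_neuron"
                },
                "decoding_accuracy": {
                    int(k): float(np.mean(v)) for k, v in decoding_by_size.items()
                },
                "_neuron_groups": per_session["selectivity_by_neuron"],
            }

        stage = "bootstrap"
        names = list(cohort_stats)
        boots = {
            c: hb.hierarchical_bootstrap(
                cohort_stats[c].pop("_neuron_groups"),
                n_boot=config.n_boot,
                seed=stage_seed(config.seed, f"boot:{c}"),
                levels="sessions->neurons",
                name="mean_selectivity",
            )
            for c in names
        }
        comparison = {
            "statistic": "mean_selectivity",
            "cohorts": names,
            "estimates": {c: boots[c].point_estimate for c in names},
            "sems": {c: boots[c].sem for c in names},
            "p_two_tailed": hb.bootstrap_p(boots[names[0]], boots[names[1]])
            if len(names) == 2
            else None,
        }

        stage = "write"
        pd.DataFrame(sel_rows).to_csv(out / "selectivity.csv", index=False)
        pd.DataFrame(dec_rows).to_csv(out / "decoding.csv", index=False)
        pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
        summary = {"cohorts": cohort_stats, "comparison": comparison}
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        config_dict = config.to_dict()
        manifest = {
            "config": config_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(config_dict, sort_keys=True).encode()
            ).hexdigest(),
            "root_seed": config.seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return summary
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
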