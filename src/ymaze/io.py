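"""Reading and writing of session CSVs and activity bundles.

A behavioral session is a CSV with one row per trial; an activity bundle is
a single NPZ file holding the binned activity tensor, per-neuron area
labels, bin edges, per-trial metadata, and optionally running channels,
generator ground truth, and the generator configuration echoed as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CUES,
    LASER_TARGETS,
    RULES,
    SIDES,
    BinnedActivity,
    GroundTruth,
    RunningTrace,
    SessionBehavior,
    TrialRecord,
)

SESSION_COLUMNS = [
    "session_id",
    "mouse_id",
    "trial_index",
    "cue",
    "rule",
    "correct_side",
    "choice",
    "correct",
    "guided",
    "laser_target",
    "forced_by_bias_correction",
]

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


def write_session_csv(session: SessionBehavior, path: str | Path) -> None:
    session.to_frame().to_csv(path, index=False)


def _parse_bool(value, column: str, row: int) -> bool:
    token = str(value).strip().lower()
    if token not in _BOOL_TOKENS:
        raise ValueError(f"row {row}: invalid boolean {value!r} in column {column!r}")
    return _BOOL_TOKENS[token]


def read_session_csv(path: str | Path) -> SessionBehavior:
    """Read a session CSV, validating the schema row by row.

    Row numbers in error messages are 1-based data rows (the header is row
    0). Unknown enum tokens, missing values, and non-consecutive trial
    indices are rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    trials = []
    session_id = mouse_id = None
    enums = {"cue": CUES, "rule": RULES, "correct_side": SIDES, "choice": SIDES,
             "laser_target": LASER_TARGETS}
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        rec = rec._asdict()
        for col in SESSION_COLUMNS:
            if rec[col] == "":
                raise ValueError(f"row {row}: missing value in column {col!r}")
        for col, allowed in enums.items():
            if rec[col] not in allowed:
                raise ValueError(
                    f"row {row}: unknown {col} token {rec[col]!r} (allowed: {allowed})"
                )
        try:
            index = int(rec["trial_index"])
        except ValueError:
            raise ValueError(f"row {row}: trial_index {rec['trial_index']!r} not an integer")
        trials.append(
            TrialRecord(
                index=index,
                cue=rec["cue"],
                rule=rec["rule"],
                correct_side=rec["correct_side"],
                choice=rec["choice"],
                correct=_parse_bool(rec["correct"], "correct", row),
                guided=_parse_bool(rec["guided"], "guided", row),
                laser_target=rec["laser_target"],
                forced_by_bias_correction=_parse_bool(
                    rec["forced_by_bias_correction"], "forced_by_bias_correction", row
                ),
            )
        )
        session_id, mouse_id = rec["session_id"], rec["mouse_id"]
    if not trials:
        raise ValueError("session CSV contains no trials")
    return SessionBehavior(session_id=session_id, mouse_id=mouse_id, trials=trials)


def write_bundle(
    path: str | Path,
    activity: BinnedActivity,
    running: RunningTrace | None = None,
    truth: GroundTruth | None = None,
    config=None,
) -> None:
    """Write a binned-activity bundle (plus optional extras) as one NPZ."""
    payload: dict[str, np.ndarray] = {
        "activity": activity.activity,
        "area": activity.area.astype(str),
        "bin_edges": activity.bin_edges,
    }
    for col in activity.trial_meta.columns:
        values = activity.trial_meta[col].to_numpy()
        if values.dtype == object:
            values = values.astype(str)  # keep the NPZ pickle-free
        payload[f"trial_{col}"] = values
    if running is not None:
        for name in ("pitch", "roll", "yaw", "lateral"):
            payload[f"running_{name}"] = getattr(running, name)
    if truth is not None:
        for f in dataclasses.fields(truth):
            payload[f"truth_{f.name}"] = np.asarray(getattr(truth, f.name))
    if config is not None:
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
        payload["config_json"] = np.array(json.dumps(config, default=str))
    np.savez(path, **payload)


def read_bundle(
    path: str | Path,
) -> tuple[BinnedActivity, RunningTrace | None, GroundTruth | None, dict | None]:
    """Read a bundle written by :func:`write_bundle`, validating shapes."""
    with np.load(path, allow_pickle=False) as data:
        for key in ("activity", "area", "bin_edges"):
            if key not in data:
                raise ValueError(f"bundle lacks required dataset {key!r}")
        activity = data["activity"]
        if activity.ndim != 3:
            raise ValueError("activity must be [neurons, trials, bins]")
        n_trials = activity.shape[1]
        meta_cols = {
            k[len("trial_"):]: data[k] for k in data.files if k.startswith("trial_")
        }
        for col, values in meta_cols.items():
            if len(values) != n_trials:
                raise ValueError(
                    f"trial metadata column {col!r} has {len(values)} entries, "
                    f"expected {n_trials} (trials axis mismatch)"
                )
        trial_meta = pd.DataFrame(meta_cols) if meta_cols else pd.DataFrame(
            index=range(n_trials)
        )
        binned = BinnedActivity(
            activity=activity,
            area=data["area"],
            bin_edges=data["bin_edges"],
            trial_meta=trial_meta,
        )
        running = None
        if "running_pitch" in data:
            running = RunningTrace(
                pitch=data["running_pitch"],
                roll=data["running_roll"],
                yaw=data["running_yaw"],
                lateral=data["running_lateral"],
                bin_edges=data["bin_edges"][: data["running_pitch"].shape[1] + 1],
            )
        truth = None
        if "truth_is_selective" in data:
            truth = GroundTruth(
                is_selective=data["truth_is_selective"],
                preferred_trial_type=data["truth_preferred_trial_type"],
                preferred_bin=data["truth_preferred_bin"],
                preferred_cue=data["truth_preferred_cue"],
                preferred_rule=data["truth_preferred_rule"],
                preferred_choice=data["truth_preferred_choice"],
                noise_loadings=data["truth_noise_loadings"],
                expected_noise_correlation=float(
                    data["truth_expected_noise_correlation"]
                ),
            )
        config = json.loads(str(data["config_json"])) if "config_json" in data else None
    return binned, running, truth, config
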