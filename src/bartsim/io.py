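"""CSV/JSON interchange: trial logs, traces, event tables, configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .scr import SCTrace
from .task import Condition, Reward, Risk, TaskSchedule

__all__ = [
    "write_trial_log",
    "read_trial_log",
    "write_trace_csv",
    "read_trace_csv",
    "write_events_csv",
    "read_events_csv",
    "load_config",
    "schedule_from_config",
]

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "risk_level",
    "reward_level",
    "response_time_ms",
    "picture_index",
    "uniform_draw",
    "outcome",
    "payoff_cents",
]


def write_trial_log(
    path: "str | Path",
    trials: pd.DataFrame,
    schedule: TaskSchedule,
    seed: Optional[int] = None,
) -> None:
    """One row per trial with a comment header recording seed and schedule."""
    path = Path(path)
    header = f"# seed={seed} schedule={schedule.hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        trials[TRIAL_COLUMNS].to_csv(fh, index=False)


def read_trial_log(path: "str | Path") -> tuple[pd.DataFrame, dict]:
    """Returns the trial table and the parsed header metadata."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = None if v == "None" else v
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    return df, meta


def write_trace_csv(path: "str | Path", trace: SCTrace) -> None:
    pd.DataFrame({"time_s": trace.time_s, "conductance_uS": trace.samples}).to_csv(
        path, index=False
    )


def read_trace_csv(path: "str | Path", events: Optional[list] = None) -> SCTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trace CSV needs at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return SCTrace(
        sampling_rate=fs,
        samples=df["conductance_uS"].to_numpy(dtype=float),
        events=events or [],
    )


def write_events_csv(path: "str | Path", events: list) -> None:
    rows = [
        {"onset_s": onset, "risk_level": c.risk.value, "reward_level": c.reward.value}
        for onset, c in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path: "str | Path") -> list:
    df = pd.read_csv(path)
    return [
        (
            float(r.onset_s),
            Condition(Risk(str(r.risk_level)), Reward(str(r.reward_level))),
        )
        for r in df.itertuples()
    ]


def load_config(path: "str | Path") -> dict:
    with open(path) as fh:
        return json.load(fh)


def schedule_from_config(config: dict) -> TaskSchedule:
    """Build a TaskSchedule from a config dict's ``schedule`` section."""
    fields = config.get("schedule", {})
    return TaskSchedule(**fields)
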