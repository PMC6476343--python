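"""Generative mechanics of the risk/reward-decoupled balloon task.

A balloon inflates through ``n_pictures`` discrete growth steps over a fixed
6-second window.  Each picture ``k`` carries a cumulative explosion
probability ``p(k)`` (set by the risk level of the trial) and a cash-out
reward ``r(k)`` in euro cents (set by the reward level).  The participant --
or a simulated agent -- makes a single timed cash-out response; the outcome
is decided by comparing one uniform draw against ``p(k)`` at the response
picture only.  Conditions form a 2x2 design (risk x reward) presented in a
pseudorandom order with at most two consecutive repeats of any condition.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Risk",
    "Reward",
    "Condition",
    "CONDITIONS",
    "TaskSchedule",
    "TrialRecord",
    "draw_outcome",
    "generate_condition_sequence",
]


class Risk(str, Enum):
    LOW = "low"
    HIGH = "high"


class Reward(str, Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the 2x2 risk x reward design."""

    risk: Risk
    reward: Reward

    @property
    def label(self) -> str:
        return f"{self.risk.value}_risk/{self.reward.value}_reward"


#: The four cells of the design, in a fixed canonical order.
CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(risk, reward) for risk in Risk for reward in Reward
)


def _as_risk(level: "Risk | str") -> Risk:
    return Risk(level.value if isinstance(level, Risk) else str(level).lower())


def _as_reward(level: "Reward | str") -> Reward:
    return Reward(level.value if isinstance(level, Reward) else str(level).lower())


@dataclass(frozen=True)
class TaskSchedule:
    """Per-picture probability/reward schedules and trial timing.

    Defaults encode the published task: 128 balloon pictures over a 6000 ms
    inflation window, low-risk explosion probability ``k/128`` and high-risk
    probability ``1.5 k/128`` capped at a 0.99 plateau (pictures 85-127) with
    certain explosion at the last picture; rewards grow linearly at 5 cents
    (low reward) or 25 cents (high reward) per picture.
    """

    n_pictures: int = 128
    balloon_duration_ms: float = 6000.0
    cue_duration_ms: float = 500.0
    fixation_ms: float = 250.0
    feedback_ms: float = 2500.0
    high_risk_multiplier: float = 1.5
    high_risk_plateau: float = 0.99
    low_reward_unit_cents: float = 5.0
    high_reward_unit_cents: float = 25.0

    def __post_init__(self) -> None:
        if self.n_pictures < 1:
            raise ValueError("n_pictures must be >= 1")
        for name in ("balloon_duration_ms", "cue_duration_ms", "fixation_ms", "feedback_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.high_risk_plateau < 1.0:
            raise ValueError("high_risk_plateau must lie strictly between 0 and 1")
        if self.low_reward_unit_cents <= 0 or self.high_reward_unit_cents <= 0:
            raise ValueError("reward units must be > 0")
        if self.high_risk_multiplier <= 0:
            raise ValueError("high_risk_multiplier must be > 0")

    # -- picture/time geometry -------------------------------------------

    @property
    def picture_duration_ms(self) -> float:
        """Duration of one balloon picture (6000/128 = 46.875 ms by default)."""
        return self.balloon_duration_ms / self.n_pictures

    def time_to_picture(self, t_ms: float) -> int:
        """Map a response time in (0, balloon_duration_ms] to a picture index.

        Picture ``k`` is on screen during ``((k-1)*dt, k*dt]``, so the mapping
        is ``ceil(t / dt)``, clamped to ``[1, n_pictures]``.
        """
        if not 0.0 < t_ms <= self.balloon_duration_ms:
            raise ValueError(
                f"response time {t_ms} ms outside (0, {self.balloon_duration_ms}]"
            )
        k = math.ceil(t_ms / self.picture_duration_ms)
        return min(max(k, 1), self.n_pictures)

    def picture_to_time(self, picture_index: int) -> float:
        """Latest response time (ms) that maps to ``picture_index``."""
        self._check_picture(picture_index)
        return picture_index * self.picture_duration_ms

    # -- probability and reward schedules --------------------------------

    def _check_picture(self, picture_index: int) -> None:
        if not 1 <= int(picture_index) <= self.n_pictures:
            raise ValueError(
                f"picture_index {picture_index} outside [1, {self.n_pictures}]"
            )
        if int(picture_index) != picture_index:
            raise ValueError("picture_index must be an integer")

    def explosion_probability(self, risk_level: "Risk | str", picture_index: int) -> float:
        """Cumulative explosion probability assigned to a balloon picture.

        Low risk: ``k / n``.  High risk: the low-risk value times
        ``high_risk_multiplier``, capped at the plateau (0.99) for all but the
        last picture, where the probability is 1 under both risk levels.
        """
        self._check_picture(picture_index)
        k, n = int(picture_index), self.n_pictures
        base = k / n
        if _as_risk(risk_level) is Risk.LOW:
            return base
        if k == n:
            return 1.0
        return min(self.high_risk_multiplier * base, self.high_risk_plateau)

    def reward_value(self, reward_level: "Reward | str", picture_index: int) -> float:
        """Cash-out reward (euro cents) at a balloon picture: 5k or 25k cents."""
        self._check_picture(picture_index)
        unit = (
            self.low_reward_unit_cents
            if _as_reward(reward_level) is Reward.LOW
            else self.high_reward_unit_cents
        )
        return unit * int(picture_index)

    def hash(self) -> str:
        """Short content hash of the schedule, recorded in trial-log headers."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class TrialRecord:
    """One simulated trial of the task."""

    participant_id: str
    trial_index: int  # 1-based
    condition: Condition
    response_time_ms: Optional[float]
    picture_index: int
    uniform_draw: float
    outcome: str  # "cashout" | "explosion"
    payoff_cents: float = field(default=0.0)


def draw_outcome(
    schedule: TaskSchedule,
    condition: Condition,
    picture_index: int,
    rng: np.random.Generator,
) -> tuple[str, float, float]:
    """Decide one trial: draw u ~ U(0,1) and explode iff ``u < p(k)``.

    The strict-inequality convention makes p = 0 explosion-free and p = 1
    explosion almost surely.  Returns ``(outcome, payoff_cents, uniform_draw)``;
    the draw is kept for audit.
    """
    p = schedule.explosion_probability(condition.risk, picture_index)
    u = float(rng.random())
    if u < p:
        return "explosion", 0.0, u
    return "cashout", schedule.reward_value(condition.reward, picture_index), u


def generate_condition_sequence(
    n_per_condition: int,
    rng: "np.random.Generator | int",
    max_restarts: int = 1000,
) -> list[Condition]:
    """Pseudorandom condition order: exact counts, no condition 3x in a row.

    Built by sequential sampling among the conditions that still have trials
    remaining and would not create a run of three; rare dead ends restart the
    sequence (bounded by ``max_restarts``).
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    conds = list(CONDITIONS)
    for _ in range(max_restarts):
        counts = {c: n_per_condition for c in conds}
        seq: list[Condition] = []
        ok = True
        for _ in range(4 * n_per_condition):
            allowed = [
                c
                for c in conds
                if counts[c] > 0
                and not (len(seq) >= 2 and seq[-1] == c and seq[-2] == c)
            ]
            if not allowed:
                ok = False
                break
            choice = allowed[int(rng.integers(len(allowed)))]
            seq.append(choice)
            counts[choice] -= 1
        if ok:
            return seq
    raise RuntimeError(
        f"could not satisfy sequence constraints after {max_restarts} restarts"
    )
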