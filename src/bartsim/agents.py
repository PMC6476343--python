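"""Simulated participants ("agents") playing full sessions of the task.

Agents stand in for human participants: each trial they emit a cash-out
response time, which the task maps to a balloon picture and resolves with a
single uniform draw.  Three policy families are provided:

``fixed_time_gaussian``
    Truncated-Gaussian response times around fixed per-condition means.
``ev_optimal``
    Means pinned at the analytic expected-value optimum of each condition.
``trait_linked``
    Condition means produced by the same linear predictor the moderation
    model fits (risk, reward, SCR covariate, impulsivity score and their
    interactions), yielding a recoverable ground truth for the statistics
    chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .analytics import expected_value_curve
from .task import (
    CONDITIONS,
    Condition,
    TaskSchedule,
    TrialRecord,
    draw_outcome,
    generate_condition_sequence,
)

__all__ = [
    "Participant",
    "AgentPolicy",
    "fixed_time_policy",
    "ev_optimal_policy",
    "trait_linked_policy",
    "SessionResult",
    "simulate_session",
    "behavioral_summary_table",
]

RT_BOUNDS = (0.0, 6000.0)  # open at 0, closed at 6000


@dataclass(frozen=True)
class Participant:
    """A (simulated) participant with latent traits.

    ``bis_total`` is the impulsivity questionnaire total (30 items, 4-point
    scale, range 30-120); ``scr_reactivity`` scales the participant's
    anticipatory skin-conductance responses; ``risk_preference`` shifts all
    response times (ms, positive = later cash-outs).
    """

    participant_id: str
    bis_total: float = 58.43
    scr_reactivity: float = 1.0
    risk_preference: float = 0.0


@dataclass(frozen=True)
class AgentPolicy:
    """Response-time policy: per-condition truncated-Gaussian RTs."""

    family: str
    mean_rt_ms: Mapping[Condition, float]
    sd_rt_ms: float = 0.0
    trait_coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd_rt_ms < 0:
            raise ValueError("sd_rt_ms must be >= 0")
        for cond, mu in self.mean_rt_ms.items():
            if not np.isfinite(mu):
                raise ValueError(f"non-finite mean RT for {cond}")


def fixed_time_policy(
    mean_rt_ms: Mapping[Condition, float], sd_rt_ms: float = 250.0
) -> AgentPolicy:
    return AgentPolicy("fixed_time_gaussian", dict(mean_rt_ms), sd_rt_ms)


def ev_optimal_policy(schedule: TaskSchedule, sd_rt_ms: float = 0.0) -> AgentPolicy:
    """Policy whose mean RT is each condition's analytic EV optimum."""
    means = {
        c: float(expected_value_curve(schedule, c).optimal_time_ms) for c in CONDITIONS
    }
    return AgentPolicy("ev_optimal", means, sd_rt_ms)


def trait_linked_policy(
    participant: Participant,
    scr_by_condition: Mapping[Condition, float],
    coefficients: Mapping[str, float],
    sd_rt_ms: float = 250.0,
) -> AgentPolicy:
    """Condition-mean RTs from the moderation model's linear predictor.

    ``coefficients`` uses the fixed-effect term names of the statistics
    module ("Intercept", "risk", "reward", "scr", "bis", "risk:scr", ...,
    "risk:scr:bis"); risk/reward are coded low = 0, high = 1.  Missing terms
    default to zero.
    """
    c = dict(coefficients)
    means = {}
    for cond in CONDITIONS:
        risk = 1.0 if cond.risk.value == "high" else 0.0
        reward = 1.0 if cond.reward.value == "high" else 0.0
        scr = float(scr_by_condition[cond])
        bis = participant.bis_total
        mu = (
            c.get("Intercept", 0.0)
            + c.get("risk", 0.0) * risk
            + c.get("reward", 0.0) * reward
            + c.get("scr", 0.0) * scr
            + c.get("bis", 0.0) * bis
            + c.get("reward:scr", 0.0) * reward * scr
            + c.get("reward:bis", 0.0) * reward * bis
            + c.get("scr:bis", 0.0) * scr * bis
            + c.get("risk:scr", 0.0) * risk * scr
            + c.get("risk:bis", 0.0) * risk * bis
            + c.get("reward:scr:bis", 0.0) * reward * scr * bis
            + c.get("risk:scr:bis", 0.0) * risk * scr * bis
            + participant.risk_preference
        )
        means[cond] = mu
    return AgentPolicy("trait_linked", means, sd_rt_ms, dict(c))


@dataclass
class SessionResult:
    """All trials of one simulated session plus per-condition summaries."""

    participant_id: str
    trials: pd.DataFrame  # one row per TrialRecord
    summary: pd.DataFrame  # condition x {mean_rt_ms, success_prop, earnings_cents}
    seed: Optional[int] = None


def _draw_rt(policy: AgentPolicy, condition: Condition, rng: np.random.Generator) -> float:
    """Truncated-Gaussian RT on (0, 6000]; degenerate SD returns the mean."""
    lo, hi = RT_BOUNDS
    mu = float(policy.mean_rt_ms[condition])
    if policy.sd_rt_ms == 0.0:
        return float(np.clip(mu, np.nextafter(lo, hi), hi))
    # rejection sampling; the truncation window is wide relative to any
    # sensible SD so this terminates almost immediately
    for _ in range(10_000):
        rt = rng.normal(mu, policy.sd_rt_ms)
        if lo < rt <= hi:
            return float(rt)
    return float(np.clip(mu, np.nextafter(lo, hi), hi))


def simulate_session(
    policy: AgentPolicy,
    participant: Participant,
    schedule: TaskSchedule,
    seed: "int | np.random.Generator",
    n_per_condition: int = 40,
) -> SessionResult:
    """Play a full session (default 4 x 40 = 160 trials).

    The condition order is drawn with the no-three-in-a-row constraint, each
    trial's RT comes from the policy, is mapped to a balloon picture, and the
    outcome is resolved by one uniform draw against p(k).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sequence = generate_condition_sequence(n_per_condition, rng)
    records: list[TrialRecord] = []
    for i, cond in enumerate(sequence, start=1):
        rt = _draw_rt(policy, cond, rng)
        k = schedule.time_to_picture(rt)
        outcome, payoff, u = draw_outcome(schedule, cond, k, rng)
        records.append(
            TrialRecord(
                participant_id=participant.participant_id,
                trial_index=i,
                condition=cond,
                response_time_ms=rt,
                picture_index=k,
                uniform_draw=u,
                outcome=outcome,
                payoff_cents=payoff,
            )
        )
    trials = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "trial_index": [r.trial_index for r in records],
            "risk_level": [r.condition.risk.value for r in records],
            "reward_level": [r.condition.reward.value for r in records],
            "response_time_ms": [r.response_time_ms for r in records],
            "picture_index": [r.picture_index for r in records],
            "uniform_draw": [r.uniform_draw for r in records],
            "outcome": [r.outcome for r in records],
            "payoff_cents": [r.payoff_cents for r in records],
        }
    )
    summary = _summarize(trials)
    seed_val = int(seed) if isinstance(seed, (int, np.integer)) else None
    return SessionResult(participant.participant_id, trials, summary, seed_val)


def _summarize(trials: pd.DataFrame) -> pd.DataFrame:
    g = trials.groupby(["risk_level", "reward_level"], sort=True)
    out = g.agg(
        mean_rt_ms=("response_time_ms", "mean"),
        success_prop=("outcome", lambda s: float(np.mean(s == "cashout"))),
        earnings_cents=("payoff_cents", "sum"),
        n_trials=("trial_index", "size"),
    ).reset_index()
    return out


def behavioral_summary_table(sessions: Sequence[SessionResult]) -> pd.DataFrame:
    """Cohort-level long table: participant x condition x behavioral DVs.

    One row per participant and condition with mean RT, success proportion
    and total earnings -- the dependent-variable triplet of the multivariate
    analysis.
    """
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    frames = []
    for s in sessions:
        df = s.summary.copy()
        df.insert(0, "participant_id", s.participant_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
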