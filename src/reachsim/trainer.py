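"""Automated shaping scheduler.

Reproduces the staged training progression: two 30-min sessions per day for
the first three days and one thereafter; once the movement-water association
is acquired, the amplitude threshold rises by at most 0.1 cm per day from
0.1 cm to 0.9 cm and the reward delay by 50 ms per day from 500 ms to 1 s,
gated on the previous day's performance. Reaction-time regimens introduce
the go-cue either from the first session ("light early") or from the seventh
("light late"), with anticipatory-reach punishment switched on at day 14.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import SegmentationParams, SessionSummary, analyze_session
from .engine import TaskConfig, run_session
from .synthetic import AgentParams, SyntheticMouse

REGIMENS = ("control", "light_early", "light_late")


@dataclass
class TrainerConfig:
    """Scheduler parameters; every advancement rule is configurable."""

    acquisition_rewards: int = 20   # rewarded reaches establishing the association
    gate_rewards: int = 50          # rewarded reaches required to advance next day
    thr_start_cm: float = 0.1
    thr_step_cm: float = 0.1        # <= 1 mm/day
    thr_max_cm: float = 0.9
    delay_start_ms: int = 500
    delay_step_ms: int = 50
    delay_max_ms: int = 1000
    dual_session_days: int = 3      # two sessions/day for this many initial days
    regimen: str = "control"        # control | light_early | light_late
    light_late_session: int = 7     # session index where the go-cue appears (light_late)
    punishment_day: int = 14
    session_ms: int = 1_800_000
    tick_ms: int = 1
    iti_ms: int = 3000
    rt_session_decay: float = 1.0   # per-RT-session factor on the agent's mean latency

    def __post_init__(self) -> None:
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}")


@dataclass
class TrainingState:
    """Where the animal sits in the shaping schedule."""

    day: int = 1
    session_in_day: int = 1
    session_index: int = 1
    amp_threshold: float = 0.1
    reward_delay_ms: int = 500
    acquired: bool = False
    history: list = field(default_factory=list)

    def sessions_today(self, cfg: TrainerConfig) -> int:
        return 2 if self.day <= cfg.dual_session_days else 1


def build_config(state: TrainingState, cfg: TrainerConfig) -> TaskConfig:
    """Task configuration for the session ``state`` points at."""
    if cfg.regimen == "light_early":
        variant = "reaction_time"
    elif cfg.regimen == "light_late":
        variant = "reaction_time" if state.session_index >= cfg.light_late_session else "center_out"
    else:
        variant = "center_out"
    return TaskConfig(
        variant=variant,
        tick_ms=cfg.tick_ms,
        amp_threshold=state.amp_threshold,
        reward_delay_ms=state.reward_delay_ms,
        iti_ms=cfg.iti_ms,
        punishment_enabled=state.day >= cfg.punishment_day,
        session_ms=cfg.session_ms,
    )


def next_config(state: TrainingState, latest: SessionSummary,
                cfg: TrainerConfig) -> tuple[TrainingState, TaskConfig]:
    """Fold one finished session into the schedule and emit the next config.

    Acquisition is declared once a session reaches ``acquisition_rewards``;
    thereafter, at each day boundary where the last session met
    ``gate_rewards``, the threshold and delay advance by one capped step.
    """
    state.history.append(latest)
    if latest.n_rewarded >= cfg.acquisition_rewards:
        state.acquired = True
    if state.session_in_day < state.sessions_today(cfg):
        state.session_in_day += 1
    else:
        state.day += 1
        state.session_in_day = 1
        if state.acquired and latest.n_rewarded >= cfg.gate_rewards:
            state.amp_threshold = round(
                min(cfg.thr_max_cm, state.amp_threshold + cfg.thr_step_cm), 10
            )
            state.reward_delay_ms = min(
                cfg.delay_max_ms, state.reward_delay_ms + cfg.delay_step_ms
            )
    state.session_index += 1
    return state, build_config(state, cfg)


@dataclass
class ProgressionRow:
    day: int
    session: int
    variant: str
    threshold_cm: float
    delay_ms: int
    n_reaches: int
    n_rewarded: int
    median_rt_ms: float | None


@dataclass
class TrainingRun:
    rows: list

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def daily(self, column: str) -> list:
        """First-session-of-day value of a column, indexed by day."""
        seen: dict[int, object] = {}
        for r in self.rows:
            seen.setdefault(r.day, getattr(r, column))
        return [seen[d] for d in sorted(seen)]


def simulate_training(agent_params: AgentParams, n_days: int, seed,
                      cfg: TrainerConfig | None = None) -> TrainingRun:
    """Run the full closed loop for ``n_days``: schedule, simulate, analyse.

    Deterministic given ``(agent_params, n_days, seed, cfg)``; each session
    gets an independent child seed.
    """
    cfg = cfg or TrainerConfig()
    state = TrainingState(amp_threshold=cfg.thr_start_cm,
                          reward_delay_ms=cfg.delay_start_ms)
    base_ss = np.random.SeedSequence(seed)
    task = build_config(state, cfg)
    rows: list[ProgressionRow] = []
    n_rt_sessions = 0
    while state.day <= n_days:
        params = agent_params
        if task.variant == "reaction_time" and cfg.rt_session_decay != 1.0:
            params = replace(
                agent_params,
                rt_mean=agent_params.rt_mean * cfg.rt_session_decay**n_rt_sessions,
            )
        record = run_session(task, SyntheticMouse(params), base_ss.spawn(1)[0])
        seg = SegmentationParams(detect_threshold=task.amp_threshold)
        _, summary = analyze_session(record, seg)
        rows.append(
            ProgressionRow(
                day=state.day,
                session=state.session_index,
                variant=task.variant,
                threshold_cm=state.amp_threshold,
                delay_ms=state.reward_delay_ms,
                n_reaches=summary.n_reaches,
                n_rewarded=summary.n_rewarded,
                median_rt_ms=summary.median_rt_ms,
            )
        )
        if task.variant == "reaction_time":
            n_rt_sessions += 1
        state, task = next_config(state, summary, cfg)
    return TrainingRun(rows)
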