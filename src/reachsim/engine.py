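"""Tick-based finite-state machines for the four joystick reaching tasks.

The engine consumes one position sample per tick and emits task events. Four
variants are supported:

``center_out``
    Direction-agnostic reaching: a radial displacement past the amplitude
    threshold earns reward after a fixed delay; a fixed inter-trial interval
    (ITI) separates trials.
``vao``
    Variable-amplitude operant: same machine, but the threshold is taken from
    a per-trial schedule.
``reaction_time``
    A go-cue light gates reward; crossings before the cue are punished with a
    timeout and a trial restart with a new random ITI (when punishment is
    enabled).
``bandit``
    Two-armed bandit: reaches into two angular sectors carry different reward
    probabilities which swap between blocks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import Baseline, EventLog, PositionSeries, SessionRecord, TaskEvent

VARIANTS = ("center_out", "vao", "reaction_time", "bandit")

# engine phases
ITI = "iti"
ARMED = "armed"
PRE_CUE = "pre_cue"
REWARD_PENDING = "reward_pending"
TIMEOUT = "timeout"


class NonContiguousTickError(ValueError):
    """Raised when a sample's timestamp does not follow the previous tick."""


def radial_displacement(x: float, y: float, baseline: Baseline) -> float:
    """Euclidean distance between ``baseline`` and the current position (cm)."""
    return math.hypot(x - baseline.x0, y - baseline.y0)


def estimate_baseline(series: PositionSeries, window_ms: int = 500) -> Baseline:
    """Componentwise median of the first ``window_ms`` of a series.

    Raises ``ValueError`` if the series does not cover the settling window.
    """
    if len(series) == 0:
        raise ValueError("empty series: no settling data")
    tick = series.tick_ms if len(series) > 1 else 1
    k = int(window_ms // tick)
    if len(series) < k or k == 0:
        raise ValueError(
            f"series too short for baseline estimation: need {window_ms} ms "
            f"({k} samples), got {len(series)}"
        )
    return Baseline(float(np.median(series.x[:k])), float(np.median(series.y[:k])))


@dataclass
class BanditSchedule:
    """Two angular reward sectors with per-block reward probabilities.

    ``sectors`` maps a label to ``(center_rad, half_width_rad)``; the boundary
    is exclusive, so a displacement exactly on a sector edge belongs to
    neither sector. ``p_reward`` gives the probability of reward for a
    threshold crossing classified into each sector during the current block.
    After each rewarded trial beyond ``min_block_len`` trials, the two
    probabilities swap with probability ``switch_prob``.
    """

    sectors: dict = field(
        default_factory=lambda: {
            "forward": (math.pi / 2, math.pi / 4),
            "backward": (-math.pi / 2, math.pi / 4),
        }
    )
    p_reward: dict = field(default_factory=lambda: {"forward": 0.8, "backward": 0.2})
    min_block_len: int = 20
    switch_prob: float = 0.1

    def __post_init__(self) -> None:
        if set(self.sectors) != set(self.p_reward):
            raise ValueError("sectors and p_reward must share labels")
        for p in self.p_reward.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("reward probabilities must lie in [0, 1]")
        labels = list(self.sectors)
        if len(labels) == 2:
            (c1, h1), (c2, h2) = (self.sectors[l] for l in labels)
            gap = abs((c1 - c2 + math.pi) % (2 * math.pi) - math.pi)
            if gap < h1 + h2:
                raise ValueError("bandit sectors overlap")

    def to_dict(self) -> dict:
        return {
            "sectors": {k: list(v) for k, v in self.sectors.items()},
            "p_reward": dict(self.p_reward),
            "min_block_len": self.min_block_len,
            "switch_prob": self.switch_prob,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BanditSchedule":
        d = dict(d)
        if "sectors" in d:
            d["sectors"] = {k: tuple(v) for k, v in d["sectors"].items()}
        return cls(**d)


def classify_direction(dx: float, dy: float, schedule: BanditSchedule) -> str | None:
    """Label of the sector containing ``atan2(dy, dx)``, or ``None``.

    Sector boundaries are exclusive. Raises ``ValueError`` for a zero vector.
    """
    if dx == 0.0 and dy == 0.0:
        raise ValueError("cannot classify direction of a zero displacement")
    ang = math.atan2(dy, dx)
    for label, (center, half_width) in schedule.sectors.items():
        delta = (ang - center + math.pi) % (2 * math.pi) - math.pi
        if abs(delta) < half_width:
            return label
    return None


@dataclass
class TaskConfig:
    """All task-engine parameters for one session.

    Durations are integer milliseconds and must be multiples of ``tick_ms``.
    """

    variant: str = "center_out"
    tick_ms: int = 1
    amp_threshold: float = 0.9
    reward_delay_ms: int = 1000
    iti_ms: int = 3000
    timeout_ms: int = 5000
    punishment_enabled: bool = True
    rt_cue_range_ms: tuple = (1000, 4000)
    iti_random_range_ms: tuple = (3000, 6000)
    vao_schedule: list | None = None  # [(trial_index, threshold_cm), ...]
    bandit: BanditSchedule = field(default_factory=BanditSchedule)
    session_ms: int = 1_800_000
    range_cm: float = 2.5
    baseline_x: float = 0.0
    baseline_y: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.amp_threshold <= 0:
            raise ValueError("amp_threshold must be > 0")
        if self.reward_delay_ms < 0:
            raise ValueError("reward_delay_ms must be >= 0")
        if self.tick_ms <= 0:
            raise ValueError("tick_ms must be positive")
        for name in ("reward_delay_ms", "iti_ms", "timeout_ms", "session_ms"):
            v = getattr(self, name)
            if v % self.tick_ms:
                raise ValueError(f"{name}={v} is not a multiple of tick_ms={self.tick_ms}")
        if self.vao_schedule is not None:
            self.vao_schedule = sorted((int(i), float(th)) for i, th in self.vao_schedule)

    @property
    def baseline(self) -> Baseline:
        return Baseline(self.baseline_x, self.baseline_y)

    def threshold_for_trial(self, trial: int) -> float:
        """Amplitude threshold in force for 1-based trial index ``trial``."""
        if self.variant == "vao" and self.vao_schedule:
            th = self.amp_threshold
            for start, value in self.vao_schedule:
                if trial >= start:
                    th = value
            return th
        return self.amp_threshold

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "tick_ms": self.tick_ms,
            "amp_threshold": self.amp_threshold,
            "reward_delay_ms": self.reward_delay_ms,
            "iti_ms": self.iti_ms,
            "timeout_ms": self.timeout_ms,
            "punishment_enabled": self.punishment_enabled,
            "rt_cue_range_ms": list(self.rt_cue_range_ms),
            "iti_random_range_ms": list(self.iti_random_range_ms),
            "vao_schedule": [list(p) for p in self.vao_schedule] if self.vao_schedule else None,
            "bandit": self.bandit.to_dict(),
            "session_ms": self.session_ms,
            "range_cm": self.range_cm,
            "baseline_x": self.baseline_x,
            "baseline_y": self.baseline_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "bandit" in d and isinstance(d["bandit"], dict):
            d["bandit"] = BanditSchedule.from_dict(d["bandit"])
        for key in ("rt_cue_range_ms", "iti_random_range_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("vao_schedule"):
            d["vao_schedule"] = [tuple(p) for p in d["vao_schedule"]]
        return cls(**d)


@dataclass
class EngineState:
    """Mutable per-session engine state; transitions only via ``TaskEngine.step``."""

    phase: str = ITI
    phase_entry_t: int = 0
    trial: int = 0
    threshold: float = 0.0
    t_cross: int = -1
    cue_t: int = -1
    iti_duration: int = 0
    pending_reward: bool = False
    pending_payload: dict | None = None
    rewards: int = 0
    punishments: int = 0
    block_trials: int = 0
    p_reward: dict = field(default_factory=dict)


class TaskEngine:
    """Closed-loop task state machine; feed one sample per tick via :meth:`step`.

    Timing rules (basic task): the first tick with displacement at or above
    the threshold latches the reward, which is dispensed ``reward_delay_ms``
    later; the next trial starts after a fixed ``iti_ms``. Retraction during
    the delay does not cancel the latched reward, and further crossings are
    ignored until the next trial starts.
    """

    def __init__(
        self,
        config: TaskConfig,
        rng: np.random.Generator,
        baseline: Baseline | None = None,
    ) -> None:
        self.config = config
        self.rng = rng
        self.baseline = baseline if baseline is not None else config.baseline
        self.state = EngineState(p_reward=dict(config.bandit.p_reward))
        self._expected_t: int | None = None
        self._started = False

    # -- helpers -------------------------------------------------------

    def _draw_ms(self, lo: int, hi: int) -> int:
        """Uniform draw on [lo, hi], snapped to the tick grid."""
        tick = self.config.tick_ms
        return int(self.rng.integers(lo // tick, hi // tick + 1)) * tick

    def _start_trial(self, t: int, events: list[TaskEvent]) -> None:
        st, cfg = self.state, self.config
        st.trial += 1
        st.threshold = cfg.threshold_for_trial(st.trial)
        st.pending_reward = False
        st.pending_payload = None
        events.append(
            TaskEvent(t, "trial_start", {"trial": st.trial, "threshold": st.threshold})
        )
        if cfg.variant == "reaction_time":
            delay = self._draw_ms(*cfg.rt_cue_range_ms)
            st.cue_t = t + delay
            st.phase = PRE_CUE
        else:
            st.phase = ARMED
        st.phase_entry_t = t

    def _enter_iti(self, t: int, events: list[TaskEvent], duration: int, payload: dict) -> None:
        st = self.state
        st.phase = ITI
        st.phase_entry_t = t
        st.iti_duration = duration
        events.append(TaskEvent(t, "iti_start", payload))

    def _handle_crossing(self, t: int, dx: float, dy: float, d: float,
                         events: list[TaskEvent]) -> None:
        st, cfg = self.state, self.config
        payload = {"trial": st.trial, "threshold": st.threshold,
                   "displacement": round(d, 6)}
        if cfg.variant == "bandit":
            label = classify_direction(dx, dy, cfg.bandit)
            if label is None:
                rewarded, p, u = False, None, None
            else:
                p = st.p_reward[label]
                u = float(self.rng.random())
                rewarded = u < p
            payload.update({"direction": label, "p": p, "u": u, "rewarded": rewarded})
            st.pending_reward = rewarded
            st.block_trials += 1
            events.append(TaskEvent(t, "threshold_cross", payload))
            if rewarded and st.block_trials >= cfg.bandit.min_block_len:
                u2 = float(self.rng.random())
                if u2 < cfg.bandit.switch_prob:
                    labels = list(st.p_reward)
                    st.p_reward = {labels[0]: st.p_reward[labels[1]],
                                   labels[1]: st.p_reward[labels[0]]}
                    st.block_trials = 0
                    events.append(
                        TaskEvent(t, "block_switch",
                                  {"p_reward": dict(st.p_reward), "u": u2})
                    )
        else:
            st.pending_reward = True
            events.append(TaskEvent(t, "threshold_cross", payload))
        st.t_cross = t
        st.pending_payload = {"trial": st.trial, "t_cross": t}
        st.phase = REWARD_PENDING
        st.phase_entry_t = t

    # -- public API ----------------------------------------------------

    def step(self, t: int, x: float, y: float) -> list[TaskEvent]:
        """Advance one tick; returns the events emitted at time ``t``."""
        cfg, st = self.config, self.state
        if self._expected_t is not None and t != self._expected_t:
            raise NonContiguousTickError(
                f"expected t={self._expected_t}, got t={t}"
            )
        self._expected_t = t + cfg.tick_ms

        events: list[TaskEvent] = []
        if not self._started:
            self._started = True
            self._start_trial(t, events)

        # timed transitions
        if st.phase == REWARD_PENDING and t - st.t_cross >= cfg.reward_delay_ms:
            if st.pending_reward:
                st.rewards += 1
                events.append(TaskEvent(t, "reward", dict(st.pending_payload)))
            self._enter_iti(t, events, cfg.iti_ms, {"trial": st.trial})
        elif st.phase == TIMEOUT and t - st.phase_entry_t >= cfg.timeout_ms:
            iti = self._draw_ms(*cfg.iti_random_range_ms)
            self._enter_iti(t, events, iti, {"trial": st.trial, "iti_ms": iti})
        elif st.phase == ITI and t - st.phase_entry_t >= st.iti_duration:
            self._start_trial(t, events)
        elif st.phase == PRE_CUE and t >= st.cue_t:
            st.phase = ARMED
            st.phase_entry_t = t
            events.append(TaskEvent(t, "cue_on", {"trial": st.trial}))

        # displacement check
        if st.phase in (ARMED, PRE_CUE):
            dx = x - self.baseline.x0
            dy = y - self.baseline.y0
            if dx * dx + dy * dy >= st.threshold * st.threshold:
                if st.phase == PRE_CUE:
                    # anticipatory crossing before the go-cue
                    if cfg.punishment_enabled:
                        st.punishments += 1
                        st.phase = TIMEOUT
                        st.phase_entry_t = t
                        events.append(
                            TaskEvent(t, "punishment_start",
                                      {"trial": st.trial,
                                       "displacement": round(math.hypot(dx, dy), 6)})
                        )
                    # punishment off: anticipatory crossings are ignored
                else:
                    self._handle_crossing(t, dx, dy, math.hypot(dx, dy), events)
        return events


def run_session(config: TaskConfig, agent, seed) -> SessionRecord:
    """Run a full closed-loop session of ``config.session_ms`` milliseconds.

    ``agent`` must expose ``reset(config, rng)`` and
    ``step(t, events) -> (x, y)``; it is called once per tick and sees the
    events emitted on the previous tick. The engine and the agent draw from
    independent child generators spawned from ``seed``, so the session is
    bit-reproducible given ``(config, agent parameters, seed)``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    engine_ss, agent_ss = ss.spawn(2)
    engine = TaskEngine(config, np.random.default_rng(engine_ss))
    agent.reset(config, np.random.default_rng(agent_ss))

    tick = config.tick_ms
    n = config.session_ms // tick
    ts = np.arange(n, dtype=np.int64) * tick
    xs = np.empty(n, dtype=np.float64)
    ys = np.empty(n, dtype=np.float64)
    log = EventLog()

    step_agent = agent.step
    step_engine = engine.step
    events: list[TaskEvent] = []
    for i in range(n):
        t = i * tick
        x, y = step_agent(t, events)
        xs[i] = x
        ys[i] = y
        events = step_engine(t, x, y)
        if events:
            log.extend(events)

    meta = {
        "subject": getattr(agent, "name", "synthetic"),
        "variant": config.variant,
        "seed": seed if isinstance(seed, int) else None,
        "tick_ms": tick,
    }
    return SessionRecord(meta=meta, series=PositionSeries(ts, xs, ys),
                         events=log, config=replace(config))
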