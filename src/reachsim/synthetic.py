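"""Synthetic joystick trace generation with the structure of head-fixed mouse reaching.

Reaches are discrete outward-and-back radial excursions with bell-shaped
speed profiles (minimum-jerk), riding on baseline jitter, with occasional
sub-threshold "blips" and optional small opposite-direction "rev-up"
pre-movements. :class:`SyntheticMouse` closes the loop with the task engine:
it emits spontaneous reaches in the self-paced tasks, cue-locked reaches in
the reaction-time task, and directional choices (win-stay/lose-shift by
default) in the bandit task.

Scripted agents (:class:`TraceAgent`, :class:`ImpulseAgent`) are provided for
deterministic engine-level tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

_JITTER_CHUNK = 1 << 15


def minimum_jerk_profile(amplitude: float, duration_ms: float, t):
    """Minimum-jerk radial position at time ``t`` of a half-movement.

    Position runs smoothly from 0 at ``t=0`` to ``amplitude`` at
    ``t=duration_ms`` following ``A*(10*tau^3 - 15*tau^4 + 6*tau^5)``; peak
    speed is ``1.875*A/D`` at the temporal midpoint. ``t`` may be a scalar or
    an array within ``[0, duration_ms]``.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    tau = np.asarray(t, dtype=np.float64) / duration_ms
    if np.any(tau < 0) or np.any(tau > 1):
        raise ValueError("t outside [0, duration]")
    out = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return float(out) if np.isscalar(t) else out


def _out_and_back(amplitude: float, duration_ms: int, tick_ms: int) -> np.ndarray:
    """Radial profile of a full excursion: two mirrored minimum-jerk halves.

    Returns one value per tick covering ``(0, duration_ms]``; the apex sample
    equals ``amplitude`` exactly and the final sample returns to 0.
    """
    n = max(2, int(round(duration_ms / tick_ms)))
    n_out = n // 2
    n_back = n - n_out
    t_out = np.arange(1, n_out + 1) * tick_ms
    t_back = np.arange(1, n_back + 1) * tick_ms
    r_out = minimum_jerk_profile(amplitude, n_out * tick_ms, t_out)
    r_back = minimum_jerk_profile(amplitude, n_back * tick_ms, n_back * tick_ms - t_back)
    return np.concatenate([r_out, r_back])


@dataclass
class ReachPlan:
    """One planned excursion: when, where, how big, how long."""

    t_start: int
    direction: float  # radians
    amplitude: float  # cm, apex displacement
    duration_ms: int  # full out-and-back duration
    revup: tuple | None = None  # (amplitude_cm, duration_ms) of the pre-movement

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class AgentParams:
    """Parameters of the synthetic mouse.

    Defaults land in the regimes of trained mice on this task: ~1 cm reaches
    of ~half a second, initiated a few times a minute, over ~0.02 cm baseline
    jitter, with occasional 0.15 cm postural blips.
    """

    reach_rate: float = 0.15        # spontaneous initiations / s
    amp_mean: float = 1.2           # cm
    amp_sd: float = 0.25
    dur_mean: float = 500.0         # ms, full out-and-back
    dur_sd: float = 100.0
    directions: tuple = ((math.pi / 2, 0.5), (-math.pi / 2, 0.5))  # (angle, weight)
    angular_sd: float = 0.15        # rad, jitter around the chosen direction
    rt_mean: float = 600.0          # ms, cue-to-initiation latency
    rt_sd: float = 150.0
    anticipation_prob: float = 0.0  # chance of reaching before the go-cue
    revup_prob: float = 0.3
    revup_frac: float = 0.15        # rev-up amplitude as a fraction of the main reach
    jitter_sd: float = 0.02         # cm
    blip_rate: float = 0.05         # blips / s
    blip_amp: float = 0.15          # cm
    blip_dur_ms: float = 200.0
    lose_shift_prob: float = 1.0    # bandit: P(switch sector) after an unrewarded trial

    def __post_init__(self) -> None:
        if min(self.reach_rate, self.blip_rate) < 0:
            raise ValueError("rates must be >= 0")
        if min(self.amp_sd, self.dur_sd, self.rt_sd, self.jitter_sd, self.angular_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        for p in (self.anticipation_prob, self.revup_prob, self.lose_shift_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.revup_frac < 1.0:
            raise ValueError("revup_frac must be < 1")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["directions"] = [list(p) for p in self.directions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        d = dict(d)
        if "directions" in d:
            d["directions"] = tuple(tuple(p) for p in d["directions"])
        return cls(**d)


def generate_reach(plan: ReachPlan, params: AgentParams, rng: np.random.Generator,
                   tick_ms: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-tick (dx, dy) offsets of one reach, relative to baseline.

    An optional rev-up (a small excursion opposite to ``plan.direction``)
    precedes the main outward-and-back movement; additive isotropic Gaussian
    jitter of sd ``params.jitter_sd`` is applied when non-zero.
    """
    segments = []
    if plan.revup is not None:
        amp_r, dur_r = plan.revup
        segments.append((_out_and_back(amp_r, int(dur_r), tick_ms), plan.direction + math.pi))
    segments.append((_out_and_back(plan.amplitude, plan.duration_ms, tick_ms), plan.direction))
    dx = np.concatenate([r * math.cos(ang) for r, ang in segments])
    dy = np.concatenate([r * math.sin(ang) for r, ang in segments])
    if params.jitter_sd > 0:
        dx = dx + rng.normal(0.0, params.jitter_sd, size=dx.size)
        dy = dy + rng.normal(0.0, params.jitter_sd, size=dy.size)
    return dx, dy


def trace_from_plans(plans: list[ReachPlan], n_ticks: int, params: AgentParams,
                     rng: np.random.Generator, tick_ms: int = 1,
                     baseline: tuple = (0.0, 0.0)) -> tuple[np.ndarray, np.ndarray]:
    """Render a list of non-overlapping reach plans into full x/y arrays."""
    x = np.full(n_ticks, baseline[0], dtype=np.float64)
    y = np.full(n_ticks, baseline[1], dtype=np.float64)
    for plan in sorted(plans, key=lambda p: p.t_start):
        dx, dy = generate_reach(plan, replace(params, jitter_sd=0.0), rng, tick_ms)
        i0 = plan.t_start // tick_ms
        i1 = min(i0 + dx.size, n_ticks)
        x[i0:i1] += dx[: i1 - i0]
        y[i0:i1] += dy[: i1 - i0]
    if params.jitter_sd > 0:
        x += rng.normal(0.0, params.jitter_sd, size=n_ticks)
        y += rng.normal(0.0, params.jitter_sd, size=n_ticks)
    return x, y


class SyntheticMouse:
    """Closed-loop synthetic agent driven by :class:`AgentParams`.

    Behavior by task variant:

    * ``center_out`` / ``vao``: spontaneous reaches as a Poisson process at
      ``reach_rate``, directions drawn from the configured mixture.
    * ``reaction_time``: a reach is initiated a Gaussian latency after each
      go-cue; with probability ``anticipation_prob`` an anticipatory reach is
      launched before the cue instead. No spontaneous reaching.
    * ``bandit``: directions follow a win-stay/lose-shift policy over the two
      reward sectors, switching with ``lose_shift_prob`` after unrewarded
      trials.

    Spontaneous initiations are suppressed while a reach is in flight and
    during punishment timeouts.
    """

    name = "synthetic"

    def __init__(self, params: AgentParams | None = None) -> None:
        self.params = params or AgentParams()

    # -- closed-loop protocol ------------------------------------------

    def reset(self, config, rng: np.random.Generator) -> None:
        p = self.params
        self.config = config
        self.rng = rng
        self.tick = config.tick_ms
        self._base = (config.baseline_x, config.baseline_y)
        self._range = config.range_cm
        self._traj = None  # (dx_arr, dy_arr, index)
        self._in_timeout = False
        self._scheduled_t: int | None = None  # cue-locked / anticipatory reach
        self._next_spont = self._exp_after(0, p.reach_rate) if self._spontaneous() else None
        self._next_blip = self._exp_after(0, p.blip_rate)
        self._jx = self._jy = None
        self._ji = _JITTER_CHUNK
        self.n_reaches_started = 0
        if config.variant == "bandit":
            labels = sorted(config.bandit.sectors)
            self._sector_labels = labels
            self._choice = labels[int(rng.integers(len(labels)))]

    def _spontaneous(self) -> bool:
        return self.config.variant != "reaction_time" and self.params.reach_rate > 0

    def _exp_after(self, t: int, rate_per_s: float) -> int | None:
        if rate_per_s <= 0:
            return None
        wait_ms = self.rng.exponential(1000.0 / rate_per_s)
        return t + max(self.tick, int(round(wait_ms / self.tick)) * self.tick)

    def _jitter(self) -> tuple[float, float]:
        sd = self.params.jitter_sd
        if sd <= 0:
            return 0.0, 0.0
        if self._ji >= _JITTER_CHUNK:
            self._jx = self.rng.normal(0.0, sd, size=_JITTER_CHUNK)
            self._jy = self.rng.normal(0.0, sd, size=_JITTER_CHUNK)
            self._ji = 0
        j = self._ji
        self._ji = j + 1
        return self._jx[j], self._jy[j]

    def _draw_direction(self) -> float:
        p = self.params
        if self.config.variant == "bandit":
            center, half = self.config.bandit.sectors[self._choice]
            ang = center + self.rng.normal(0.0, p.angular_sd)
            lo, hi = center - 0.9 * half, center + 0.9 * half
            return min(max(ang, lo), hi)
        weights = np.array([w for _, w in p.directions], dtype=float)
        weights /= weights.sum()
        k = int(self.rng.choice(len(weights), p=weights))
        return p.directions[k][0] + self.rng.normal(0.0, p.angular_sd)

    def _start_reach(self, amplitude: float | None = None,
                     duration: float | None = None,
                     direction: float | None = None,
                     revup_allowed: bool = True) -> None:
        p = self.params
        amp = amplitude if amplitude is not None else max(0.05, self.rng.normal(p.amp_mean, p.amp_sd))
        dur = duration if duration is not None else max(100.0, self.rng.normal(p.dur_mean, p.dur_sd))
        dur = max(2, int(round(dur / self.tick))) * self.tick
        ang = direction if direction is not None else self._draw_direction()
        revup = None
        if revup_allowed and p.revup_prob > 0 and self.rng.random() < p.revup_prob:
            revup = (p.revup_frac * amp, max(2 * self.tick, int(0.25 * dur)))
        plan = ReachPlan(0, ang, amp, dur, revup)
        dx, dy = generate_reach(plan, replace(p, jitter_sd=0.0), self.rng, self.tick)
        self._traj = (dx, dy, 0)
        self.n_reaches_started += 1

    def _start_blip(self) -> None:
        p = self.params
        ang = self.rng.uniform(-math.pi, math.pi)
        dur = max(2, int(round(p.blip_dur_ms / self.tick))) * self.tick
        r = _out_and_back(p.blip_amp, dur, self.tick)
        self._traj = (r * math.cos(ang), r * math.sin(ang), 0)

    def _handle_event(self, ev, t: int) -> None:
        p = self.params
        kind = ev.kind
        if kind == "trial_start":
            if self.config.variant == "reaction_time":
                self._scheduled_t = None
                if p.anticipation_prob > 0 and self.rng.random() < p.anticipation_prob:
                    lead = self.rng.uniform(200.0, 1200.0)
                    self._scheduled_t = t + max(self.tick, int(round(lead / self.tick)) * self.tick)
        elif kind == "cue_on":
            lat = max(float(self.tick), self.rng.normal(p.rt_mean, p.rt_sd))
            self._scheduled_t = t + max(self.tick, int(round(lat / self.tick)) * self.tick)
        elif kind == "punishment_start":
            self._in_timeout = True
            self._scheduled_t = None
        elif kind == "iti_start":
            self._in_timeout = False
        elif kind == "threshold_cross" and self.config.variant == "bandit":
            rewarded = ev.payload.get("rewarded", False)
            if not rewarded and self.rng.random() < p.lose_shift_prob:
                other = [l for l in self._sector_labels if l != self._choice]
                self._choice = other[0] if other else self._choice

    def step(self, t: int, events: list) -> tuple[float, float]:
        """One tick: consume last tick's events, return the current position."""
        for ev in events:
            self._handle_event(ev, t)

        dx = dy = 0.0
        if self._traj is not None:
            ax, ay, i = self._traj
            dx, dy = ax[i], ay[i]
            i += 1
            if i >= ax.size:
                self._traj = None
                if self._spontaneous():
                    self._next_spont = self._exp_after(t, self.params.reach_rate)
                self._next_blip = self._exp_after(t, self.params.blip_rate)
            else:
                self._traj = (ax, ay, i)
        elif not self._in_timeout:
            if self._scheduled_t is not None and t >= self._scheduled_t:
                self._scheduled_t = None
                self._start_reach()
                dx, dy = self._traj[0][0], self._traj[1][0]
                self._traj = (self._traj[0], self._traj[1], 1)
            elif self._next_spont is not None and t >= self._next_spont:
                self._start_reach()
                dx, dy = self._traj[0][0], self._traj[1][0]
                self._traj = (self._traj[0], self._traj[1], 1)
            elif self._next_blip is not None and t >= self._next_blip:
                self._start_blip()
                dx, dy = self._traj[0][0], self._traj[1][0]
                self._traj = (self._traj[0], self._traj[1], 1)

        jx, jy = self._jitter()
        r = self._range
        x = min(max(self._base[0] + dx + jx, -r), r)
        y = min(max(self._base[1] + dy + jy, -r), r)
        return x, y


class TraceAgent:
    """Plays back a precomputed trace; ignores all events."""

    name = "trace"

    def __init__(self, x: np.ndarray, y: np.ndarray) -> None:
        self.x = np.asarray(x, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)

    def reset(self, config, rng) -> None:
        self.tick = config.tick_ms

    def step(self, t: int, events: list) -> tuple[float, float]:
        i = min(t // self.tick, self.x.size - 1)
        return float(self.x[i]), float(self.y[i])


class ImpulseAgent:
    """Steps to a fixed displacement a fixed latency after every trial start.

    Useful for exact timing tests: the threshold crossing lands exactly
    ``delay_ms`` after ``trial_start`` (or after ``cue_on`` when
    ``after_cue=True``).
    """

    name = "impulse"

    def __init__(self, delay_ms: int, amplitude: float = 1.2, hold_ms: int = 200,
                 direction: float = math.pi / 2, after_cue: bool = False) -> None:
        self.delay_ms = delay_ms
        self.amplitude = amplitude
        self.hold_ms = hold_ms
        self.direction = direction
        self.after_cue = after_cue

    def reset(self, config, rng) -> None:
        self._base = (config.baseline_x, config.baseline_y)
        self._window: tuple[int, int] | None = None

    def step(self, t: int, events: list) -> tuple[float, float]:
        trigger = "cue_on" if self.after_cue else "trial_start"
        for ev in events:
            if ev.kind == trigger:
                self._window = (ev.t + self.delay_ms, ev.t + self.delay_ms + self.hold_ms)
            elif ev.kind == "punishment_start":
                self._window = None
        if self._window and self._window[0] <= t < self._window[1]:
            return (self._base[0] + self.amplitude * math.cos(self.direction),
                    self._base[1] + self.amplitude * math.sin(self.direction))
        return self._base
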