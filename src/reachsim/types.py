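"""Core data types shared by the task engine, trace generator and analysis layers.

All positions are in centimetres, all times in integer milliseconds measured
from session start. A session is a fixed-rate tick stream: sample ``i`` has
``t = i * tick_ms``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Event kinds that may appear in an :class:`EventLog`.
EVENT_KINDS = frozenset(
    {
        "trial_start",
        "cue_on",
        "threshold_cross",
        "reward",
        "punishment_start",
        "iti_start",
        "block_switch",
    }
)


@dataclass(frozen=True)
class Baseline:
    """Resting joystick centre from which radial displacement is measured."""

    x0: float = 0.0
    y0: float = 0.0


@dataclass(frozen=True)
class PositionSample:
    """A single timestamped joystick position."""

    t: int
    x: float
    y: float


@dataclass
class TaskEvent:
    """A typed, timestamped task event.

    ``payload`` carries variant-specific detail (trial index, threshold in
    force, direction label, random draws) and must stay JSON-serialisable so
    sessions round-trip through CSV exactly.
    """

    t: int
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")


class EventLog:
    """Time-ordered collection of :class:`TaskEvent`."""

    def __init__(self, events: list[TaskEvent] | None = None) -> None:
        self._events: list[TaskEvent] = list(events) if events else []

    def append(self, event: TaskEvent) -> None:
        if self._events and event.t < self._events[-1].t:
            raise ValueError("events must be appended in time order")
        self._events.append(event)

    def extend(self, events: list[TaskEvent]) -> None:
        for ev in events:
            self.append(ev)

    def of_kind(self, kind: str) -> list[TaskEvent]:
        """All events of one kind, in time order."""
        return [ev for ev in self._events if ev.kind == kind]

    def times(self, kind: str) -> list[int]:
        return [ev.t for ev in self._events if ev.kind == kind]

    def __iter__(self) -> Iterator[TaskEvent]:
        return iter(self._events)

    def __len__(self) -> int:
        return len(self._events)

    def __getitem__(self, i):
        return self._events[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return self._events == other._events

    def __repr__(self) -> str:
        return f"EventLog({len(self._events)} events)"


@dataclass
class PositionSeries:
    """Fixed-rate x-y position time series.

    ``t`` is int64 milliseconds, strictly increasing; ``x``/``y`` are float64
    centimetres.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")

    def validate(self, range_cm: float | None = None) -> None:
        """Raise ``ValueError`` on non-monotonic timestamps or out-of-range positions."""
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            i = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise ValueError(f"non-monotonic timestamp at sample {i}")
        if range_cm is not None:
            if np.any(np.abs(self.x) > range_cm) or np.any(np.abs(self.y) > range_cm):
                raise ValueError(f"position exceeds physical range ±{range_cm} cm")

    @property
    def tick_ms(self) -> int:
        if len(self.t) < 2:
            raise ValueError("cannot infer tick from a series of <2 samples")
        return int(self.t[1] - self.t[0])

    def displacement(self, baseline: Baseline) -> np.ndarray:
        """Radial (Euclidean) displacement of every sample from ``baseline``."""
        return np.hypot(self.x - baseline.x0, self.y - baseline.y0)

    def slice(self, i0: int, i1: int) -> "PositionSeries":
        """Half-open index slice ``[i0, i1)`` sharing the underlying buffers."""
        return PositionSeries(self.t[i0:i1], self.x[i0:i1], self.y[i0:i1])

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PositionSeries):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )


@dataclass
class SessionRecord:
    """One session: metadata + position series + event log + task config.

    The unit of storage and analysis; round-trips exactly through the session
    CSV format (see :mod:`reachsim.sessionio`).
    """

    meta: dict
    series: PositionSeries
    events: EventLog
    config: object = None  # TaskConfig; typed loosely to avoid an import cycle

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionRecord):
            return NotImplemented
        return (
            self.meta == other.meta
            and self.series == other.series
            and self.events == other.events
            and self.config == other.config
        )
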