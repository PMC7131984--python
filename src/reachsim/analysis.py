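"""Offline reach segmentation, kinematics and session summaries.

Segmentation is threshold-based: every maximal run of samples whose radial
displacement meets the detection threshold seeds a reach, which is then
expanded backward and forward in time to a low fractional level of that
threshold to recover the full initiation and termination times. Nearby
reaches are merged and too-short candidates dropped, so small non-task
"blips" are ignored.
"""
from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .types import Baseline, EventLog, PositionSeries, SessionRecord

logger = logging.getLogger(__name__)

#: Reaction times strictly greater than this are omitted from RT summaries.
RT_OMIT_MS = 5000

#: Expert criterion: rewarded reaches per session must exceed this count...
EXPERT_MIN_REWARDED = 100
#: ...at a session amplitude threshold of at least this many cm.
EXPERT_MIN_THRESHOLD_CM = 0.9


@dataclass
class SegmentationParams:
    """Parameters of threshold-crossing reach detection."""

    detect_threshold: float        # cm; minimal amplitude a candidate must reach
    onset_frac: float = 0.1        # fraction of detect_threshold defining onset/offset level
    min_duration_ms: int = 50
    merge_gap_ms: int = 20
    smooth_ms: int = 0             # odd moving-average width for velocity; 0 = off

    def __post_init__(self) -> None:
        if self.detect_threshold <= 0:
            raise ValueError("detect_threshold must be > 0")
        if not 0.0 < self.onset_frac < 1.0:
            raise ValueError("onset_frac must lie in (0, 1)")


@dataclass
class Reach:
    """One segmented reach with its kinematic features."""

    onset_t: int
    offset_t: int
    trajectory: PositionSeries
    amplitude: float          # cm, peak radial displacement
    peak_out_velocity: float  # cm/s, max outward radial speed
    duration_ms: int
    direction: float          # rad, displacement angle at the apex
    rewarded: bool = False
    edge: bool = False        # truncated by a session boundary


@dataclass
class SessionSummary:
    n_reaches: int
    n_rewarded: int
    n_punishments: int = 0
    median_rt_ms: float | None = None
    rts_ms: list = field(default_factory=list)
    moving_avg_rt5: list = field(default_factory=list)
    iri_ms: list = field(default_factory=list)
    expert: bool = False

    def to_dict(self) -> dict:
        return {
            "n_reaches": self.n_reaches,
            "n_rewarded": self.n_rewarded,
            "n_punishments": self.n_punishments,
            "median_rt_ms": self.median_rt_ms,
            "rts_ms": list(self.rts_ms),
            "moving_avg_rt5": list(self.moving_avg_rt5),
            "iri_ms": list(self.iri_ms),
            "expert": self.expert,
        }


def _displacement_kinematics(d: np.ndarray, tick_ms: int) -> tuple[float, float, int]:
    amplitude = float(np.max(d))
    dv = np.diff(d)
    peak_v = float(np.max(dv)) / (tick_ms / 1000.0) if dv.size else 0.0
    return amplitude, max(peak_v, 0.0), int(np.argmax(d))


def reach_kinematics(reach: Reach, tick_ms: int,
                     baseline: Baseline = Baseline()) -> tuple[float, float, int]:
    """(amplitude cm, peak outward velocity cm/s, duration ms) of a reach.

    Velocity is the forward difference of radial displacement at native
    resolution; the positive lobe's maximum is reported.
    """
    d = reach.trajectory.displacement(baseline)
    amplitude, peak_v, _ = _displacement_kinematics(d, tick_ms)
    return amplitude, peak_v, reach.offset_t - reach.onset_t


def detect_reaches(series: PositionSeries, baseline: Baseline,
                   params: SegmentationParams) -> list[Reach]:
    """Segment reaches from a position series.

    For each maximal run of samples with displacement >= ``detect_threshold``,
    the reach is expanded backward to the sample after the last one below
    ``onset_frac * detect_threshold`` and forward to the sample before the
    next one below that level. Candidates separated by less than
    ``merge_gap_ms`` of sub-level samples are merged, then candidates shorter
    than ``min_duration_ms`` are dropped. Returned reaches are disjoint and
    time-ordered.
    """
    if len(series) == 0:
        return []
    tick = series.tick_ms if len(series) > 1 else 1
    d = series.displacement(baseline)
    above = d >= params.detect_threshold
    if not above.any():
        return []
    low = params.onset_frac * params.detect_threshold
    below_low = np.flatnonzero(d < low)

    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(d) - 1]])

    n = len(d)
    intervals: list[list] = []  # [onset_i, offset_i, left_edge, right_edge]
    for s, e in zip(starts, ends):
        j = np.searchsorted(below_low, s)
        if j > 0:
            onset_i, left_edge = int(below_low[j - 1]) + 1, False
        else:
            onset_i, left_edge = 0, True
        k = np.searchsorted(below_low, e)
        if k < below_low.size:
            offset_i, right_edge = int(below_low[k]) - 1, False
        else:
            offset_i, right_edge = n - 1, True
        if intervals and onset_i <= intervals[-1][1] + 1:
            # expansion reached into (or touches) the previous candidate
            intervals[-1][1] = max(intervals[-1][1], offset_i)
            intervals[-1][3] = right_edge
        else:
            intervals.append([onset_i, offset_i, left_edge, right_edge])

    # merge candidates separated by < merge_gap_ms of sub-level samples
    merged: list[list] = []
    for iv in intervals:
        if merged:
            gap_ms = (iv[0] - merged[-1][1] - 1) * tick
            if gap_ms < params.merge_gap_ms:
                merged[-1][1] = iv[1]
                merged[-1][3] = iv[3]
                continue
        merged.append(iv)

    reaches: list[Reach] = []
    for onset_i, offset_i, left_edge, right_edge in merged:
        duration = (offset_i - onset_i) * tick
        if duration < params.min_duration_ms:
            continue
        traj = series.slice(onset_i, offset_i + 1)
        seg = d[onset_i : offset_i + 1]
        amplitude, peak_v, apex = _displacement_kinematics(seg, tick)
        direction = math.atan2(traj.y[apex] - baseline.y0, traj.x[apex] - baseline.x0)
        reaches.append(
            Reach(
                onset_t=int(series.t[onset_i]),
                offset_t=int(series.t[offset_i]),
                trajectory=traj,
                amplitude=amplitude,
                peak_out_velocity=peak_v,
                duration_ms=duration,
                direction=direction,
                edge=left_edge or right_edge,
            )
        )
    return reaches


def mark_rewarded(reaches: list[Reach], events: EventLog) -> list[Reach]:
    """Flag each reach whose span contains a rewarded threshold crossing."""
    cross_ts = [ev.payload.get("t_cross", ev.t) for ev in events.of_kind("reward")]
    for reach in reaches:
        reach.rewarded = any(reach.onset_t <= tc <= reach.offset_t for tc in cross_ts)
    return reaches


def inter_reach_intervals(reaches: list[Reach]) -> list[int]:
    """Onset-to-onset intervals (ms) between consecutive reaches.

    The inter-trial interval is part of the IRI by construction, so in a
    rewarded basic-task session every IRI sits above the ITI-driven floor.
    """
    onsets = [r.onset_t for r in reaches]
    return [b - a for a, b in zip(onsets, onsets[1:])]


def filter_reaction_times(rts_ms: list[float]) -> list[float]:
    """Drop reaction times strictly greater than 5 s; order preserved."""
    return [rt for rt in rts_ms if rt <= RT_OMIT_MS]


def reaction_times(session: SessionRecord, reaches: list[Reach]) -> list[float]:
    """Retained reaction times: rewarded-reach onset minus latest prior go-cue.

    RTs above 5 s are omitted. A rewarded reach with no preceding cue is
    skipped with a logged warning.
    """
    cue_ts = session.events.times("cue_on")
    rts: list[float] = []
    for reach in reaches:
        if not reach.rewarded:
            continue
        i = bisect_right(cue_ts, reach.onset_t) - 1
        if i < 0:
            logger.warning(
                "rewarded reach at t=%d has no preceding cue_on; skipped", reach.onset_t
            )
            continue
        rts.append(float(reach.onset_t - cue_ts[i]))
    return filter_reaction_times(rts)


def moving_average_rt(rts: list[float], window: int = 5) -> list[float]:
    """Running mean of the last ``window`` values (shorter at the start)."""
    out: list[float] = []
    for i in range(len(rts)):
        chunk = rts[max(0, i - window + 1) : i + 1]
        out.append(sum(chunk) / len(chunk))
    return out


def is_expert(n_rewarded: int, amp_threshold: float) -> bool:
    """Expert session: >100 rewarded reaches at a threshold of >=0.9 cm."""
    return n_rewarded > EXPERT_MIN_REWARDED and amp_threshold >= EXPERT_MIN_THRESHOLD_CM


def session_summary(session: SessionRecord, reaches: list[Reach]) -> SessionSummary:
    """Counts, retained RTs, IRIs and the expert flag for one session."""
    n_rewarded = sum(r.rewarded for r in reaches)
    rts = reaction_times(session, reaches) if session.events.of_kind("cue_on") else []
    thr = session.config.amp_threshold if session.config is not None else 0.0
    return SessionSummary(
        n_reaches=len(reaches),
        n_rewarded=n_rewarded,
        n_punishments=len(session.events.of_kind("punishment_start")),
        median_rt_ms=float(np.median(rts)) if rts else None,
        rts_ms=rts,
        moving_avg_rt5=moving_average_rt(rts),
        iri_ms=inter_reach_intervals(reaches),
        expert=is_expert(n_rewarded, thr),
    )


def analyze_session(session: SessionRecord, params: SegmentationParams,
                    baseline: Baseline | None = None) -> tuple[list[Reach], SessionSummary]:
    """Full offline pipeline: segment, join with rewards, summarise."""
    if baseline is None:
        baseline = session.config.baseline if session.config is not None else Baseline()
    reaches = detect_reaches(session.series, baseline, params)
    mark_rewarded(reaches, session.events)
    return reaches, session_summary(session, reaches)
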