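"""Bit-exact session log and config I/O.

Session CSV layout::

    # key=<json value>          (metadata block; one line per key)
    # config=<json object>      (task configuration, when present)
    t_ms,x_cm,y_cm,event,payload
    0,0.0,0.0,trial_start,"{""trial"": 1, ""threshold"": 0.9}"
    1,0.0012,-0.0007,,

``event`` is blank on most rows; multiple events on one tick are
semicolon-joined with a JSON *list* payload. Floats are written in shortest
round-trip form, so ``read_session(write_session(r)) == r`` exactly. A
headerless ``t,x,y`` stream is also accepted for analysis-only use.
"""
from __future__ import annotations

import io
import json

import numpy as np
import pandas as pd

from .engine import TaskConfig
from .types import EVENT_KINDS, EventLog, PositionSeries, SessionRecord, TaskEvent

_HEADER = "t_ms,x_cm,y_cm,event,payload"


class SessionParseError(ValueError):
    """Malformed session file; carries the 1-based offending line number."""

    def __init__(self, message: str, lineno: int | None = None) -> None:
        self.lineno = lineno
        suffix = f" (line {lineno})" if lineno is not None else ""
        super().__init__(message + suffix)


def apply_calibration(series: PositionSeries, gain: tuple = (1.0, 1.0),
                      offset: tuple = (0.0, 0.0)) -> PositionSeries:
    """Linear two-point calibration for ingesting real (voltage-scaled) logs."""
    return PositionSeries(series.t,
                          series.x * gain[0] + offset[0],
                          series.y * gain[1] + offset[1])


def write_session(record: SessionRecord, path) -> None:
    """Write a session record; output bytes are deterministic."""
    series, events = record.series, record.events
    tick = record.meta.get("tick_ms") or (series.tick_ms if len(series) > 1 else 1)
    n = len(series)
    kinds = [""] * n
    payloads: list[list] = [None] * n  # type: ignore[list-item]
    for ev in events:
        i = int(ev.t) // tick
        if not 0 <= i < n or int(series.t[i]) != ev.t:
            raise ValueError(f"event at t={ev.t} outside the series tick grid")
        if kinds[i]:
            kinds[i] += ";" + ev.kind
            payloads[i].append(ev.payload)
        else:
            kinds[i] = ev.kind
            payloads[i] = [ev.payload]
    payload_col = [
        ""
        if p is None
        else json.dumps(p[0] if len(p) == 1 else p, separators=(", ", ": "))
        for p in payloads
    ]
    # shortest round-trip float form; pandas' default float writer is lossy
    df = pd.DataFrame(
        {
            "t_ms": series.t,
            "x_cm": [repr(v) for v in series.x.tolist()],
            "y_cm": [repr(v) for v in series.y.tolist()],
            "event": kinds,
            "payload": payload_col,
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in record.meta.items():
            fh.write(f"# {key}={json.dumps(value)}\n")
        if record.config is not None:
            fh.write(f"# config={json.dumps(record.config.to_dict())}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for i, line in enumerate(lines, start=1):
        body = line[1:].strip()
        if not body:
            continue
        if "=" not in body:
            raise SessionParseError(f"malformed metadata line {body!r}", lineno=i)
        key, _, raw = body.partition("=")
        try:
            meta[key.strip()] = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise SessionParseError(f"bad JSON in metadata key {key!r}: {exc}", lineno=i)
    return meta


def read_session(path) -> SessionRecord:
    """Read a session CSV (or a headerless ``t,x,y`` stream) back into a record."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    n_meta = 0
    while n_meta < len(lines) and lines[n_meta].startswith("#"):
        n_meta += 1
    if n_meta >= len(lines):
        raise SessionParseError("no data rows", lineno=len(lines))
    meta = _parse_meta(lines[:n_meta])
    config = TaskConfig.from_dict(meta.pop("config")) if "config" in meta else None

    header_line = lines[n_meta]
    headerless = not header_line.startswith("t_ms")
    body = "\n".join(lines[n_meta:])
    try:
        if headerless:
            df = pd.read_csv(io.StringIO(body), header=None,
                             names=["t_ms", "x_cm", "y_cm"], usecols=[0, 1, 2],
                             float_precision="round_trip")
            df["event"] = ""
            df["payload"] = ""
        else:
            df = pd.read_csv(io.StringIO(body),
                             dtype={"event": str, "payload": str},
                             keep_default_na=False,
                             float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise SessionParseError(f"cannot parse data block: {exc}", lineno=n_meta + 1)
    for col in ("t_ms", "x_cm", "y_cm"):
        if col not in df.columns:
            raise SessionParseError(f"missing column {col!r}", lineno=n_meta + 1)

    # 1-based physical line number of data row 0
    first_data_line = n_meta + (1 if headerless else 2)
    t = df["t_ms"].to_numpy(dtype=np.int64)
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise SessionParseError(
                f"non-monotonic t_ms at t={int(t[bad[0] + 1])}",
                lineno=first_data_line + int(bad[0]) + 1,
            )
    series = PositionSeries(t, df["x_cm"].to_numpy(np.float64),
                            df["y_cm"].to_numpy(np.float64))

    events = EventLog()
    if not headerless:
        ev_rows = df.index[df["event"] != ""]
        for i in ev_rows:
            kinds = str(df.at[i, "event"]).split(";")
            raw = df.at[i, "payload"]
            lineno = first_data_line + int(i)
            try:
                loaded = json.loads(raw) if raw else {}
            except json.JSONDecodeError as exc:
                raise SessionParseError(f"bad event payload JSON: {exc}", lineno=lineno)
            pls = loaded if len(kinds) > 1 else [loaded]
            if len(pls) != len(kinds):
                raise SessionParseError("event/payload count mismatch", lineno=lineno)
            for kind, pl in zip(kinds, pls):
                if kind not in EVENT_KINDS:
                    raise SessionParseError(f"unknown event code {kind!r}", lineno=lineno)
                events.append(TaskEvent(int(df.at[i, "t_ms"]), kind, pl))

    return SessionRecord(meta=meta, series=series, events=events, config=config)
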