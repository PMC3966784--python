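"""Domain types and I/O for satellite-tag Behavior Log event streams.

A Behavior Log (BL) is a time-ordered stream of two kinds of events
reconstructed from satellite messages: qualifying *dives* (submergence
exceeding 50 m depth for longer than 30 s, reported with start, end,
maximum depth, and dive shape) and intervening *surfacing bouts* (start
and end only).  Message loss leaves gaps in the stream; between gaps the
record is contiguous — each event starts where the previous one ended.

Surfacing-bout timestamps come from one of two sensor configurations:
a wet/dry conductivity switch at the surface (``wet_dry``) or the 5 m
depth-threshold crossing on descent/ascent (``depth_5m``).  The two
modes yield systematically different bout durations and are kept
separate downstream; this module only carries the label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Minimum maximum-depth (m) for a qualifying dive.
QUALIFYING_DEPTH_M = 50.0
#: Minimum duration (s) for a qualifying dive.
QUALIFYING_DURATION_S = 30.0
#: Default contiguity tolerance (s): adjacent events whose start/end
#: differ by no more than this are treated as contiguous; larger
#: shortfalls are recorded as gaps.
DEFAULT_TAU_GAP_S = 60.0

DIVE_SHAPES = ("Square", "V", "U")
SENSOR_MODES = ("wet_dry", "depth_5m")

#: Argos location-quality classes, best first.
ARGOS_QUALITY_ORDER = ("3", "2", "1", "0", "A", "B")
_QUALITY_RANK = {q: i for i, q in enumerate(ARGOS_QUALITY_ORDER)}


class BehaviorLogError(Exception):
    """Base class for Behavior Log parsing/validation failures."""


class ParseError(BehaviorLogError):
    """A row could not be parsed (malformed timestamp or number)."""


class ValidationError(BehaviorLogError):
    """Structurally invalid stream (overlap, unknown kind, unsorted)."""


@dataclass
class BehaviorLogEvent:
    """One dive or surfacing-bout record."""

    whale_id: str
    kind: str  # "dive" | "surfacing"
    start: datetime
    end: datetime
    max_depth: float | None = None  # meters; dives only
    shape: str | None = None  # "Square" | "V" | "U"; dives only

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def __post_init__(self) -> None:
        if self.kind not in ("dive", "surfacing"):
            raise ValidationError(f"unknown event kind {self.kind!r}")


@dataclass
class BehaviorLog:
    """Validated, time-ordered event stream for one tagged whale."""

    whale_id: str
    sensor_mode: str
    events: list[BehaviorLogEvent] = field(default_factory=list)
    gaps: list[tuple[datetime, datetime]] = field(default_factory=list)
    #: (source row number, reason) for rows rejected on read.
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def total_hours(self) -> float:
        """Hours of BL coverage: sum of event durations / 3600."""
        return sum(e.duration_s for e in self.events) / 3600.0

    def dives(self) -> list[BehaviorLogEvent]:
        return [e for e in self.events if e.kind == "dive"]

    def surfacings(self) -> list[BehaviorLogEvent]:
        return [e for e in self.events if e.kind == "surfacing"]


@dataclass
class Deployment:
    """Per-individual tag-deployment metadata."""

    whale_id: str
    age_class: str
    sex: str
    sensor_mode: str
    deploy_date: datetime
    deploy_lat: float
    deploy_lon: float
    transmission_duration_days: float
    total_bl_hours: float


@dataclass
class PositionEstimate:
    """One Argos-style location fix with its quality class."""

    whale_id: str
    time: datetime
    lat: float
    lon: float
    quality: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude {self.lon} outside [-180, 180]")
        if self.quality not in _QUALITY_RANK:
            raise ValidationError(f"unknown Argos quality class {self.quality!r}")


def quality_rank(quality: str) -> int:
    """Ordinal rank of an Argos quality class; 0 is best (class 3)."""
    return _QUALITY_RANK[quality]


# ---------------------------------------------------------------------------
# timestamps

_TS_FMT = "%Y-%m-%dT%H:%M:%SZ"


def parse_timestamp(text: str) -> datetime:
    """Parse an ISO-8601 UTC timestamp with trailing Z, 1 s resolution."""
    try:
        return datetime.strptime(text.strip(), _TS_FMT).replace(tzinfo=timezone.utc)
    except (ValueError, AttributeError) as exc:
        raise ParseError(f"malformed timestamp {text!r}") from exc


def format_timestamp(dt: datetime) -> str:
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc).strftime(_TS_FMT)


# ---------------------------------------------------------------------------
# gap detection


def detect_gaps(
    events: Sequence[BehaviorLogEvent], tau_gap_s: float = DEFAULT_TAU_GAP_S
) -> list[tuple[datetime, datetime]]:
    """Find message-loss gaps between adjacent events.

    Any adjacent pair with ``next.start - prev.end > tau_gap_s`` yields a
    gap ``(prev.end, next.start)``; smaller deltas are treated as
    contiguous record.  Events must be time-sorted.
    """
    gaps: list[tuple[datetime, datetime]] = []
    for prev, nxt in zip(events, events[1:]):
        if nxt.start < prev.start:
            raise ValidationError("events are not sorted by start time")
        delta = (nxt.start - prev.end).total_seconds()
        if delta > tau_gap_s:
            gaps.append((prev.end, nxt.start))
    return gaps


def _check_no_overlap(events: Sequence[BehaviorLogEvent]) -> None:
    for i, (prev, nxt) in enumerate(zip(events, events[1:])):
        if nxt.start < prev.end:
            raise ValidationError(
                f"events overlap: event ending {format_timestamp(prev.end)} "
                f"overlaps event starting {format_timestamp(nxt.start)} "
                f"(positions {i}, {i + 1})"
            )


# ---------------------------------------------------------------------------
# Behavior Log CSV I/O
#
# Dialect: comma-separated UTF-8 with header
#   whale_id,kind,start,end,max_depth,shape
# max_depth and shape are empty for surfacing rows.

BL_COLUMNS = ["whale_id", "kind", "start", "end", "max_depth", "shape"]


def read_behavior_log(
    path: str | Path,
    sensor_mode: str,
    tau_gap_s: float = DEFAULT_TAU_GAP_S,
) -> BehaviorLog:
    """Read and validate a Behavior Log CSV.

    Rows violating the qualifying-dive invariants (max depth below 50 m,
    duration under 30 s) are rejected and reported in
    ``BehaviorLog.rejected`` rather than silently dropped.  Malformed
    timestamps, unknown kinds and overlapping events raise.
    """
    if sensor_mode not in SENSOR_MODES:
        raise ValidationError(f"unknown sensor mode {sensor_mode!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in BL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}")

    events: list[BehaviorLogEvent] = []
    rejected: list[tuple[int, str]] = []
    whale_id = ""
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        kind = row.kind.strip()
        if kind not in ("dive", "surfacing"):
            raise ValidationError(f"row {idx}: unknown kind {kind!r}")
        try:
            start = parse_timestamp(row.start)
            end = parse_timestamp(row.end)
        except ParseError as exc:
            raise ParseError(f"row {idx}: {exc}") from None
        if end <= start:
            rejected.append((idx, "end not after start"))
            continue
        depth: float | None = None
        shape: str | None = None
        if kind == "dive":
            try:
                depth = float(row.max_depth)
            except ValueError:
                raise ParseError(f"row {idx}: malformed max_depth {row.max_depth!r}") from None
            if not math.isfinite(depth):
                raise ParseError(f"row {idx}: non-finite max_depth")
            shape = row.shape.strip() or None
            if shape is not None and shape not in DIVE_SHAPES:
                raise ValidationError(f"row {idx}: unknown dive shape {shape!r}")
            if depth < QUALIFYING_DEPTH_M:
                rejected.append((idx, "below 50 m qualifying threshold"))
                continue
            if (end - start).total_seconds() < QUALIFYING_DURATION_S:
                rejected.append((idx, "shorter than 30 s qualifying threshold"))
                continue
        else:
            if row.max_depth.strip():
                rejected.append((idx, "surfacing row carries a max_depth"))
                continue
        whale_id = row.whale_id or whale_id
        events.append(BehaviorLogEvent(row.whale_id, kind, start, end, depth, shape))

    events.sort(key=lambda e: e.start)
    _check_no_overlap(events)
    gaps = detect_gaps(events, tau_gap_s)
    return BehaviorLog(whale_id, sensor_mode, events, gaps, rejected)


def write_behavior_log(log: BehaviorLog, path: str | Path) -> None:
    """Write a BL CSV that round-trips bit-exactly through read."""
    rows = []
    for e in log.events:
        rows.append(
            {
                "whale_id": e.whale_id,
                "kind": e.kind,
                "start": format_timestamp(e.start),
                "end": format_timestamp(e.end),
                # repr() gives the shortest float literal that round-trips
                "max_depth": "" if e.max_depth is None else repr(float(e.max_depth)),
                "shape": e.shape or "",
            }
        )
    pd.DataFrame(rows, columns=BL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# positions & deployments CSV I/O

POSITION_COLUMNS = ["whale_id", "time", "lat", "lon", "quality"]


def read_positions(path: str | Path) -> list[PositionEstimate]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                PositionEstimate(
                    row.whale_id,
                    parse_timestamp(row.time),
                    float(row.lat),
                    float(row.lon),
                    row.quality.strip(),
                )
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"row {idx}: {exc}") from None
    out.sort(key=lambda p: p.time)
    return out


def write_positions(positions: Iterable[PositionEstimate], path: str | Path) -> None:
    rows = [
        {
            "whale_id": p.whale_id,
            "time": format_timestamp(p.time),
            "lat": repr(float(p.lat)),
            "lon": repr(float(p.lon)),
            "quality": p.quality,
        }
        for p in positions
    ]
    pd.DataFrame(rows, columns=POSITION_COLUMNS).to_csv(path, index=False)


DEPLOYMENT_COLUMNS = [
    "whale_id",
    "age_class",
    "sex",
    "sensor_mode",
    "deploy_date",
    "deploy_lat",
    "deploy_lon",
    "transmission_duration_days",
    "total_bl_hours",
]


def read_deployments(path: str | Path) -> list[Deployment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Deployment(
                row.whale_id,
                row.age_class,
                row.sex,
                row.sensor_mode,
                parse_timestamp(row.deploy_date),
                float(row.deploy_lat),
                float(row.deploy_lon),
                float(row.transmission_duration_days),
                float(row.total_bl_hours),
            )
        )
    return out


def write_deployments(deployments: Iterable[Deployment], path: str | Path) -> None:
    rows = [
        {
            "whale_id": d.whale_id,
            "age_class": d.age_class,
            "sex": d.sex,
            "sensor_mode": d.sensor_mode,
            "deploy_date": format_timestamp(d.deploy_date),
            "deploy_lat": repr(float(d.deploy_lat)),
            "deploy_lon": repr(float(d.deploy_lon)),
            "transmission_duration_days": repr(float(d.transmission_duration_days)),
            "total_bl_hours": repr(float(d.total_bl_hours)),
        }
        for d in deployments
    ]
    pd.DataFrame(rows, columns=DEPLOYMENT_COLUMNS).to_csv(path, index=False)
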