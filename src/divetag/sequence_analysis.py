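"""Surfacing-bout typing, inter-deep-dive intervals, and dive rates.

The stereotypical dive cycle is a single deep (foraging) dive followed
by a series of shallow dives, with brief surfacing bouts between all
dives.  Surfacing bouts are typed by the classes of the bracketing
dives:

========  ==================  =====================================
type      bracketing classes  meaning
========  ==================  =====================================
FS        deep, shallow       first surfacing after a deep dive
IS        shallow, shallow    intermediate, between shallow dives
TS        shallow, deep       terminal, just before the next deep
SS        deep, deep          single bout between back-to-back deeps
untyped   —                   a neighbor is missing (gap/record edge)
========  ==================  =====================================

The inter-deep-dive interval (IDDI) is the time from the end of one
deep dive to the start of the next, computed only when no message-loss
gap falls in between; intervals spanning a gap are excluded outright,
never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

from .behavior_log import BehaviorLog, BehaviorLogEvent
from .dive_classification import DEEP, SHALLOW, ClassifiedDive

FS = "FS"
IS = "IS"
TS = "TS"
SS = "SS"
UNTYPED = "untyped"

#: (preceding dive class, following dive class) -> bout type
BOUT_TYPE_TABLE = {
    (DEEP, SHALLOW): FS,
    (SHALLOW, SHALLOW): IS,
    (SHALLOW, DEEP): TS,
    (DEEP, DEEP): SS,
}


@dataclass
class TypedSurfacing:
    event: BehaviorLogEvent
    bout_type: str


@dataclass
class DeepDiveInterval:
    whale_id: str
    start: datetime  # end of the bounding deep dive
    end: datetime  # start of the next deep dive
    duration_min: float
    n_shallow: int


def _class_lookup(classified: Sequence[ClassifiedDive]) -> dict[int, str]:
    return {id(c.event): c.dive_class for c in classified}


def _adjacent(a: BehaviorLogEvent, b: BehaviorLogEvent) -> bool:
    """Contiguous in the record: b starts exactly where a ends."""
    return a.end == b.start


def type_surfacings(
    log: BehaviorLog, classified: Sequence[ClassifiedDive]
) -> list[TypedSurfacing]:
    """Type every surfacing bout from its bracketing dive classes.

    A surfacing at the record edge, or whose neighbor on either side is
    separated by a gap, is ``untyped``; neighbor classes are never
    guessed across missing record.
    """
    class_of = _class_lookup(classified)
    out: list[TypedSurfacing] = []
    events = log.events
    for i, e in enumerate(events):
        if e.kind != "surfacing":
            continue
        prev = events[i - 1] if i > 0 else None
        nxt = events[i + 1] if i + 1 < len(events) else None
        ok = (
            prev is not None
            and nxt is not None
            and prev.kind == "dive"
            and nxt.kind == "dive"
            and _adjacent(prev, e)
            and _adjacent(e, nxt)
            and id(prev) in class_of
            and id(nxt) in class_of
        )
        if ok:
            btype = BOUT_TYPE_TABLE[(class_of[id(prev)], class_of[id(nxt)])]
        else:
            btype = UNTYPED
        out.append(TypedSurfacing(e, btype))
    return out


def compute_iddis(
    log: BehaviorLog, classified: Sequence[ClassifiedDive]
) -> list[DeepDiveInterval]:
    """Gap-free intervals between consecutive deep dives.

    One interval per consecutive deep-dive pair whose intervening record
    contains no gap; ``n_shallow`` counts shallow dives lying entirely
    inside the interval.
    """
    class_of = _class_lookup(classified)
    dives = [e for e in log.events if e.kind == "dive" and id(e) in class_of]
    deep = [e for e in dives if class_of[id(e)] == DEEP]
    out: list[DeepDiveInterval] = []
    for a, b in zip(deep, deep[1:]):
        if any(g0 < b.start and g1 > a.end for g0, g1 in log.gaps):
            continue
        n_shallow = sum(
            1
            for e in dives
            if class_of[id(e)] == SHALLOW and e.start >= a.end and e.end <= b.start
        )
        out.append(
            DeepDiveInterval(
                whale_id=a.whale_id,
                start=a.end,
                end=b.start,
                duration_min=(b.start - a.end).total_seconds() / 60.0,
                n_shallow=n_shallow,
            )
        )
    return out


def deep_dive_rate(
    classified: Sequence[ClassifiedDive], total_bl_hours: float
) -> float:
    """Deep dives per hour of Behavior Log data (a foraging-rate proxy)."""
    if total_bl_hours <= 0:
        raise ValueError("total BL hours must be positive")
    n_deep = sum(c.dive_class == DEEP for c in classified)
    return n_deep / total_bl_hours
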