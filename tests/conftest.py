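"""Shared fixtures: hand-built event streams and simulated deployments."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from divetag.behavior_log import BehaviorLog, BehaviorLogEvent, detect_gaps
from divetag.dive_classification import ClassifiedDive
from divetag.synthetic_data import (
    reference_scenarios,
    scenario_with,
    simulate_deployment,
)

T0 = datetime(2011, 3, 1, 0, 0, tzinfo=timezone.utc)


def build_log(spec, t0=T0, whale_id="w1", sensor_mode="wet_dry"):
    """Build a contiguous BehaviorLog from a compact spec.

    ``spec`` is a list of entries:
      ("dive", duration_min, depth_m) | ("surf", duration_min) |
      ("gap", duration_min)  — advances the clock without an event.
    """
    events = []
    t = t0
    for entry in spec:
        kind = entry[0]
        dur = timedelta(minutes=entry[1])
        if kind == "gap":
            t = t + dur
            continue
        if kind == "dive":
            ev = BehaviorLogEvent(whale_id, "dive", t, t + dur, float(entry[2]), "Square")
        else:
            ev = BehaviorLogEvent(whale_id, "surfacing", t, t + dur)
        events.append(ev)
        t = ev.end
    return BehaviorLog(whale_id, sensor_mode, events, detect_gaps(events))


def classify_by_depth(log, threshold=800.0, flags=()):
    """Manual ClassifiedDive list: deep iff depth > threshold; ``flags``
    is a set of dive indices to mark borderline."""
    out = []
    for i, e in enumerate(log.dives()):
        cls = "deep" if e.max_depth > threshold else "shallow"
        c = ClassifiedDive(e, cls)
        c.borderline = i in set(flags)
        out.append(c)
    return out


def neutral(scenario, **extra):
    """Gap-free, diel-neutral variant of a scenario."""
    return scenario_with(
        scenario,
        gap_probability=0.0,
        duty_cycle_after_days=None,
        night_depth_offset_m=0.0,
        night_duration_offset_min=0.0,
        night_surface_multiplier=1.0,
        night_shallow_factor=1.0,
        p_extended_day=0.0,
        p_extended_night=0.0,
        **extra,
    )


@pytest.fixture(scope="session")
def presets():
    return reference_scenarios()


@pytest.fixture(scope="session")
def sim_zc010(presets):
    """One calibrated deployment with gaps and diel effects (336 h)."""
    return simulate_deployment(presets["Zc010"], seed=11, hours=336)


@pytest.fixture(scope="session")
def sim_gapfree(presets):
    """A gap-free, duty-cycle-free deployment; every surfacing typeable."""
    scn = scenario_with(presets["Zc015"], gap_probability=0.0, duty_cycle_after_days=None)
    return simulate_deployment(scn, seed=12, hours=336)
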