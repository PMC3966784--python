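"""Solar elevation and day/night assignment for tag events.

Implements the NOAA solar position equations (Julian century, geometric
mean solar longitude and anomaly, equation of center, apparent
longitude, corrected obliquity, declination, equation of time, true
solar time, hour angle) to compute the sun's elevation at an arbitrary
UTC time and location.  Each Behavior Log event is assigned ``day`` when
the solar elevation at its *start* time is >= 0 degrees and ``night``
otherwise, using the position estimate nearest in time to the event
(ties go to the earlier position).

Elevation is geometric by default; atmospheric refraction (which lifts
the apparent sun by ~0.57 degrees at the horizon) can be switched on but
only matters within minutes of sunrise/sunset.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np

from .behavior_log import BehaviorLogEvent, PositionEstimate

DAY = "day"
NIGHT = "night"


@dataclass
class DielAssignment:
    event: BehaviorLogEvent
    solar_elevation_deg: float
    diel_class: str
    position_used: PositionEstimate
    position_time_offset_s: float


def _julian_day(times_utc) -> np.ndarray:
    """Julian day from UTC datetimes (scalar or sequence)."""
    arr = np.atleast_1d(np.asarray(times_utc, dtype=object))
    unix = np.array(
        [
            (t if t.tzinfo else t.replace(tzinfo=timezone.utc)).timestamp()
            for t in arr
        ],
        dtype=float,
    )
    return unix / 86400.0 + 2440587.5


def solar_elevation(time_utc, lat, lon, refraction: bool = False):
    """Solar elevation angle in degrees.

    Accepts scalars or equal-length sequences of times and coordinates;
    returns a float for scalar input, else an ndarray.  ``lat`` must lie
    in [-90, 90].  Agrees with the NOAA solar calculator to within 0.1
    degree for |lat| <= 72.
    """
    scalar = isinstance(time_utc, datetime)
    lat_arr = np.atleast_1d(np.asarray(lat, dtype=float))
    lon_arr = np.atleast_1d(np.asarray(lon, dtype=float))
    if np.any(np.abs(lat_arr) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon_arr) > 180):
        raise ValueError("longitude outside [-180, 180]")

    jd = _julian_day(time_utc)
    jc = (jd - 2451545.0) / 36525.0

    gmls = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    seqc = (
        np.sin(np.radians(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(np.radians(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + np.sin(np.radians(3 * gmas)) * 0.000289
    )
    stl = gmls + seqc
    sal = stl - 0.00569 - 0.00478 * np.sin(np.radians(125.04 - 1934.136 * jc))
    moe = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    oc = moe + 0.00256 * np.cos(np.radians(125.04 - 1934.136 * jc))
    decl = np.degrees(np.arcsin(np.sin(np.radians(oc)) * np.sin(np.radians(sal))))

    vary = np.tan(np.radians(oc / 2.0)) ** 2
    eqtime = 4.0 * np.degrees(
        vary * np.sin(2 * np.radians(gmls))
        - 2 * eeo * np.sin(np.radians(gmas))
        + 4 * eeo * vary * np.sin(np.radians(gmas)) * np.cos(2 * np.radians(gmls))
        - 0.5 * vary**2 * np.sin(4 * np.radians(gmls))
        - 1.25 * eeo**2 * np.sin(2 * np.radians(gmas))
    )

    minutes_utc = np.mod(jd + 0.5, 1.0) * 1440.0
    tst = np.mod(minutes_utc + eqtime + 4.0 * lon_arr, 1440.0)
    ha = tst / 4.0 - 180.0
    ha = np.where(ha < -180.0, ha + 360.0, ha)

    cos_zen = np.sin(np.radians(lat_arr)) * np.sin(np.radians(decl)) + np.cos(
        np.radians(lat_arr)
    ) * np.cos(np.radians(decl)) * np.cos(np.radians(ha))
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))

    if refraction:
        elev = elev + _refraction_correction(elev)
    return float(elev[0]) if scalar and elev.size == 1 else elev


def _refraction_correction(elev: np.ndarray) -> np.ndarray:
    """NOAA atmospheric refraction correction, degrees."""
    e = np.asarray(elev, dtype=float)
    corr = np.zeros_like(e)
    t = np.tan(np.radians(np.where(np.abs(e) < 89.9, e, 89.9)))
    hi = (e <= 85) & (e > 5)
    corr = np.where(hi, (58.1 / t - 0.07 / t**3 + 0.000086 / t**5) / 3600.0, corr)
    mid = (e <= 5) & (e > -0.575)
    corr = np.where(
        mid,
        (1735 + e * (-518.2 + e * (103.4 + e * (-12.79 + e * 0.711)))) / 3600.0,
        corr,
    )
    lo = e <= -0.575
    corr = np.where(lo, (-20.772 / t) / 3600.0, corr)
    return corr


def assign_diel(
    events: Sequence[BehaviorLogEvent],
    positions: Sequence[PositionEstimate],
    refraction: bool = False,
) -> list[DielAssignment]:
    """Assign each event to day or night from the nearest position fix.

    For each event the position minimizing |event.start - position.time|
    is chosen (ties broken toward the earlier position), solar elevation
    is computed at the event start, and the event is ``day`` iff the
    elevation is >= 0.
    """
    if not positions:
        raise ValueError("cannot assign diel class: no positions for whale")
    pos = sorted(positions, key=lambda p: p.time)
    pos_t = np.array([p.time.timestamp() for p in pos])

    ev_t = np.array([e.start.timestamp() for e in events])
    idx = np.searchsorted(pos_t, ev_t)
    out: list[DielAssignment] = []
    chosen = []
    for i, t in zip(idx, ev_t):
        lo = max(i - 1, 0)
        hi = min(i, len(pos) - 1)
        # tie -> earlier position, hence strict < when comparing hi to lo
        if abs(pos_t[hi] - t) < abs(pos_t[lo] - t):
            chosen.append(hi)
        else:
            chosen.append(lo)
    lats = np.array([pos[i].lat for i in chosen])
    lons = np.array([pos[i].lon for i in chosen])
    times = [e.start for e in events]
    elev = solar_elevation(times, lats, lons, refraction=refraction)
    elev = np.atleast_1d(elev)
    for e, i, h in zip(events, chosen, elev):
        out.append(
            DielAssignment(
                event=e,
                solar_elevation_deg=float(h),
                diel_class=DAY if h >= 0 else NIGHT,
                position_used=pos[i],
                position_time_offset_s=abs(pos[i].time.timestamp() - e.start.timestamp()),
            )
        )
    return out
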