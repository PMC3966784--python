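"""Great-circle movement summaries from filtered Argos positions.

Positions are assumed already screened for plausibility (e.g. with the
Douglas Argos Filter); this module selects the single best position per
whale per UTC date (highest Argos quality class, ties broken by
proximity to local solar noon), attaches great-circle distances to the
deployment location, and counts occupancy of user-supplied regions by
even-odd point-in-polygon testing (boundary points count as inside).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from datetime import date
from typing import Sequence

from .behavior_log import PositionEstimate, quality_rank

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DailyBestPosition:
    whale_id: str
    date: date
    position: PositionEstimate
    distance_to_deploy_km: float


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in km on a sphere of radius 6371.0088 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _noon_offset_s(p: PositionEstimate) -> float:
    """Seconds between the fix and local solar noon (mean-sun) that day."""
    seconds_utc = (
        p.time.hour * 3600 + p.time.minute * 60 + p.time.second
    )
    noon_utc = 12 * 3600 - p.lon * 240.0  # 4 min per degree
    diff = abs(seconds_utc - noon_utc)
    return min(diff, 86400 - diff)


def best_daily_positions(
    positions: Sequence[PositionEstimate],
    deploy_lat: float,
    deploy_lon: float,
) -> list[DailyBestPosition]:
    """One best position per whale-UTC-date.

    Best = highest Argos quality class (3 > 2 > 1 > 0 > A > B); among
    equal-quality fixes, the one nearest local solar noon, so the daily
    position is representative of mid-day.  Remaining ties go to the
    earlier fix.
    """
    by_day: dict[tuple[str, date], list[PositionEstimate]] = defaultdict(list)
    for p in positions:
        by_day[(p.whale_id, p.time.date())].append(p)
    out = []
    for (wid, d), plist in sorted(by_day.items()):
        best = min(plist, key=lambda p: (quality_rank(p.quality), _noon_offset_s(p), p.time))
        out.append(
            DailyBestPosition(
                whale_id=wid,
                date=d,
                position=best,
                distance_to_deploy_km=great_circle_km(
                    best.lat, best.lon, deploy_lat, deploy_lon
                ),
            )
        )
    return out


def median_distance_to_deploy(
    daily: Sequence[DailyBestPosition],
) -> tuple[float, tuple[float, float]]:
    """Median and (min, max) of daily distances to the deployment site."""
    if not daily:
        raise ValueError("no daily positions")
    dists = sorted(d.distance_to_deploy_km for d in daily)
    n = len(dists)
    mid = n // 2
    median = dists[mid] if n % 2 else 0.5 * (dists[mid - 1] + dists[mid])
    return median, (dists[0], dists[-1])


def point_in_polygon(lon: float, lat: float, ring: Sequence[tuple[float, float]]) -> bool:
    """Even-odd point-in-polygon test on a closed lon/lat ring.

    The ring must repeat its first vertex last.  Points on an edge or
    vertex are counted inside.
    """
    if len(ring) < 4 or ring[0] != ring[-1]:
        raise ValueError("polygon ring must be closed (first vertex repeated last)")
    # boundary check first: on-segment points are inside by convention
    for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
        cross = (x2 - x1) * (lat - y1) - (y2 - y1) * (lon - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= lon <= max(x1, x2) + 1e-12 and (
                min(y1, y2) - 1e-12 <= lat <= max(y1, y2) + 1e-12
            ):
                return True
    inside = False
    for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
        if (y1 > lat) != (y2 > lat):
            x_cross = x1 + (lat - y1) * (x2 - x1) / (y2 - y1)
            if lon < x_cross:
                inside = not inside
    return inside


def region_occupancy(
    daily: Sequence[DailyBestPosition], ring: Sequence[tuple[float, float]]
) -> float:
    """Fraction of days whose best position lies inside the region.

    Denominator: days with any position (i.e. the daily list itself).
    """
    if not daily:
        raise ValueError("no daily positions")
    n_inside = sum(
        point_in_polygon(d.position.lon, d.position.lat, ring) for d in daily
    )
    return n_inside / len(daily)
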