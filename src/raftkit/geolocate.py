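"""Shore-based raft geolocation.

Observers on clifftops record, for each raft of birds on the water: a
magnetic compass bearing, an inclinometer angle below the horizontal
(the "declination"), and a bird count.  Knowing the cliff height above mean
sea level ``C``, the instantaneous tide height ``T`` (signed, relative to
mean sea level) and the inclinometer's own height ``H`` above the ground,
the horizontal range to the raft follows from right-triangle geometry::

    range = (C + H - T) / tan(declination)

The raft position is then the great-circle destination point from the
station at that range along the (declination-corrected) true bearing.
Rafts ranged at or beyond the 2,000 m survey boundary are flagged as not
retained, mirroring the field protocol's exclusion rule.

Curvature and refraction corrections are below 0.3 m at these ranges and
cliff heights and are ignored by default (an optional curvature mode is
provided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .geo import (
    EARTH_RADIUS_M,
    GeoPoint,
    destination_point,
    haversine_distance_arrays,
)

__all__ = [
    "INCLINOMETER_HEIGHT_M",
    "RETENTION_RANGE_M",
    "STATION_CLIFF_HEIGHTS_M",
    "GeometryError",
    "ObservationStation",
    "RaftObservation",
    "TideRecord",
    "GeolocatedRaft",
    "effective_eye_height",
    "raft_range",
    "georeference_raft",
    "distance_to_shore",
    "match_nearest_time",
]

#: Height of the inclinometer above the clifftop (metres).
INCLINOMETER_HEIGHT_M = 0.895

#: Survey boundary: rafts at this range or beyond are excluded.
RETENTION_RANGE_M = 2_000.0

#: Cliff heights above mean sea level (metres) of the four survey stations:
#: Garland Stone, Skomer Head, South Haven, North Haven.
STATION_CLIFF_HEIGHTS_M = {"GSN": 64.1, "SHD": 66.7, "SHV": 63.7, "NHV": 49.0}


class GeometryError(ValueError):
    """Physically impossible observation geometry."""


@dataclass(frozen=True)
class ObservationStation:
    name: str
    position: GeoPoint
    cliff_height_m: float

    def __post_init__(self) -> None:
        if self.cliff_height_m <= 0:
            raise GeometryError(f"cliff height must be positive, got {self.cliff_height_m}")


@dataclass(frozen=True)
class RaftObservation:
    station: ObservationStation
    timestamp: datetime
    magnetic_bearing_deg: float
    declination_deg: float  # line-of-sight angle below the horizontal
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"raft count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class TideRecord:
    timestamp: datetime
    height_m: float  # signed, relative to mean sea level

    def __post_init__(self) -> None:
        if not math.isfinite(self.height_m) or abs(self.height_m) >= 10.0:
            raise ValueError(f"implausible tide height: {self.height_m}")


@dataclass
class GeolocatedRaft:
    observation: RaftObservation
    range_from_station_m: float
    position: GeoPoint
    retained: bool
    distance_to_shore_m: float = field(default=float("nan"))


def effective_eye_height(cliff_height_m: float, tide_height_m: float,
                         inclinometer_height_m: float = INCLINOMETER_HEIGHT_M) -> float:
    """Observer eye (instrument) height above the instantaneous sea surface.

    ``C + H - T``: a higher tide raises the sea surface toward the observer.
    """
    if cliff_height_m <= 0:
        raise GeometryError(f"cliff height must be positive, got {cliff_height_m}")
    if inclinometer_height_m <= 0:
        raise GeometryError(f"inclinometer height must be positive, got {inclinometer_height_m}")
    eye = cliff_height_m + inclinometer_height_m - tide_height_m
    if eye <= 0:
        raise GeometryError(
            f"sea surface above observer: C={cliff_height_m}, T={tide_height_m}, H={inclinometer_height_m}"
        )
    return eye


def raft_range(eye_height_m: float, declination_deg: float) -> float:
    """Horizontal range to a raft sighted ``declination_deg`` below the horizon.

    Strictly decreasing in declination; diverges as the sight line approaches
    the horizontal.
    """
    if eye_height_m <= 0:
        raise GeometryError(f"eye height must be positive, got {eye_height_m}")
    if not 0.0 < declination_deg < 90.0:
        raise GeometryError(f"declination must lie in (0, 90) degrees, got {declination_deg}")
    return eye_height_m / math.tan(math.radians(declination_deg))


def georeference_raft(
    obs: RaftObservation,
    tide: TideRecord,
    magnetic_declination_offset_deg: float = 0.0,
    shoreline: Sequence[tuple[float, float]] | None = None,
    max_range_m: float = RETENTION_RANGE_M,
) -> GeolocatedRaft:
    """Convert one shore observation plus its matched tide into a positioned raft.

    The true bearing is ``magnetic_bearing + offset``; the raft is flagged as
    retained only when its range is strictly inside ``max_range_m``.  If a
    ``shoreline`` ((lat, lon) vertex sequence) is given, the minimum haversine
    distance to the densified shoreline is filled in.
    """
    eye = effective_eye_height(obs.station.cliff_height_m, tide.height_m)
    rng = raft_range(eye, obs.declination_deg)
    bearing = obs.magnetic_bearing_deg + magnetic_declination_offset_deg
    position = destination_point(obs.station.position, bearing, rng)
    # 1 um guard band: a range within numerical noise of the boundary counts
    # as at the boundary (the exclusion rule is "at the boundary and beyond")
    raft = GeolocatedRaft(
        observation=obs,
        range_from_station_m=rng,
        position=position,
        retained=rng < max_range_m - 1e-6,
    )
    if shoreline is not None:
        raft.distance_to_shore_m = distance_to_shore(position, shoreline)
    return raft


def _densify_ring(vertices: np.ndarray, spacing_m: float) -> np.ndarray:
    """Insert points along each edge of a (lat, lon) ring so that no gap
    exceeds ``spacing_m`` (linear interpolation in lat/lon; edges here are
    short enough that this is indistinguishable from the great circle)."""
    closed = np.vstack([vertices, vertices[:1]])
    seg_len = haversine_distance_arrays(
        closed[:-1, 0], closed[:-1, 1], closed[1:, 0], closed[1:, 1]
    )
    pts = []
    for i, length in enumerate(seg_len):
        n = max(1, int(np.ceil(length / spacing_m)))
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        pts.append(closed[i] + t[:, None] * (closed[i + 1] - closed[i]))
    return np.vstack(pts)


def distance_to_shore(
    p: GeoPoint,
    shoreline: Sequence[tuple[float, float]],
    densify_spacing_m: float = 10.0,
) -> float:
    """Minimum haversine distance (m) from a point to an island shoreline.

    ``shoreline`` is a sequence of (lat, lon) polygon vertices; edges are
    densified at ``densify_spacing_m`` so the result approximates the
    continuous boundary rather than the vertex set.
    """
    verts = np.asarray(shoreline, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("shoreline needs at least 3 (lat, lon) vertices")
    dense = _densify_ring(verts, densify_spacing_m)
    d = haversine_distance_arrays(p.lat, p.lon, dense[:, 0], dense[:, 1])
    return float(np.min(d))


def distances_to_shore(
    lats,
    lons,
    shoreline: Sequence[tuple[float, float]],
    densify_spacing_m: float = 10.0,
) -> np.ndarray:
    """Vectorised :func:`distance_to_shore` over arrays of points (the
    shoreline is densified once)."""
    verts = np.asarray(shoreline, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("shoreline needs at least 3 (lat, lon) vertices")
    dense = _densify_ring(verts, densify_spacing_m)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    out = np.empty(lats.shape, dtype=float)
    for i in range(lats.size):
        d = haversine_distance_arrays(lats.flat[i], lons.flat[i], dense[:, 0], dense[:, 1])
        out.flat[i] = np.min(d)
    return out


def match_nearest_time(
    record_time: datetime | pd.Timestamp,
    series_times: Sequence[datetime] | pd.DatetimeIndex,
    max_gap: pd.Timedelta = pd.Timedelta(hours=3),
) -> tuple[int, bool]:
    """Index of the record in a sorted time series nearest to ``record_time``.

    Ties (exact midpoints) break toward the earlier record.  Returns
    ``(index, flagged)`` where ``flagged`` marks gaps beyond ``max_gap``.
    """
    times = pd.DatetimeIndex(series_times)
    if len(times) == 0:
        raise ValueError("empty time series")
    if not times.is_monotonic_increasing:
        raise ValueError("time series must be sorted")
    t = pd.Timestamp(record_time)
    pos = int(np.searchsorted(times.values, t.to_datetime64()))
    candidates = [i for i in (pos - 1, pos) if 0 <= i < len(times)]
    # earlier record first -> on a tie the earlier index wins the strict '<'
    best = min(candidates, key=lambda i: (abs(times[i] - t), i))
    flagged = abs(times[best] - t) > max_gap
    return best, flagged
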