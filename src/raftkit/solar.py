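"""Solar position and sunrise/sunset from the NOAA solar calculator equations.

Used to label GPS segments as day or night (night: solar elevation below
-0.833 degrees, the standard sunrise/sunset convention including average
atmospheric refraction and the solar semidiameter) and to locate the
"two hours before sunset / after sunrise" observation windows.

Accuracy is a few hundredths of a degree in elevation and well under two
minutes on rise/set times at mid-latitudes, ample for diel labelling.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone

__all__ = [
    "SUNSET_ELEVATION_DEG",
    "solar_elevation",
    "sunrise_sunset",
    "is_night",
]

#: Elevation of the solar centre at geometric sunrise/sunset (refraction
#: -34' plus semidiameter -16').
SUNSET_ELEVATION_DEG = -0.833


def _julian_day(dt: datetime) -> float:
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    dt = dt.astimezone(timezone.utc)
    y, m = dt.year, dt.month
    d = dt.day + (dt.hour + dt.minute / 60.0 + dt.second / 3600.0 + dt.microsecond / 3.6e9) / 24.0
    if m <= 2:
        y -= 1
        m += 12
    A = y // 100
    B = 2 - A + A // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + B - 1524.5


def _solar_coords(jc: float) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes) at Julian
    century ``jc`` past J2000."""
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(omega)
    eps_rad = math.radians(eps)
    decl = math.asin(math.sin(eps_rad) * math.sin(math.radians(app_long)))
    y = math.tan(eps_rad / 2.0) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * e * math.sin(mrad)
        + 4.0 * e * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mrad)
    )
    return decl, eot


def solar_elevation(dt_utc: datetime, lat: float, lon: float) -> float:
    """Apparent-free (geometric) solar elevation in degrees at a UTC instant."""
    jd = _julian_day(dt_utc)
    jc = (jd - 2451545.0) / 36525.0
    decl, eot = _solar_coords(jc)
    if dt_utc.tzinfo is None:
        dt_utc = dt_utc.replace(tzinfo=timezone.utc)
    dt_utc = dt_utc.astimezone(timezone.utc)
    minutes = dt_utc.hour * 60.0 + dt_utc.minute + dt_utc.second / 60.0 + dt_utc.microsecond / 6e7
    tst = (minutes + eot + 4.0 * lon) % 1440.0
    ha = math.radians(tst / 4.0 - 180.0)
    phi = math.radians(lat)
    cos_zen = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(ha)
    return 90.0 - math.degrees(math.acos(max(-1.0, min(1.0, cos_zen))))


def sunrise_sunset(day: date, lat: float, lon: float) -> tuple[datetime, datetime]:
    """UTC sunrise and sunset on a calendar day at a position.

    Raises ``ValueError`` if the sun never crosses the horizon (polar
    day/night); not reachable at the mid-latitudes this package targets.
    """
    noon_guess = datetime(day.year, day.month, day.day, 12, 0, tzinfo=timezone.utc)
    times = []
    for which in ("rise", "set"):
        # two passes: evaluate declination/EoT at the previous estimate
        est = noon_guess
        for _ in range(2):
            jc = (_julian_day(est) - 2451545.0) / 36525.0
            decl, eot = _solar_coords(jc)
            phi = math.radians(lat)
            cos_ha = (
                math.cos(math.radians(90.0 - SUNSET_ELEVATION_DEG)) / (math.cos(phi) * math.cos(decl))
                - math.tan(phi) * math.tan(decl)
            )
            if not -1.0 <= cos_ha <= 1.0:
                raise ValueError(f"sun does not cross the horizon at lat={lat} on {day}")
            ha_deg = math.degrees(math.acos(cos_ha))
            if which == "rise":
                minutes = 720.0 - 4.0 * (lon + ha_deg) - eot
            else:
                minutes = 720.0 - 4.0 * (lon - ha_deg) - eot
            est = datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(minutes=minutes)
        times.append(est)
    return times[0], times[1]


def is_night(dt_utc: datetime, lat: float, lon: float) -> bool:
    """Night iff the solar elevation is below the rise/set convention."""
    return solar_elevation(dt_utc, lat, lon) < SUNSET_ELEVATION_DEG
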