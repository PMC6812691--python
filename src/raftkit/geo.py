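"""Great-circle and ellipsoidal geodesy primitives.

All coordinates are WGS84 decimal degrees; bearings are degrees clockwise
from true north; internal angle arithmetic is in radians.  Distances are in
metres.  The working scale of the package is a few kilometres around a small
island, where spherical and ellipsoidal distances agree to well under 0.5%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EARTH_RADIUS_M",
    "WGS84_A",
    "WGS84_B",
    "WGS84_F",
    "GeoPoint",
    "GeodesyError",
    "haversine_distance",
    "geodesic_distance",
    "destination_point",
    "initial_bearing",
]

#: Mean Earth radius used for all spherical formulae (overridable per call).
EARTH_RADIUS_M = 6_371_000.0

#: WGS84 ellipsoid: semi-major axis, flattening, semi-minor axis.
WGS84_A = 6_378_137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)


class GeodesyError(ValueError):
    """Invalid geometry input (non-finite coordinate, undefined bearing...)."""


def _normalise_lon(lon: float) -> float:
    """Wrap a longitude into [-180, 180)."""
    return ((lon + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position.

    Latitude in [-90, 90] decimal degrees; longitude normalised to
    [-180, 180) on construction.
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise GeodesyError(f"non-finite coordinates: ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise GeodesyError(f"latitude out of range: {self.lat}")
        object.__setattr__(self, "lon", _normalise_lon(self.lon))


def haversine_distance(a: GeoPoint, b: GeoPoint, sphere_radius: float = EARTH_RADIUS_M) -> float:
    """Great-circle distance between two points on a sphere, in metres.

    Symmetric, non-negative, and bounded by pi * radius.
    """
    if sphere_radius <= 0:
        raise GeodesyError(f"sphere radius must be positive, got {sphere_radius}")
    return float(
        haversine_distance_arrays(
            np.asarray(a.lat), np.asarray(a.lon), np.asarray(b.lat), np.asarray(b.lon), sphere_radius
        )
    )


def haversine_distance_arrays(lat1, lon1, lat2, lon2, sphere_radius: float = EARTH_RADIUS_M):
    """Vectorised haversine over arrays of decimal degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards rounding for antipodal / coincident points
    return 2.0 * sphere_radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geodesic_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Ellipsoidal (WGS84) distance via Vincenty's inverse formula, in metres.

    Iterates to 1e-12 on the auxiliary longitude; on the rare non-convergent
    (near-antipodal) pair it falls back to the spherical value with a warning.
    """
    d, converged = geodesic_distance_arrays(
        np.asarray([a.lat]), np.asarray([a.lon]), np.asarray([b.lat]), np.asarray([b.lon])
    )
    if not converged[0]:
        warnings.warn(
            "Vincenty iteration did not converge (near-antipodal pair); "
            "falling back to spherical distance",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(d[0])


def geodesic_distance_arrays(lat1, lon1, lat2, lon2, tol: float = 1e-12, max_iter: int = 200):
    """Vectorised Vincenty inverse distance on the WGS84 ellipsoid.

    Returns ``(distance_m, converged)``; non-convergent pairs carry the
    haversine fallback value with ``converged=False``.
    """
    lat1 = np.asarray(lat1, dtype=float)
    lon1 = np.asarray(lon1, dtype=float)
    lat2 = np.asarray(lat2, dtype=float)
    lon2 = np.asarray(lon2, dtype=float)

    a, b, f = WGS84_A, WGS84_B, WGS84_F
    U1 = np.arctan((1.0 - f) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1.0 - f) * np.tan(np.radians(lat2)))
    L = np.radians(lon2 - lon1)
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    active = np.ones(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    coincident = (lat1 == lat2) & (np.mod(lon1 - lon2, 360.0) == 0.0)

    for _ in range(max_iter):
        if not active.any():
            break
        sl, cl = np.sin(lam[active]), np.cos(lam[active])
        su1, cu1 = sinU1[active], cosU1[active]
        su2, cu2 = sinU2[active], cosU2[active]
        ss = np.sqrt((cu2 * sl) ** 2 + (cu1 * su2 - su1 * cu2 * cl) ** 2)
        cs = su1 * su2 + cu1 * cu2 * cl
        sig = np.arctan2(ss, cs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(ss > 0, cu1 * cu2 * sl / np.where(ss > 0, ss, 1.0), 0.0)
        csa = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2sm = np.where(csa > 0, cs - 2.0 * su1 * su2 / np.where(csa > 0, csa, 1.0), 0.0)
        C = f / 16.0 * csa * (4.0 + f * (4.0 - 3.0 * csa))
        lam_new = L[active] + (1.0 - C) * f * sin_alpha * (
            sig + C * ss * (c2sm + C * cs * (-1.0 + 2.0 * c2sm**2))
        )

        sin_sigma[active] = ss
        cos_sigma[active] = cs
        sigma[active] = sig
        cos_sq_alpha[active] = csa
        cos2sm[active] = c2sm

        done = np.abs(lam_new - lam[active]) < tol
        lam[active] = lam_new
        idx = np.flatnonzero(active)
        active[idx[done]] = False

    converged = ~active
    u_sq = cos_sq_alpha * (a**2 - b**2) / b**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = B * sin_sigma * (
        cos2sm
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - B / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    dist = b * A * (sigma - delta_sigma)
    dist = np.where(coincident, 0.0, dist)
    converged = converged | coincident
    if not converged.all():
        fallback = haversine_distance_arrays(lat1, lon1, lat2, lon2)
        dist = np.where(converged, dist, fallback)
    return dist, converged


def destination_point(
    origin: GeoPoint,
    bearing_deg: float,
    distance_m: float,
    sphere_radius: float = EARTH_RADIUS_M,
) -> GeoPoint:
    """Point reached travelling ``distance_m`` along a great circle from
    ``origin`` at initial bearing ``bearing_deg`` (degrees true, mod 360)."""
    if distance_m < 0:
        raise GeodesyError(f"distance must be non-negative, got {distance_m}")
    if not math.isfinite(bearing_deg):
        raise GeodesyError(f"non-finite bearing: {bearing_deg}")
    if distance_m == 0:
        return origin
    delta = distance_m / sphere_radius
    theta = math.radians(bearing_deg % 360.0)
    phi1 = math.radians(origin.lat)
    lam1 = math.radians(origin.lon)
    sin_phi2 = math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    phi2 = math.asin(max(-1.0, min(1.0, sin_phi2)))
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * sin_phi2,
    )
    return GeoPoint(math.degrees(phi2), math.degrees(lam2))


def initial_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Initial great-circle bearing from ``a`` to ``b``, degrees true in [0, 360)."""
    if a.lat == b.lat and a.lon == b.lon:
        raise GeodesyError("bearing undefined for coincident points")
    return float(initial_bearing_arrays(a.lat, a.lon, b.lat, b.lon))


def initial_bearing_arrays(lat1, lon1, lat2, lon2):
    """Vectorised initial bearing, degrees true in [0, 360)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)
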