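"""GPS-track behavioural classification.

Raw 5-minute GPS fixes from breeding seabirds are turned into between-fix
speed segments, cleaned (fixes on land removed, implausible speeds above an
error threshold excluded), and labelled as *rafting* (sitting on the water)
or *flying*.  The rafting/flying boundary is the equal-posterior speed of a
two-component normal mixture fitted to the pooled speeds by
expectation-maximisation: below that speed a fix is more likely to have come
from the slow (rafting) component, above it from the fast (flying) one.

Segments are further annotated day/night from solar elevation and flagged
by whether they fall within the 5 km study radius of the colony.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import brentq
from scipy.stats import norm
from shapely.geometry import Polygon

from .geo import (
    GeoPoint,
    geodesic_distance_arrays,
    haversine_distance,
    initial_bearing_arrays,
)
from .solar import SUNSET_ELEVATION_DEG, solar_elevation

__all__ = [
    "MAX_PLAUSIBLE_SPEED_MS",
    "DEFAULT_SPEED_THRESHOLD_MS",
    "STUDY_RADIUS_M",
    "NORTH_HAVEN_COLONY",
    "SpeedMixture",
    "MixtureFitError",
    "remove_land_fixes",
    "compute_speeds",
    "filter_speed_errors",
    "fit_speed_mixture",
    "classification_threshold",
    "classify_behaviour",
    "day_night_label",
    "within_radius",
    "behaviour_summary",
]

logger = logging.getLogger(__name__)

#: Speed filter: segments faster than this are GPS errors, not birds.
MAX_PLAUSIBLE_SPEED_MS = 30.0

#: Rafting/flying boundary used when no mixture is fitted.
DEFAULT_SPEED_THRESHOLD_MS = 2.5

#: Radius around the colony defining the nearshore study area.
STUDY_RADIUS_M = 5_000.0

#: North Haven sub-colony, Skomer Island (51d44'14.0"N, 5d16'55.5"W).
NORTH_HAVEN_COLONY = GeoPoint(51.0 + 44.0 / 60 + 14.0 / 3600, -(5.0 + 16.0 / 60 + 55.5 / 3600))


class MixtureFitError(RuntimeError):
    """EM failed to produce a usable two-component fit."""


@dataclass(frozen=True)
class SpeedMixture:
    """A fitted two-component normal mixture of speeds, ordered mu1 < mu2."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    w1: float
    w2: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    threshold: float
    poorly_separated: bool = False


# ---------------------------------------------------------------------------
# cleaning


def remove_land_fixes(tracks: pd.DataFrame, land: Polygon) -> pd.DataFrame:
    """Drop fixes whose position falls inside the land polygon.

    ``tracks`` needs ``lat``/``lon`` columns; the polygon is in lon-lat
    (GeoJSON) axis order.
    """
    pts = shapely.points(tracks["lon"].to_numpy(), tracks["lat"].to_numpy())
    on_land = shapely.contains(land, pts)
    n_removed = int(on_land.sum())
    if n_removed:
        logger.info("removed %d fixes on land", n_removed)
    return tracks.loc[~on_land].reset_index(drop=True)


def compute_speeds(tracks: pd.DataFrame) -> pd.DataFrame:
    """Between-fix speed segments per bird.

    Expects columns ``bird_id, timestamp, lat, lon``; timestamps strictly
    increasing within a bird (duplicate timestamps are collapsed to the
    first fix with a warning).  Returns one row per consecutive fix pair
    with ellipsoidal speed (m/s) and initial bearing, labels initialised to
    ``unclassified``.
    """
    frames = []
    for bird, grp in tracks.groupby("bird_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        dup = grp["timestamp"].duplicated()
        if dup.any():
            logger.warning("bird %s: collapsed %d duplicate timestamps", bird, int(dup.sum()))
            grp = grp.loc[~dup].reset_index(drop=True)
        if len(grp) < 2:
            continue
        lat, lon = grp["lat"].to_numpy(), grp["lon"].to_numpy()
        t = pd.DatetimeIndex(grp["timestamp"])
        dt = (t[1:] - t[:-1]).total_seconds()
        if (dt <= 0).any():
            bad = t[1:][dt <= 0][0]
            raise ValueError(f"non-increasing timestamps for bird {bird} at {bad}")
        dist, _ = geodesic_distance_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
        with np.errstate(invalid="ignore"):
            bearing = initial_bearing_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
        frames.append(
            pd.DataFrame(
                {
                    "bird_id": bird,
                    "start_time": t[:-1],
                    "end_time": t[1:],
                    "start_lat": lat[:-1],
                    "start_lon": lon[:-1],
                    "end_lat": lat[1:],
                    "end_lon": lon[1:],
                    "speed_ms": dist / dt,
                    "bearing_deg": bearing,
                    "behaviour": "unclassified",
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "bird_id", "start_time", "end_time", "start_lat", "start_lon",
                "end_lat", "end_lon", "speed_ms", "bearing_deg", "behaviour",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def filter_speed_errors(segments: pd.DataFrame, max_speed: float = MAX_PLAUSIBLE_SPEED_MS) -> pd.DataFrame:
    """Mark segments faster than ``max_speed`` as ``excluded`` (never dropped)."""
    if max_speed <= 0:
        raise ValueError(f"max_speed must be positive, got {max_speed}")
    out = segments.copy()
    bad = out["speed_ms"] > max_speed
    out.loc[bad, "behaviour"] = "excluded"
    logger.info("speed filter: %d kept, %d excluded", int((~bad).sum()), int(bad.sum()))
    return out


# ---------------------------------------------------------------------------
# speed mixture


def _em_two_normal(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray, w: np.ndarray,
                   tol: float, max_iter: int):
    """EM iterations for a 2-component normal mixture; returns params + loglik
    trace, or None on a degenerate component."""
    ll_prev = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E step
        log_comp = np.stack(
            [np.log(w[k]) + norm.logpdf(x, mu[k], sigma[k]) for k in range(2)]
        )
        log_norm = np.logaddexp(log_comp[0], log_comp[1])
        ll = float(np.sum(log_norm))
        resp = np.exp(log_comp - log_norm)
        # M step
        nk = resp.sum(axis=1)
        if (nk < 1e-8).any():
            return None
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        if (var < 1e-12).any():
            return None
        sigma = np.sqrt(var)
        w = nk / len(x)
        if ll - ll_prev < 0 and abs(ll - ll_prev) > 1e-6 * abs(ll):
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        if abs(ll - ll_prev) < tol * (abs(ll) + tol):
            converged = True
            break
        ll_prev = ll
    return mu, sigma, w, ll, n_iter, converged


def fit_speed_mixture(
    speeds: np.ndarray,
    seed: int = 0,
    n_starts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1_000,
) -> SpeedMixture:
    """Fit the two-normal speed mixture by EM with jittered restarts.

    Initialisation is quantile based (component means at the 25th/75th
    percentiles, pooled sd, equal weights); ``n_starts - 1`` further starts
    jitter the means.  The best log-likelihood wins; components are returned
    ordered ``mu1 < mu2`` together with the equal-posterior threshold.
    """
    x = np.asarray(speeds, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise MixtureFitError(f"need at least 50 speeds, got {len(x)}")
    if (x < 0).any():
        raise MixtureFitError("speeds must be non-negative")
    if np.std(x) < 1e-12:
        raise MixtureFitError("speeds have zero variance")

    rng = np.random.default_rng(seed)
    q25, q75 = np.quantile(x, [0.25, 0.75])
    sd = np.std(x)
    best = None
    for start in range(n_starts):
        mu = np.array([q25, q75], dtype=float)
        if start > 0:
            mu = mu + rng.normal(0.0, 0.25 * sd, size=2)
        res = _em_two_normal(x, mu, np.array([sd, sd]), np.array([0.5, 0.5]), tol, max_iter)
        if res is None:
            continue
        if best is None or res[3] > best[3]:
            best = res
    if best is None:
        raise MixtureFitError("all EM restarts hit a degenerate component")

    mu, sigma, w, ll, n_iter, converged = best
    order = np.argsort(mu)
    mu, sigma, w = mu[order], sigma[order], w[order]
    # overlap diagnostic: components closer than one pooled sd apart
    poorly_separated = (mu[1] - mu[0]) < max(sigma[0], sigma[1])
    thr = _equal_posterior_threshold(mu[0], sigma[0], w[0], mu[1], sigma[1], w[1])
    return SpeedMixture(
        mu1=float(mu[0]), sigma1=float(sigma[0]),
        mu2=float(mu[1]), sigma2=float(sigma[1]),
        w1=float(w[0]), w2=float(w[1]),
        log_likelihood=float(ll), n_iterations=n_iter, converged=converged,
        threshold=thr, poorly_separated=bool(poorly_separated),
    )


def _equal_posterior_threshold(mu1, s1, w1, mu2, s2, w2) -> float:
    """Root of w1*phi(s; mu1, s1) = w2*phi(s; mu2, s2) in (mu1, mu2)."""
    def logdiff(s):
        return (math.log(w1) + norm.logpdf(s, mu1, s1)) - (math.log(w2) + norm.logpdf(s, mu2, s2))

    eps = 1e-9 * max(1.0, mu2 - mu1)
    lo, hi = mu1 + eps, mu2 - eps
    flo, fhi = logdiff(lo), logdiff(hi)
    if flo * fhi > 0:
        raise MixtureFitError(
            "no equal-posterior crossing between the component means (pathological overlap)"
        )
    return float(brentq(logdiff, lo, hi, xtol=1e-12))


def classification_threshold(m: SpeedMixture) -> float:
    """Equal-posterior speed of a fitted mixture, strictly inside (mu1, mu2)."""
    return _equal_posterior_threshold(m.mu1, m.sigma1, m.w1, m.mu2, m.sigma2, m.w2)


def classify_behaviour(segments: pd.DataFrame, threshold: float = DEFAULT_SPEED_THRESHOLD_MS) -> pd.DataFrame:
    """Label non-excluded segments rafting (speed strictly below the
    threshold) or flying (at or above it)."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    out = segments.copy()
    ok = out["behaviour"] != "excluded"
    out.loc[ok, "behaviour"] = np.where(out.loc[ok, "speed_ms"] < threshold, "rafting", "flying")
    return out


# ---------------------------------------------------------------------------
# annotation


def day_night_label(timestamp: datetime, location: GeoPoint) -> tuple[str, float]:
    """('day'|'night', solar elevation deg); night below the rise/set elevation."""
    elev = solar_elevation(timestamp, location.lat, location.lon)
    return ("night" if elev < SUNSET_ELEVATION_DEG else "day"), elev


def within_radius(p: GeoPoint, centre: GeoPoint = NORTH_HAVEN_COLONY,
                  radius_m: float = STUDY_RADIUS_M) -> bool:
    """Strict haversine test against the study radius."""
    return haversine_distance(p, centre) < radius_m


def annotate_segments(segments: pd.DataFrame, centre: GeoPoint = NORTH_HAVEN_COLONY,
                      radius_m: float = STUDY_RADIUS_M) -> pd.DataFrame:
    """Add ``day_night`` and ``within_5km`` columns (evaluated at the
    segment's end fix, where the behaviour label lives)."""
    out = segments.copy()
    elev = np.array([
        solar_elevation(ts, la, lo)
        for ts, la, lo in zip(out["end_time"], out["end_lat"], out["end_lon"])
    ])
    out["day_night"] = np.where(elev < SUNSET_ELEVATION_DEG, "night", "day")
    from .geo import haversine_distance_arrays

    d = haversine_distance_arrays(out["end_lat"].to_numpy(), out["end_lon"].to_numpy(),
                                  centre.lat, centre.lon)
    out["within_5km"] = d < radius_m
    return out


def behaviour_summary(segments: pd.DataFrame) -> pd.DataFrame:
    """Rafting/flying fractions among non-excluded within-radius segments,
    plus the day/night split of rafting."""
    if segments.empty:
        logger.warning("behaviour_summary called on empty segment set")
        return pd.DataFrame(columns=["metric", "fraction"])
    sel = segments
    if "within_5km" in sel.columns:
        sel = sel[sel["within_5km"]]
    sel = sel[sel["behaviour"].isin(["rafting", "flying"])]
    n = len(sel)
    rows = []
    if n:
        n_raft = int((sel["behaviour"] == "rafting").sum())
        rows.append(("rafting", n_raft / n))
        rows.append(("flying", (n - n_raft) / n))
        rafting = sel[sel["behaviour"] == "rafting"]
        if "day_night" in rafting.columns and len(rafting):
            n_night = int((rafting["day_night"] == "night").sum())
            rows.append(("rafting_night", n_night / len(rafting)))
            rows.append(("rafting_day", 1.0 - n_night / len(rafting)))
    return pd.DataFrame(rows, columns=["metric", "fraction"])
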