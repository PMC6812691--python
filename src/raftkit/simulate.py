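"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the structure of a one-month colony study: two-state
(rafting/flying) GPS tracks at 5-minute fixes around a small island,
clifftop raft observations produced by inverting the inclinometer geometry
from known raft positions, wind and tide series, and a raft-size series
with a log-linear wind dependence and MA(4) within-day error correlation.
All ground truth is returned alongside the data, so every downstream module
can be tested end to end without field data.

Defaults follow the study's stated world where it states one: rafting and
flying speed components straddling a ~2.5 m/s boundary, wind speeds spanning
roughly 2-18 m/s with an 8 m/s mean, the survey's four cliff heights, and
size-model truth taken from the published coefficient table.  The rest
(state-switch rates, heading concentrations, the circular 1 km island) are
fixture conventions documented in the methods note, not field estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .geo import GeoPoint, destination_point, haversine_distance, initial_bearing
from .geolocate import (
    INCLINOMETER_HEIGHT_M,
    ObservationStation,
    STATION_CLIFF_HEIGHTS_M,
)
from .sizemodel import ma_acf
from .solar import is_night
from .tracks import NORTH_HAVEN_COLONY

__all__ = [
    "SimConfig",
    "synthetic_island",
    "synthetic_stations",
    "simulate_tracks",
    "simulate_observations",
    "simulate_weather",
    "simulate_tides",
    "simulate_size_series",
    "simulate_circular_pairs",
]


@dataclass
class SimConfig:
    """The stated world of the synthetic colony.

    Speeds are m/s, distances metres, angles degrees unless noted.
    """

    seed: int = 0
    n_birds: int = 10
    days: int = 3
    start: datetime = field(default_factory=lambda: datetime(2016, 8, 5, tzinfo=timezone.utc))
    fix_interval_s: float = 300.0

    # two-component speed truth: slow (rafting) and fast (flying)
    raft_speed_mu: float = 1.0
    raft_speed_sd: float = 0.5
    fly_speed_mu: float = 9.0
    fly_speed_sd: float = 2.5
    p_raft_to_fly: float = 0.04
    p_fly_to_raft: float = 0.10
    heading_kappa_raft: float = 8.0    # drifting rafts hold a loose heading
    heading_kappa_fly: float = 4.0

    # geography: circular island, colony at its centre
    island_centre: GeoPoint = field(default_factory=lambda: NORTH_HAVEN_COLONY)
    island_radius_m: float = 1_000.0
    island_vertices: int = 180

    # diel halo: target distance from the island centre by day / by night
    day_offset_m: float = 900.0
    night_offset_m: float = 300.0
    offset_kappa: float = 6.0          # how tightly birds track the target ring

    # raft-size model truth (log-linear in wind, MA(4) errors within day)
    size_beta0: float = 4.674
    size_beta1: float = 0.065
    size_theta: tuple[float, float, float, float] = (0.088, 0.162, 0.185, 0.162)
    size_sigma: float = 1.146          # marginal residual sd on the log scale
    rafts_per_day: int = 11

    # wind and tide regimes
    wind_mean: float = 8.0
    wind_sd: float = 3.5
    wind_min: float = 2.1
    wind_max: float = 17.6
    wind_dir_mu_deg: float = 270.0
    wind_dir_kappa: float = 2.0
    tide_amplitude_m: float = 2.0
    tide_period_h: float = 12.42       # principal lunar semidiurnal

    def __post_init__(self) -> None:
        for name in ("raft_speed_sd", "fly_speed_sd", "wind_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_raft_to_fly", "p_fly_to_raft"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.island_radius_m <= 0:
            raise ValueError("island_radius_m must be positive")
        if haversine_distance(self.island_centre, NORTH_HAVEN_COLONY) > 50_000:
            # colony and island are a single nearshore system in this world
            raise ValueError("island centre implausibly far from the colony")


def synthetic_island(cfg: SimConfig) -> list[tuple[float, float]]:
    """(lat, lon) vertices of the circular synthetic island."""
    pts = []
    for b in np.linspace(0.0, 360.0, cfg.island_vertices, endpoint=False):
        p = destination_point(cfg.island_centre, float(b), cfg.island_radius_m)
        pts.append((p.lat, p.lon))
    return pts


def synthetic_stations(cfg: SimConfig) -> list[ObservationStation]:
    """Four clifftop stations on the synthetic island rim, carrying the
    survey's cliff heights."""
    bearings = {"GSN": 0.0, "NHV": 90.0, "SHV": 180.0, "SHD": 270.0}
    return [
        ObservationStation(
            name=name,
            position=destination_point(cfg.island_centre, b, cfg.island_radius_m),
            cliff_height_m=STATION_CLIFF_HEIGHTS_M[name],
        )
        for name, b in bearings.items()
    ]


# ---------------------------------------------------------------------------
# GPS tracks


def simulate_tracks(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Two-state Markov GPS tracks with a diel halo.

    Returns a fix table ``bird_id, timestamp, lat, lon, true_state`` where
    ``true_state`` labels the behaviour that generated the *step ending* at
    the fix (the first fix of a bird carries its initial state).  Headings
    are von Mises; rafting headings drift slowly to mimic wind/tide carriage.
    Birds steer toward a target ring around the island whose radius is the
    day or night offset, producing a daytime halo that closes at night.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_steps = int(round(cfg.days * 86_400 / cfg.fix_interval_s))
    rows = []
    for b in range(cfg.n_birds):
        bird = f"bird{b:03d}"
        state = "rafting" if rng.random() < 0.7 else "flying"
        # start on the day ring at a random azimuth
        az = rng.uniform(0.0, 360.0)
        pos = destination_point(cfg.island_centre, az, cfg.island_radius_m + cfg.day_offset_m)
        heading = rng.uniform(0.0, 360.0)
        t = cfg.start
        rows.append((bird, t, pos.lat, pos.lon, state))
        for _ in range(n_steps):
            p_switch = cfg.p_raft_to_fly if state == "rafting" else cfg.p_fly_to_raft
            if rng.random() < p_switch:
                state = "flying" if state == "rafting" else "rafting"
            if state == "rafting":
                mu, sd, kappa = cfg.raft_speed_mu, cfg.raft_speed_sd, cfg.heading_kappa_raft
            else:
                mu, sd, kappa = cfg.fly_speed_mu, cfg.fly_speed_sd, cfg.heading_kappa_fly
            speed = max(0.0, rng.normal(mu, sd))
            # steer toward the diel target ring
            offset = cfg.night_offset_m if is_night(t, pos.lat, pos.lon) else cfg.day_offset_m
            target_r = cfg.island_radius_m + offset
            r_now = haversine_distance(cfg.island_centre, pos)
            if r_now < 1.0:
                base = rng.uniform(0.0, 360.0)
            else:
                outward = initial_bearing(cfg.island_centre, pos)
                base = outward if r_now < target_r else (outward + 180.0) % 360.0
            # blend persistence with the steering direction
            pull = np.degrees(np.angle(np.exp(1j * np.radians(base - heading))))
            heading = (heading + 0.5 * pull + np.degrees(rng.vonmises(0.0, kappa))) % 360.0
            step = speed * cfg.fix_interval_s
            new = destination_point(pos, heading, step)
            if haversine_distance(cfg.island_centre, new) < cfg.island_radius_m:
                # bounce off the shoreline instead of walking onto land
                heading = (heading + 180.0) % 360.0
                new = destination_point(pos, heading, step)
            pos = new
            t = t + timedelta(seconds=cfg.fix_interval_s)
            rows.append((bird, t, pos.lat, pos.lon, state))
    return pd.DataFrame(rows, columns=["bird_id", "timestamp", "lat", "lon", "true_state"])


# ---------------------------------------------------------------------------
# shore observations


def simulate_tides(cfg: SimConfig, rng: np.random.Generator | None = None,
                   interval_min: int = 15) -> pd.DataFrame:
    """Sinusoidal semidiurnal tide series, metres about mean sea level."""
    n = int(cfg.days * 24 * 60 / interval_min) + 1
    t = pd.date_range(cfg.start, periods=n, freq=f"{interval_min}min")
    hours = (t - t[0]).total_seconds() / 3600.0
    h = cfg.tide_amplitude_m * np.sin(2.0 * np.pi * hours / cfg.tide_period_h)
    return pd.DataFrame({"timestamp": t, "height_m": h})


def simulate_weather(cfg: SimConfig, rng: np.random.Generator | None = None,
                     interval_min: int = 60) -> pd.DataFrame:
    """Hourly wind series: truncated-normal speeds, von Mises directions."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = int(cfg.days * 24 * 60 / interval_min) + 1
    t = pd.date_range(cfg.start, periods=n, freq=f"{interval_min}min")
    # daily mean with hourly wobble, truncated to the observed range
    day_idx = ((t - t[0]).days).to_numpy()
    day_means = rng.normal(cfg.wind_mean, cfg.wind_sd, size=int(day_idx.max()) + 1)
    speed = np.clip(day_means[day_idx] + rng.normal(0.0, 0.8, size=n),
                    cfg.wind_min, cfg.wind_max)
    direction = np.degrees(rng.vonmises(np.radians(cfg.wind_dir_mu_deg - 180.0),
                                        cfg.wind_dir_kappa, size=n)) % 360.0
    return pd.DataFrame({"timestamp": t, "wind_speed_ms": speed, "wind_dir_deg": direction})


def simulate_observations(
    cfg: SimConfig,
    true_rafts: pd.DataFrame,
    stations: list[ObservationStation] | None = None,
    tides: pd.DataFrame | None = None,
    declination_noise_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Invert the clifftop geometry to produce observation records.

    ``true_rafts`` needs ``timestamp, lat, lon, count``.  Each raft is
    observed from the nearest station: the inclinometer declination is
    recovered from the eye height and true range, optional Gaussian noise is
    added to it, and the compass bearing is the true bearing (magnetic
    offset zero in the synthetic world).  Rafts effectively behind the
    horizontal (range -> infinity) are skipped.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    stations = synthetic_stations(cfg) if stations is None else stations
    tides = simulate_tides(cfg) if tides is None else tides
    tide_times = pd.DatetimeIndex(tides["timestamp"])
    rows = []
    for _, rec in true_rafts.iterrows():
        raft = GeoPoint(rec["lat"], rec["lon"])
        st = min(stations, key=lambda s: haversine_distance(s.position, raft))
        rng_m = haversine_distance(st.position, raft)
        if rng_m < 1.0:
            continue
        bearing = initial_bearing(st.position, raft)
        idx = int(np.argmin(np.abs(tide_times - pd.Timestamp(rec["timestamp"]))))
        tide_h = float(tides["height_m"].iloc[idx])
        eye = st.cliff_height_m + INCLINOMETER_HEIGHT_M - tide_h
        decl = np.degrees(np.arctan2(eye, rng_m))
        if declination_noise_deg > 0:
            decl += rng.normal(0.0, declination_noise_deg)
        if not 0.0 < decl < 90.0:
            continue
        rows.append((st.name, pd.Timestamp(rec["timestamp"]), bearing, decl, int(rec["count"])))
    return pd.DataFrame(rows, columns=["station", "timestamp", "bearing_deg",
                                       "declination_deg", "count"])


# ---------------------------------------------------------------------------
# raft-size series and circular pairs


def simulate_size_series(cfg: SimConfig, rng: np.random.Generator | None = None,
                         n_days: int = 22) -> pd.DataFrame:
    """Raft sizes with log-linear wind dependence and MA(4) errors in-day.

    log size = beta0 + beta1 * wind + eps, with eps an MA(4) process nested
    within each Julian day whose marginal sd is ``size_sigma``; sizes are
    exponentiated and rounded up to at least one bird.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    theta = np.asarray(cfg.size_theta, dtype=float)
    q = len(theta)
    sigma_e = cfg.size_sigma / np.sqrt(1.0 + float(np.sum(theta**2)))
    rows = []
    for day in range(n_days):
        jday = 218 + day  # early-August Julian days
        day_mean = float(np.clip(rng.normal(cfg.wind_mean, cfg.wind_sd),
                                 cfg.wind_min, cfg.wind_max))
        e = rng.normal(0.0, sigma_e, size=cfg.rafts_per_day + q)
        for i in range(cfg.rafts_per_day):
            eps = e[i + q] + float(np.dot(theta, e[i + q - 1 :: -1][:q]))
            wind = float(np.clip(day_mean + rng.normal(0.0, 0.8), cfg.wind_min, cfg.wind_max))
            log_size = cfg.size_beta0 + cfg.size_beta1 * wind + eps
            size = max(1, int(np.ceil(np.exp(log_size))))
            rows.append((jday, i, wind, size))
    return pd.DataFrame(rows, columns=["julian_day", "order", "wind_speed", "raft_size"])


def simulate_raft_counts(
    cfg: SimConfig,
    timestamps,
    weather: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raft sizes for observed rafts at given times, from the size-model truth.

    log size = beta0 + beta1 * wind(nearest hour) + MA(4) noise chained over
    the day's observations in time order; sizes rounded up to >= 1 bird.
    """
    rng = np.random.default_rng(cfg.seed + 4) if rng is None else rng
    ts = pd.DatetimeIndex(timestamps)
    wx_times = pd.DatetimeIndex(weather["timestamp"])
    theta = np.asarray(cfg.size_theta, dtype=float)
    q = len(theta)
    sigma_e = cfg.size_sigma / np.sqrt(1.0 + float(np.sum(theta**2)))
    order = np.argsort(ts.values, kind="stable")
    counts = np.empty(len(ts), dtype=int)
    for day in np.unique(ts[order].dayofyear):
        idx = order[ts[order].dayofyear == day]
        e = rng.normal(0.0, sigma_e, size=len(idx) + q)
        for j, i in enumerate(idx):
            pos = int(np.argmin(np.abs(wx_times - ts[i])))
            wind = float(weather["wind_speed_ms"].iloc[pos])
            eps = e[j + q] + float(np.dot(theta, e[j + q - 1 :: -1][:q]))
            counts[i] = max(1, int(np.ceil(np.exp(cfg.size_beta0 + cfg.size_beta1 * wind + eps))))
    return counts


def simulate_circular_pairs(
    n: int,
    noise_kappa: float | None = None,
    seed: int = 0,
    mu_a: float = 0.0,
    kappa_a: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired angle samples (radians) for the circular-correlation test.

    ``noise_kappa=None`` gives the independence null (two independent von
    Mises draws); otherwise ``beta = alpha + von Mises(0, noise_kappa)``
    noise, so dependence strengthens with ``noise_kappa``.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rng = np.random.default_rng(seed)
    alpha = np.mod(rng.vonmises(mu_a, kappa_a, size=n), 2.0 * np.pi)
    if noise_kappa is None:
        beta = np.mod(rng.vonmises(mu_a, kappa_a, size=n), 2.0 * np.pi)
    else:
        beta = np.mod(alpha + rng.vonmises(0.0, noise_kappa, size=n), 2.0 * np.pi)
    return alpha, beta


def expected_lag_correlations(cfg: SimConfig) -> np.ndarray:
    """Theoretical within-day autocorrelations rho(0..4) of the size errors."""
    return ma_acf(np.asarray(cfg.size_theta), 4)
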