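"""Readers, writers, run configuration, and the end-to-end analysis driver.

CSV conventions: columns in lat,lon order as conventionally logged by GPS
units; GeoJSON in lon-lat axis order per the GeoJSON standard.  Timestamps
are ISO-8601 and treated as UTC throughout; local solar time enters only
inside the day/night labelling.  Malformed rows are never silently dropped:
every reader returns a rejects table alongside the clean records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape

from . import circular, geolocate, sizemodel, tracks as trk, trends
from .geo import GeoPoint, haversine_distance_arrays, initial_bearing_arrays
from .geolocate import ObservationStation, match_nearest_time

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_tracks",
    "read_observations",
    "read_weather",
    "read_tides",
    "read_shoreline",
    "write_shoreline",
    "write_rafts_geojson",
    "run_full_analysis",
]


class SchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths, station table and thresholds for a full pipeline run."""

    out_dir: Path
    tracks_path: Path | None = None
    observations_path: Path | None = None
    weather_path: Path | None = None
    tides_path: Path | None = None
    shoreline_path: Path | None = None
    stations: list[ObservationStation] = field(default_factory=list)
    seed: int = 0
    error_speed_ms: float = trk.MAX_PLAUSIBLE_SPEED_MS
    classification_threshold: float | str = "auto"  # "auto" -> fit the mixture
    observation_radius_m: float = geolocate.RETENTION_RANGE_M
    study_radius_m: float = trk.STUDY_RADIUS_M
    colony: GeoPoint = field(default_factory=lambda: trk.NORTH_HAVEN_COLONY)
    magnetic_declination_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.observation_radius_m <= 0 or self.study_radius_m <= 0:
            raise ValueError("radii must be positive")


# ---------------------------------------------------------------------------
# readers


def _read_csv_checked(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _split_valid_times(df: pd.DataFrame, col: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    parsed = pd.to_datetime(df[col], errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna()
    rejects = df.loc[bad].copy()
    out = df.loc[~bad].copy()
    out[col] = parsed[~bad]
    if len(rejects):
        logger.warning("rejected %d rows with unparsable timestamps", len(rejects))
    return out, rejects


def read_tracks(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GPS fixes (``bird_id,timestamp,lat,lon``) -> (records, rejects)."""
    df = _read_csv_checked(path, ["bird_id", "timestamp", "lat", "lon"])
    df, rejects = _split_valid_times(df, "timestamp")
    bad_coord = (
        ~np.isfinite(df["lat"]) | ~np.isfinite(df["lon"])
        | (df["lat"].abs() > 90) | (df["lon"].abs() > 360)
    )
    if bad_coord.any():
        rejects = pd.concat([rejects, df.loc[bad_coord]]) if len(rejects) else df.loc[bad_coord]
        df = df.loc[~bad_coord]
    if df.empty:
        raise SchemaError(f"{path}: all rows rejected")
    return df.sort_values(["bird_id", "timestamp"]).reset_index(drop=True), rejects


def read_observations(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shore observations -> (records, rejects).

    Accepts either a single ISO ``timestamp`` column or separate
    ``date``/``time`` columns; other columns are
    ``station,bearing_deg,declination_deg,count``.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns and {"date", "time"} <= set(df.columns):
        df["timestamp"] = df["date"].astype(str) + "T" + df["time"].astype(str)
    for col in ["timestamp", "station", "bearing_deg", "declination_deg", "count"]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column(s) ['{col}']")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    df, rejects = _split_valid_times(df, "timestamp")
    bad = (
        ~np.isfinite(df["declination_deg"]) | (df["declination_deg"] <= 0)
        | (df["declination_deg"] >= 90) | (df["count"] < 1)
    )
    if bad.any():
        rejects = pd.concat([rejects, df.loc[bad]]) if len(rejects) else df.loc[bad]
        df = df.loc[~bad]
    if df.empty:
        raise SchemaError(f"{path}: all rows rejected")
    return df.sort_values("timestamp").reset_index(drop=True), rejects


def read_weather(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = _read_csv_checked(path, ["timestamp", "wind_speed_ms", "wind_dir_deg"])
    df, rejects = _split_valid_times(df, "timestamp")
    return df.sort_values("timestamp").reset_index(drop=True), rejects


def read_tides(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = _read_csv_checked(path, ["timestamp", "height_m"])
    df, rejects = _split_valid_times(df, "timestamp")
    return df.sort_values("timestamp").reset_index(drop=True), rejects


def read_shoreline(path) -> list[tuple[float, float]]:
    """GeoJSON Polygon (lon-lat order) -> (lat, lon) vertex list."""
    with open(path) as fh:
        gj = json.load(fh)
    geom = gj["features"][0]["geometry"] if gj.get("type") == "FeatureCollection" else (
        gj.get("geometry", gj)
    )
    poly = shape(geom)
    if poly.geom_type != "Polygon":
        raise SchemaError(f"{path}: expected a Polygon, got {poly.geom_type}")
    return [(lat, lon) for lon, lat in poly.exterior.coords[:-1]]


def write_shoreline(path, vertices_latlon) -> None:
    ring = [[lon, lat] for lat, lon in vertices_latlon]
    ring.append(ring[0])
    gj = {"type": "Feature", "properties": {},
          "geometry": {"type": "Polygon", "coordinates": [ring]}}
    with open(path, "w") as fh:
        json.dump(gj, fh)


def write_rafts_geojson(path, rafts: pd.DataFrame) -> None:
    feats = []
    for _, rec in rafts.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [rec["lon"], rec["lat"]]},
            "properties": {
                "count": int(rec["count"]), "range_m": float(rec["range_m"]),
                "dist_shore_m": float(rec["dist_shore_m"]), "retained": bool(rec["retained"]),
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# full pipeline


def _geolocate_stage(cfg: RunConfig, obs: pd.DataFrame, tides: pd.DataFrame,
                     shoreline) -> tuple[pd.DataFrame, dict]:
    stations = {s.name: s for s in cfg.stations}
    tide_times = pd.DatetimeIndex(tides["timestamp"])
    rows = []
    for _, rec in obs.iterrows():
        st = stations[rec["station"]]
        idx, flagged = match_nearest_time(rec["timestamp"], tide_times)
        tide = geolocate.TideRecord(tides["timestamp"].iloc[idx],
                                    float(tides["height_m"].iloc[idx]))
        raft = geolocate.georeference_raft(
            geolocate.RaftObservation(st, rec["timestamp"], rec["bearing_deg"],
                                      rec["declination_deg"], int(rec["count"])),
            tide,
            cfg.magnetic_declination_offset_deg,
            shoreline=shoreline,
            max_range_m=cfg.observation_radius_m,
        )
        rows.append((rec["station"], rec["timestamp"], raft.position.lat, raft.position.lon,
                     int(rec["count"]), raft.range_from_station_m, raft.distance_to_shore_m,
                     raft.retained, flagged))
    rafts = pd.DataFrame(rows, columns=["station", "timestamp", "lat", "lon", "count",
                                        "range_m", "dist_shore_m", "retained", "tide_gap_flag"])
    kept = rafts[rafts["retained"]]
    summary = {
        "n_rafts": int(len(rafts)),
        "n_retained": int(len(kept)),
        "size_min": int(kept["count"].min()) if len(kept) else None,
        "size_mean": float(kept["count"].mean()) if len(kept) else None,
        "size_sd": float(kept["count"].std()) if len(kept) else None,
        "size_max": int(kept["count"].max()) if len(kept) else None,
        "total_birds": int(kept["count"].sum()) if len(kept) else 0,
        "shore_min_m": float(kept["dist_shore_m"].min()) if len(kept) else None,
        "shore_mean_m": float(kept["dist_shore_m"].mean()) if len(kept) else None,
        "shore_sd_m": float(kept["dist_shore_m"].std()) if len(kept) else None,
    }
    return rafts, summary


def _classify_stage(cfg: RunConfig, track_df: pd.DataFrame,
                    shoreline) -> tuple[pd.DataFrame, dict]:
    if shoreline is not None:
        land = Polygon([(lon, lat) for lat, lon in shoreline])
        track_df = trk.remove_land_fixes(track_df, land)
    segments = trk.compute_speeds(track_df)
    segments = trk.filter_speed_errors(segments, cfg.error_speed_ms)
    ok = segments["behaviour"] != "excluded"
    if cfg.classification_threshold == "auto":
        mix = trk.fit_speed_mixture(segments.loc[ok, "speed_ms"].to_numpy(), seed=cfg.seed)
        threshold = mix.threshold
        mix_info = {
            "mu1": mix.mu1, "sigma1": mix.sigma1, "mu2": mix.mu2, "sigma2": mix.sigma2,
            "w1": mix.w1, "w2": mix.w2, "converged": mix.converged,
        }
    else:
        threshold = float(cfg.classification_threshold)
        mix_info = None
    segments = trk.classify_behaviour(segments, threshold)
    segments = trk.annotate_segments(segments, cfg.colony, cfg.study_radius_m)
    summary_df = trk.behaviour_summary(segments)
    summary = {
        "threshold_ms": float(threshold),
        "mixture": mix_info,
        "fractions": dict(zip(summary_df["metric"], summary_df["fraction"])),
        "n_segments": int(len(segments)),
        "n_excluded": int((segments["behaviour"] == "excluded").sum()),
    }
    return segments, summary


def _circular_stage(cfg: RunConfig, rafts, segments, weather) -> dict:
    wx_times = pd.DatetimeIndex(weather["timestamp"])
    out = {}
    if rafts is not None and len(rafts) >= 3:
        kept = rafts[rafts["retained"]]
        if len(kept) >= 3:
            # rafting direction: bearing from the island/colony centre to the raft
            bearings = initial_bearing_arrays(
                np.full(len(kept), cfg.colony.lat), np.full(len(kept), cfg.colony.lon),
                kept["lat"].to_numpy(), kept["lon"].to_numpy())
            wind = [weather["wind_dir_deg"].iloc[match_nearest_time(t, wx_times)[0]]
                    for t in kept["timestamp"]]
            res = circular.circular_correlation_js(np.radians(bearings), np.radians(wind))
            out["observations"] = {"r": res.r, "z": res.z, "p": res.p, "n": res.n}
    if segments is not None:
        rafting = segments[(segments["behaviour"] == "rafting") & segments["within_5km"]]
        if len(rafting) >= 3:
            wind = [weather["wind_dir_deg"].iloc[match_nearest_time(t, wx_times)[0]]
                    for t in rafting["end_time"]]
            res = circular.circular_correlation_js(
                np.radians(rafting["bearing_deg"].to_numpy()), np.radians(wind))
            out["gps"] = {"r": res.r, "z": res.z, "p": res.p, "n": res.n}
    return out


def _size_stage(cfg: RunConfig, rafts: pd.DataFrame, weather: pd.DataFrame) -> dict:
    kept = rafts[rafts["retained"]].copy()
    wx_times = pd.DatetimeIndex(weather["timestamp"])
    kept["wind_speed"] = [
        float(weather["wind_speed_ms"].iloc[match_nearest_time(t, wx_times)[0]])
        for t in kept["timestamp"]
    ]
    ts = pd.DatetimeIndex(kept["timestamp"])
    kept["julian_day"] = ts.dayofyear
    kept["order"] = kept.groupby("julian_day").cumcount()
    kept = kept.rename(columns={"count": "raft_size"})
    fit = sizemodel.fit_gls_ma(kept[["raft_size", "wind_speed", "julian_day", "order"]],
                               q=4, method="REML", seed=cfg.seed)
    rs = fit.residual_summary()
    return {
        "coefficients": {
            name: {"value": float(fit.params[i]), "se": float(fit.bse[i]),
                   "t": float(fit.tvalues[i]), "p": float(fit.pvalues[i]),
                   "ci_lo": float(fit.conf_int[i, 0]), "ci_hi": float(fit.conf_int[i, 1])}
            for i, name in enumerate(fit.exog_names)
        },
        "theta": fit.theta.tolist(),
        "sigma": fit.sigma,
        "logLik": fit.log_likelihood, "AIC": fit.aic, "BIC": fit.bic,
        "method": fit.method, "n": fit.nobs, "df_resid": fit.df_resid,
        "residual_summary": rs,
    }


def _trends_stage(cfg: RunConfig, segments: pd.DataFrame, out_dir: Path,
                  shoreline=None) -> dict:
    rafting = segments[(segments["behaviour"] == "rafting") & segments["within_5km"]].copy()
    if rafting.empty:
        raise RuntimeError("no rafting segments within the study radius")
    t = pd.DatetimeIndex(rafting["end_time"])
    hour = t.hour + t.minute / 60.0 + t.second / 3600.0
    rafting["time_h"] = hour

    # birds present in nearshore waters per half-hour-of-day bin (summed
    # across days): a count series on a cyclic 24 h axis
    bins = np.floor(hour * 2.0) / 2.0
    counts = rafting.groupby(bins)["bird_id"].count()
    count_fit = trends.fit_poisson_gam(counts.index.to_numpy() + 0.25,
                                       counts.to_numpy().astype(int))
    count_fit.frame().to_csv(out_dir / "trend_counts.csv", index=False)

    if shoreline is not None:
        shore_d = geolocate.distances_to_shore(
            rafting["end_lat"].to_numpy(), rafting["end_lon"].to_numpy(), shoreline)
    else:
        shore_d = haversine_distance_arrays(
            rafting["end_lat"].to_numpy(), rafting["end_lon"].to_numpy(),
            cfg.colony.lat, cfg.colony.lon)
    dist_fit = trends.fit_gaussian_gamm_random_intercept(
        rafting["time_h"].to_numpy(), shore_d, rafting["bird_id"].to_numpy())
    dist_fit.frame().to_csv(out_dir / "trend_distance.csv", index=False)
    return {
        "counts": {"lam": count_fit.lam, "edf": count_fit.edf,
                   "file": "trend_counts.csv"},
        "distance": {"lam": dist_fit.lam, "edf": dist_fit.edf,
                     "bird_sd": dist_fit.bird_sd, "sigma": dist_fit.sigma,
                     "file": "trend_distance.csv"},
    }


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage the inputs allow; write outputs + manifest to out_dir.

    Stages: (a) raft geolocation, (b) track classification, (c) circular
    correlations, (d) raft-size model, (e) diel trends.  A missing input
    skips only the stages that need it; a stage failure is recorded in the
    manifest and the remaining stages still run.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "failures": {}}

    shoreline = read_shoreline(cfg.shoreline_path) if cfg.shoreline_path else None
    weather = rejects = None
    if cfg.weather_path:
        weather, rejects = read_weather(cfg.weather_path)
        if len(rejects):
            rejects.to_csv(out_dir / "rejects_weather.csv", index=False)

    rafts = segments = None
    if cfg.observations_path and cfg.tides_path and cfg.stations:
        try:
            obs, rej = read_observations(cfg.observations_path)
            if len(rej):
                rej.to_csv(out_dir / "rejects_observations.csv", index=False)
            tides, _ = read_tides(cfg.tides_path)
            rafts, summary = _geolocate_stage(cfg, obs, tides, shoreline)
            rafts.to_csv(out_dir / "rafts.csv", index=False)
            write_rafts_geojson(out_dir / "rafts.geojson", rafts)
            manifest["stages"]["geolocate"] = {"summary": summary,
                                               "files": ["rafts.csv", "rafts.geojson"]}
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.exception("geolocation stage failed")
            manifest["failures"]["geolocate"] = str(exc)

    if cfg.tracks_path:
        try:
            track_df, rej = read_tracks(cfg.tracks_path)
            if len(rej):
                rej.to_csv(out_dir / "rejects_tracks.csv", index=False)
            segments, summary = _classify_stage(cfg, track_df, shoreline)
            segments.to_csv(out_dir / "classified.csv", index=False)
            manifest["stages"]["classify"] = {"summary": summary, "files": ["classified.csv"]}
        except Exception as exc:  # noqa: BLE001
            logger.exception("classification stage failed")
            manifest["failures"]["classify"] = str(exc)

    if weather is not None and (rafts is not None or segments is not None):
        try:
            manifest["stages"]["circular"] = {
                "summary": _circular_stage(cfg, rafts, segments, weather)}
        except Exception as exc:  # noqa: BLE001
            logger.exception("circular stage failed")
            manifest["failures"]["circular"] = str(exc)

    if weather is not None and rafts is not None and rafts["retained"].sum() >= 10:
        try:
            manifest["stages"]["size_model"] = {"summary": _size_stage(cfg, rafts, weather)}
        except Exception as exc:  # noqa: BLE001
            logger.exception("size-model stage failed")
            manifest["failures"]["size_model"] = str(exc)

    if segments is not None:
        try:
            manifest["stages"]["trends"] = {
                "summary": _trends_stage(cfg, segments, out_dir, shoreline)}
        except Exception as exc:  # noqa: BLE001
            logger.exception("trends stage failed")
            manifest["failures"]["trends"] = str(exc)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
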