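import numpy as np
import pandas as pd
import pytest

from raftkit.geo import haversine_distance, GeoPoint
from raftkit.simulate import (
    SimConfig,
    simulate_circular_pairs,
    simulate_observations,
    simulate_size_series,
    simulate_tides,
    simulate_tracks,
    simulate_weather,
    synthetic_island,
    synthetic_stations,
)
from raftkit.sizemodel import ma_acf
from raftkit.tracks import classify_behaviour, compute_speeds, filter_speed_errors, fit_speed_mixture
from tests.test_tracks import closed_form_threshold


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_raft_to_fly=0.0)

    def test_far_island_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(island_centre=GeoPoint(0.0, 0.0))


class TestTracks:
    def test_bit_reproducible(self):
        cfg = SimConfig(seed=9, n_birds=2, days=1)
        a = simulate_tracks(cfg)
        b = simulate_tracks(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_fix_cadence(self, sim_cfg, sim_tracks):
        for _, grp in sim_tracks.groupby("bird_id"):
            dt = pd.DatetimeIndex(grp["timestamp"]).diff().dropna()
            assert (dt == pd.Timedelta(seconds=sim_cfg.fix_interval_s)).all()

    def test_zero_flying_means_all_rafting(self):
        cfg = SimConfig(seed=10, n_birds=2, days=1, p_raft_to_fly=1e-12, p_fly_to_raft=0.999)
        fx = simulate_tracks(cfg)
        # after at most one initial flying step per bird, everything rafts
        assert (fx["true_state"] == "rafting").mean() > 0.98
        seg = classify_behaviour(filter_speed_errors(compute_speeds(fx)), 2.5)
        ok = seg["behaviour"] != "excluded"
        assert (seg.loc[ok, "behaviour"] == "rafting").mean() > 0.99

    def test_em_threshold_matches_generating_mixture(self, sim_tracks, sim_cfg):
        seg = filter_speed_errors(compute_speeds(sim_tracks))
        speeds = seg.loc[seg["behaviour"] != "excluded", "speed_ms"].to_numpy()
        m = fit_speed_mixture(speeds, seed=0)
        w1 = (sim_tracks["true_state"] == "rafting").mean()
        oracle = closed_form_threshold(
            sim_cfg.raft_speed_mu, sim_cfg.raft_speed_sd, w1,
            sim_cfg.fly_speed_mu, sim_cfg.fly_speed_sd, 1 - w1)
        assert m.threshold == pytest.approx(oracle, abs=0.25)


class TestObservations:
    def test_boundary_raft_excluded_downstream(self, sim_cfg):
        from raftkit.geolocate import RaftObservation, TideRecord, georeference_raft
        from raftkit.geo import destination_point

        st = synthetic_stations(sim_cfg)[0]
        raft = destination_point(st.position, 45.0, 2_000.0)
        df = pd.DataFrame([{"timestamp": pd.Timestamp("2016-08-05T12:00Z"),
                            "lat": raft.lat, "lon": raft.lon, "count": 30}])
        obs = simulate_observations(sim_cfg, df, stations=[st])
        tides = simulate_tides(sim_cfg)
        rec = obs.iloc[0]
        idx = int(np.argmin(np.abs(pd.DatetimeIndex(tides["timestamp"]) - rec["timestamp"])))
        out = georeference_raft(
            RaftObservation(st, rec["timestamp"], rec["bearing_deg"],
                            rec["declination_deg"], 30),
            TideRecord(tides["timestamp"].iloc[idx], float(tides["height_m"].iloc[idx])))
        assert not out.retained

    def test_declination_noise_error_propagation(self, sim_cfg):
        """Angle noise maps to range error as predicted by the delta method."""
        from raftkit.geolocate import RaftObservation, TideRecord, georeference_raft
        from raftkit.geo import destination_point

        st = synthetic_stations(sim_cfg)[0]
        truth_range = 1_000.0
        rows = []
        for i in range(300):
            p = destination_point(st.position, i * 1.2 % 360, truth_range)
            rows.append({"timestamp": pd.Timestamp("2016-08-05T12:00Z"),
                         "lat": p.lat, "lon": p.lon, "count": 20})
        noise_sd = 0.1
        obs = simulate_observations(sim_cfg, pd.DataFrame(rows), stations=[st],
                                    declination_noise_deg=noise_sd,
                                    rng=np.random.default_rng(13))
        tides = simulate_tides(sim_cfg)
        idx = int(np.argmin(np.abs(pd.DatetimeIndex(tides["timestamp"])
                                   - pd.Timestamp("2016-08-05T12:00Z"))))
        tide = TideRecord(tides["timestamp"].iloc[idx], float(tides["height_m"].iloc[idx]))
        errors = []
        for _, rec in obs.iterrows():
            out = georeference_raft(
                RaftObservation(st, rec["timestamp"], rec["bearing_deg"],
                                rec["declination_deg"], 20), tide)
            errors.append(abs(out.range_from_station_m - truth_range))
        # delta method: |dr/dD| = eye / sin^2(D) with D = atan(eye/range)
        eye = st.cliff_height_m + 0.895 - tide.height_m
        decl = np.arctan2(eye, truth_range)
        sd_range = eye / np.sin(decl) ** 2 * np.radians(noise_sd)
        median_pred = 0.6745 * sd_range
        assert 0.3 * median_pred < np.median(errors) < 3.0 * median_pred


class TestSizeSeries:
    def test_iid_theta_zero(self):
        df = simulate_size_series(SimConfig(seed=14, size_theta=(0, 0, 0, 0)), n_days=200)
        resid = np.log(df["raft_size"]) - 4.674 - 0.065 * df["wind_speed"]
        lag1 = [np.corrcoef(g[:-1], g[1:])[0, 1]
                for _, grp in df.assign(r=resid).groupby("julian_day")
                if len(g := grp["r"].to_numpy()) > 5]
        assert abs(np.mean(lag1)) < 0.12  # finite-block bias ~ -1/n only

    def test_default_theta_lag1(self):
        cfg = SimConfig(seed=15)
        df = simulate_size_series(cfg, n_days=600)
        resid = np.log(df["raft_size"]) - cfg.size_beta0 - cfg.size_beta1 * df["wind_speed"]
        x0, x1 = [], []
        for _, grp in df.assign(r=resid).groupby("julian_day"):
            r = grp["r"].to_numpy()
            x0.append(r[:-1]); x1.append(r[1:])
        x0, x1 = np.concatenate(x0), np.concatenate(x1)
        rho1 = np.mean(x0 * x1) / np.sqrt(np.mean(x0**2) * np.mean(x1**2))
        assert rho1 == pytest.approx(ma_acf(np.array(cfg.size_theta), 1)[1], abs=0.03)

    def test_marginal_sd_matches(self):
        cfg = SimConfig(seed=16)
        df = simulate_size_series(cfg, n_days=600)
        resid = np.log(df["raft_size"]) - cfg.size_beta0 - cfg.size_beta1 * df["wind_speed"]
        assert np.std(resid) == pytest.approx(cfg.size_sigma, rel=0.05)

    def test_sizes_at_least_one(self):
        df = simulate_size_series(SimConfig(seed=17, size_beta0=0.0), n_days=50)
        assert (df["raft_size"] >= 1).all()


class TestWeatherTides:
    def test_wind_within_stated_range(self):
        wx = simulate_weather(SimConfig(seed=18, days=30))
        assert wx["wind_speed_ms"].between(2.1, 17.6).all()
        assert wx["wind_dir_deg"].between(0, 360).all()

    def test_tide_amplitude(self):
        td = simulate_tides(SimConfig(seed=19))
        assert td["height_m"].abs().max() <= 2.0 + 1e-9


class TestCircularPairs:
    def test_high_kappa_gives_r_near_one(self):
        from raftkit.circular import circular_correlation_js

        a, b = simulate_circular_pairs(500, noise_kappa=1e4, seed=20)
        assert circular_correlation_js(a, b).r > 0.99

    def test_minimal_n_runs(self):
        a, b = simulate_circular_pairs(3, seed=21)
        assert len(a) == len(b) == 3

    def test_reproducible(self):
        a1, b1 = simulate_circular_pairs(50, noise_kappa=2.0, seed=22)
        a2, b2 = simulate_circular_pairs(50, noise_kappa=2.0, seed=22)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)


def test_island_is_closed_ring_of_radius(sim_cfg):
    ring = synthetic_island(sim_cfg)
    for lat, lon in ring[:: len(ring) // 10]:
        d = haversine_distance(sim_cfg.island_centre, GeoPoint(lat, lon))
        assert d == pytest.approx(sim_cfg.island_radius_m, rel=1e-6)
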