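from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from raftkit import io as rio, simulate
from raftkit.simulate import SimConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160805)


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=7, n_birds=4, days=1)


@pytest.fixture(scope="session")
def sim_tracks(sim_cfg):
    return simulate.simulate_tracks(sim_cfg)


@pytest.fixture(scope="session")
def input_bundle(tmp_path_factory, sim_cfg, sim_tracks):
    """A full synthetic input bundle on disk (tracks, observations, weather,
    tides, island)."""
    out = tmp_path_factory.mktemp("bundle")
    sim_tracks.drop(columns=["true_state"]).to_csv(out / "tracks.csv", index=False)
    rafting = sim_tracks[sim_tracks["true_state"] == "rafting"]
    sample = rafting.sample(n=min(60, len(rafting)), random_state=sim_cfg.seed).copy()
    weather = simulate.simulate_weather(sim_cfg)
    sample["count"] = simulate.simulate_raft_counts(sim_cfg, sample["timestamp"], weather)
    obs = simulate.simulate_observations(sim_cfg, sample[["timestamp", "lat", "lon", "count"]])
    obs.to_csv(out / "observations.csv", index=False)
    weather.to_csv(out / "weather.csv", index=False)
    simulate.simulate_tides(sim_cfg).to_csv(out / "tides.csv", index=False)
    rio.write_shoreline(out / "island.geojson", simulate.synthetic_island(sim_cfg))
    return out


@pytest.fixture()
def utc():
    def make(*args):
        return datetime(*args, tzinfo=timezone.utc)

    return make
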