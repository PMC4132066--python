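import logging

import numpy as np
import pandas as pd
import pytest

from coforage.io import ColonySite
from coforage.pipeline import PipelineConfig, analyze
from coforage.simulate import SimConfig, simulate_deployment

logging.getLogger("coforage").setLevel(logging.ERROR)

M_PER_DEG = 111_194.93  # metres per degree of latitude on the package sphere


def make_fixes(times_s, lats, lons, start="2012-10-01T05:00:00"):
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "time": [t0 + pd.Timedelta(seconds=float(s)) for s in times_s],
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
        }
    )


def make_depth_series(depths, dt_s=4.0, start="2012-10-01T06:00:00"):
    t0 = pd.Timestamp(start)
    times = [t0 + pd.Timedelta(seconds=dt_s * i) for i in range(len(depths))]
    return pd.DataFrame({"time": times, "depth_m": np.asarray(depths, dtype=float)})


@pytest.fixture(scope="session")
def colony():
    return ColonySite(lat=-38.6219, lon=142.9325, rafting_radius_m=1000.0)


@pytest.fixture(scope="session")
def sim_result():
    """Default synthetic deployment, shared across the suite."""
    return simulate_deployment(SimConfig(seed=1))


def bundle_from_sim(res, seed=1, n_perm=199):
    gps = {
        ind: sub.rename(columns={"timestamp": "time"})[["time", "lat", "lon"]].reset_index(drop=True)
        for ind, sub in res.gps.groupby("id")
    }
    tdr = {
        ind: sub.rename(columns={"timestamp": "time"})[["time", "depth_m"]].reset_index(drop=True)
        for ind, sub in res.tdr.groupby("id")
    }
    deployments = res.deployments.rename(columns={"id": "individual_id"})
    cfg = PipelineConfig(seed=seed, n_perm=n_perm)
    return analyze(gps, tdr, deployments, res.config.colony(), cfg)


@pytest.fixture(scope="session")
def sim_bundle(sim_result):
    """Full pipeline output on the default synthetic deployment."""
    return bundle_from_sim(sim_result)
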