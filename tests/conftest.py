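import numpy as np
import pandas as pd
import pytest

import murretrax as mt


@pytest.fixture(scope="session")
def config():
    return mt.PipelineConfig()


@pytest.fixture(scope="session")
def truth_spec():
    return mt.default_truth_spec()


@pytest.fixture(scope="session")
def small_sim():
    """Five simulated 2-day deployments with ground truth (seed-fixed)."""
    scen = mt.SimScenario(seed=11, n_birds=5)
    return mt.simulate_deployments(scen)


def make_deployment(t, lon, lat, depth=None, wingbeat=None, pitch=None,
                    bird_id="b0", config=None, **kw):
    """Hand-built deployment for small deterministic cases."""
    config = config or mt.PipelineConfig()
    n = len(t)
    fixes = pd.DataFrame({
        "t": np.asarray(t, dtype=float),
        "lon": np.asarray(lon, dtype=float),
        "lat": np.asarray(lat, dtype=float),
        "depth": np.zeros(n) if depth is None else np.asarray(depth, dtype=float),
        "wingbeat_hz": np.zeros(n) if wingbeat is None else np.asarray(wingbeat, float),
        "pitch": np.zeros(n) if pitch is None else np.asarray(pitch, float),
    })
    from murretrax.geodesy import haversine_km
    lon0, lat0 = config.colony_lon_lat
    fixes["dist_colony_km"] = haversine_km(fixes.lon, fixes.lat, lon0, lat0)
    return mt.Deployment(bird_id=bird_id, fixes=fixes, **kw)


@pytest.fixture
def make_dep():
    return make_deployment
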