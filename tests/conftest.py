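import numpy as np
import pandas as pd
import pytest

import npmrtrack as nt


@pytest.fixture(scope="session")
def logistic_table():
    """120 rows; presence probability logistic in x, z is pure noise."""
    rng = np.random.default_rng(7)
    n = 120
    x = rng.uniform(0.0, 10.0, n)
    z = rng.normal(0.0, 1.0, n)
    p = 1.0 / (1.0 + np.exp(-1.2 * (x - 5.0)))
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({
        "y": y, "x": x, "z": z,
        "lon": rng.uniform(-126.0, -120.0, n),
        "lat": rng.uniform(32.0, 42.0, n),
        "whale": rng.choice(["a", "b", "c"], n),
    })


@pytest.fixture(scope="session")
def small_table():
    """40-row table used for brute-force oracle comparisons."""
    rng = np.random.default_rng(11)
    n = 40
    x = rng.uniform(0.0, 4.0, n)
    w = rng.uniform(-1.0, 1.0, n)
    p = np.clip(0.2 + 0.6 * (x > 2.0), 0.0, 1.0)
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"y": y, "x": x, "w": w})


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated season: fields + tracks + truth."""
    cfg = nt.SimConfig(seed=3, n_whales=4, days_per_whale=60,
                       grid_extent=(-127.0, -119.0, 32.0, 42.0))
    fields = nt.gen_env_fields(cfg)
    tracks, truth = nt.gen_tracks(cfg, fields)
    return cfg, fields, tracks, truth
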