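import numpy as np
import pandas as pd
import pytest

from divetrace import synthetic


def make_records(rows, animal_id="A"):
    """Build a behavior-record table from (kind, start, dur_s, depth) tuples."""
    out = []
    for kind, start, dur_s, depth in rows:
        start = pd.Timestamp(start)
        end = start + pd.Timedelta(seconds=dur_s)
        out.append({
            "animal_id": animal_id, "kind": kind, "start": start, "end": end,
            "depth_min": depth * 0.99 if kind == "dive" else np.nan,
            "depth_max": depth * 1.01 if kind == "dive" else np.nan,
            "dur_min": dur_s, "dur_max": dur_s,
            "shape": "u" if kind == "dive" else "none",
            "depth": depth if kind == "dive" else np.nan,
            "duration": float(dur_s),
        })
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_rasters():
    return synthetic.build_rasters((-161.0, -153.0, 17.0, 24.6), 0.02, seed=7,
                                   env_resolution_deg=0.08)


@pytest.fixture(scope="session")
def small_scenario():
    cfg = synthetic.ScenarioConfig(n_animals=3, duration_days=5.0, seed=11)
    return synthetic.simulate_scenario(cfg)
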