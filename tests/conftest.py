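import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import beambreak as bb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

T0 = pd.Timestamp("2022-02-17 00:00:00")


@pytest.fixture(scope="session")
def geometry():
    return bb.DetectorGeometry()


@pytest.fixture(scope="session")
def scan():
    return bb.ScanParams()


@pytest.fixture(scope="session")
def regime():
    return bb.LightRegime()


def make_records(events, column_id="c01", base=T0, beam=1):
    """Records frame from (offset_ms, module[, beam]) tuples."""
    rows = []
    for ev in events:
        ms, module = ev[0], ev[1]
        b = ev[2] if len(ev) > 2 else beam
        rows.append((base + pd.Timedelta(milliseconds=ms), column_id, module, b))
    df = pd.DataFrame(rows, columns=["timestamp", "column_id", "module", "beam"])
    return df.astype({"module": np.int64, "beam": np.int64})


@pytest.fixture(scope="session")
def two_column_run():
    """A small simulated run (2 individuals, 1 day) shared across tests."""
    config = bb.default_config(n_individuals=2, days=1, seed=11)
    records = bb.simulate_experiment(config)
    return config, records
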