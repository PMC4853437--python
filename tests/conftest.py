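import numpy as np
import pandas as pd
import pytest

from socspat import ScanTable, SimulationConfig, generate_dataset


def make_scan_table(rows):
    """Build a ScanTable from (scan_id, time, individual, x, y) tuples;
    x = None marks an out-of-sight record."""
    records = []
    for scan_id, time, ind, x, y in rows:
        records.append(
            {
                "scan_id": scan_id,
                "date": "2012-04-02",
                "time": time,
                "individual": ind,
                "x": np.nan if x is None else x,
                "y": np.nan if y is None else y,
                "visible": x is not None,
            }
        )
    return ScanTable(pd.DataFrame(records))


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study for fast end-to-end tests."""
    return SimulationConfig(n_individuals=15, n_males=8, n_subgroups=3,
                            n_matrilines=3, n_days=8, interactions_per_day=40,
                            base_distance=12.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-scale dataset under the default study conditions."""
    return generate_dataset(SimulationConfig(seed=0))
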