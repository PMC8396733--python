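import numpy as np
import pandas as pd
import pytest

from floragap.grid import GridRaster
from floragap.synthetic import LandscapeConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(width_cells=20, height_cells=20, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A small but complete synthetic dataset shared across tests (read-only)."""
    return simulate_dataset(small_config, n_species=120, n_records=3000)


@pytest.fixture
def toy_grid():
    """4x5 planar grid with origin (0, 0) and unit cell size 10."""
    return GridRaster(np.zeros((4, 5)), origin=(0.0, 0.0), cell_size=10.0, crs="identity")


def make_records(rows):
    """Build a canonical record frame from (name, lat, lon) or full dict rows."""
    recs = []
    for r in rows:
        if isinstance(r, dict):
            base = {"verbatim_name": r.get("accepted_name", ""), "accepted_name": "",
                    "family": "", "lat": np.nan, "lon": np.nan,
                    "dataset_id": "t", "flags": ""}
            base.update(r)
            recs.append(base)
        else:
            name, lat, lon = r
            recs.append({"verbatim_name": name, "accepted_name": name, "family": "",
                         "lat": lat, "lon": lon, "dataset_id": "t", "flags": ""})
    return pd.DataFrame(recs)
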