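import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vertibelt.grid import Raster, StandMap

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def raster_from_rows(rows, cell_size=10.0, xll=0.0, yll=0.0) -> Raster:
    """Tiny raster builder; `rows` listed north to south."""
    return Raster(np.asarray(rows, dtype=float), cell_size, xll, yll)


def standmap_from_types(type_rows, cell_size=10.0, xll=0.0, yll=0.0) -> StandMap:
    """StandMap with one single-cell stand per cell and given forest types.

    Compositions are chosen so that classify_stands reproduces the requested
    type labels; the table also carries the labels directly.
    """
    comp = {
        "deciduous_broadleaf": ("QUE", "8QUE2PIN"),
        "temperate_conifer": ("PIN", "8PIN2QUE"),
        "mixed": ("QUE", "5QUE5PIN"),
        "nonforest": ("", ""),
    }
    types = np.asarray(type_rows, dtype=object)
    ids = np.arange(types.size).reshape(types.shape)
    records = []
    for t in types.ravel():
        dom, c = comp[t]
        records.append(
            {"dominant_species": dom, "composition": c, "forest_type": t}
        )
    table = pd.DataFrame(records)
    table.index.name = "stand_id"
    return StandMap(ids, table, cell_size, xll, yll)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but fully featured synthetic landscape, shared across tests."""
    from vertibelt.forest_typing import classify_stands
    from vertibelt.synthetic import SyntheticConfig, generate_dem, generate_stand_map, generate_truth

    # patch_scale=1 keeps cell draws independent, so per-bin shares obey the
    # plain binomial tolerance used by the truth-curve agreement test
    cfg = SyntheticConfig(n_rows=200, n_cols=200, cell_size=30.0, patch_scale=1, seed=11)
    dem = generate_dem(cfg)
    stands = classify_stands(generate_stand_map(cfg, dem))
    truth = generate_truth(cfg)
    return cfg, dem, stands, truth
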