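import numpy as np
import pandas as pd
import pytest

from gapatlas import synthetic_data as sd
from gapatlas.geodata_io import OccurrenceTable, RasterLayer


@pytest.fixture(scope="session")
def world():
    """Shared synthetic study system (100×100 pixels, ~4% protected)."""
    return sd.generate_world(seed=7, resolution=0.02)


@pytest.fixture(scope="session")
def occ_truth(world):
    occ, truth = sd.generate_species(world, seed=7, n_species=15)
    return occ, truth


@pytest.fixture(scope="session")
def exhaustive_occ_truth(world):
    """One record at every truly occupied pixel center (recovery fixture)."""
    occ, truth = sd.generate_species(world, seed=11, n_species=8, exhaustive=True)
    return occ, truth


def make_occ(rows):
    """rows: iterable of (species_id, lon, lat)."""
    return OccurrenceTable(pd.DataFrame(rows, columns=["species_id", "lon", "lat"]))


def make_raster(values, origin=(0.0, 1.0), res=0.1, nodata=-9999.0, kind="continuous"):
    return RasterLayer(np.asarray(values), origin, (res, res), nodata=nodata, kind=kind)


@pytest.fixture
def flat_raster():
    return make_raster(np.full((10, 10), 7.0))
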