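import numpy as np
import pandas as pd
import pytest

from geolca import Grid, LandscapeParams, LulcClassTable, generate_landscape
from geolca.classes import _COLUMNS


@pytest.fixture(scope="session")
def landscape_200():
    """Default synthetic landscape at the size the core contracts are stated for."""
    return generate_landscape(LandscapeParams(shape=(200, 200), seed=5))


@pytest.fixture(scope="session")
def landscape_small():
    """An 80x80 landscape for cheaper end-to-end checks."""
    return generate_landscape(LandscapeParams(shape=(80, 80), seed=11))


def make_table(rows):
    """Build a class table from compact row dicts; unspecified params are inert."""
    defaults = dict(
        is_agriculture=False, is_natural=False, convertible=False,
        carbon_density=0.0, usle_c=0.0, usle_p=1.0,
        sed_retention_eff=0.0, n_retention_eff=0.0, n_load=0.0,
        kc=np.nan, msa_lu=1.0,
    )
    full = []
    for row in rows:
        d = dict(defaults)
        d.update(row)
        full.append(d)
    df = pd.DataFrame(full)
    for col in _COLUMNS:
        if col not in df.columns:
            raise KeyError(col)
    return LulcClassTable(df[_COLUMNS])


def plane_dem(nrows, ncols, cell_size=100.0, drop=1.0):
    """Inclined plane dipping south: row r has elevation (nrows-1-r)*drop."""
    rows = np.arange(nrows, dtype=float)[:, None]
    return Grid((nrows - 1 - rows) * drop * np.ones((1, ncols)), cell_size=cell_size)


@pytest.fixture
def table_factory():
    return make_table
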