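import numpy as np
import pytest

from paleodown import FixtureParams, GeoGrid, GridSpec, MonthlyStack


@pytest.fixture
def spec_5x5() -> GridSpec:
    return GridSpec(lat_origin=10.0, lon_origin=0.0,
                    cell_size_lat=2.0, cell_size_lon=2.0,
                    n_rows=5, n_cols=5)


@pytest.fixture
def small_params() -> FixtureParams:
    """Fixture world shrunk to a 6x6 coarse / 60x60 fine window for speed."""
    coarse = GridSpec(lat_origin=15.0, lon_origin=0.0,
                      cell_size_lat=2.5, cell_size_lon=2.5,
                      n_rows=6, n_cols=6)
    return FixtureParams(seed=0, coarse_spec=coarse, fine_spec=coarse.refine(10))


def uniform_stack(variable: str, spec: GridSpec, value: float,
                  units: str = "") -> MonthlyStack:
    cube = np.full((12, spec.n_rows, spec.n_cols), float(value))
    return MonthlyStack.from_array(variable, spec, cube, units=units)


def random_stack(variable: str, spec: GridSpec, rng, lo: float, hi: float,
                 units: str = "") -> MonthlyStack:
    cube = rng.uniform(lo, hi, size=(12, spec.n_rows, spec.n_cols))
    return MonthlyStack.from_array(variable, spec, cube, units=units)
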