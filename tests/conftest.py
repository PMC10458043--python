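import numpy as np
import pandas as pd
import pytest

from ecoshift.grid import GridLayer, GridSpec, RasterStack


@pytest.fixture
def spec3() -> GridSpec:
    return GridSpec(origin_x=0.0, origin_y=300.0, cell_size=100.0,
                    n_rows=3, n_cols=3, crs_tag="LOCAL_METERS")


@pytest.fixture
def spec10() -> GridSpec:
    return GridSpec(origin_x=0.0, origin_y=1000.0, cell_size=100.0,
                    n_rows=10, n_cols=10, crs_tag="LOCAL_METERS")


def make_layer(spec, values, name="layer", kind="continuous", nodata=-9999.0):
    return GridLayer(spec=spec, name=name, kind=kind,
                     values=np.asarray(values), nodata=nodata)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_stack(spec, arrays: dict, categorical=(), nodata=-9999.0) -> RasterStack:
    return RasterStack([
        make_layer(spec, vals, name=name,
                   kind="categorical" if name in categorical else "continuous",
                   nodata=nodata)
        for name, vals in arrays.items()
    ])


def random_env(rng, n, names) -> pd.DataFrame:
    return pd.DataFrame({name: rng.normal(size=n) for name in names})
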