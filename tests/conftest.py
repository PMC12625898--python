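import warnings

import numpy as np
import pytest

import paleotrail as pt


@pytest.fixture(scope="session")
def markers():
    return pt.datasets.reference_markers()


@pytest.fixture(scope="session")
def star1():
    return pt.datasets.star1_peaks()


@pytest.fixture(scope="session")
def records():
    """Normalized dated-specimen table (12 rows, three boxes)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pt.load_occurrences(pt.datasets.starosele_occurrences())


@pytest.fixture(scope="session")
def boxes():
    return pt.datasets.region_boxes()


@pytest.fixture(scope="session")
def coarse_field():
    """Small noise-free climate field for fast niche tests."""
    # steps chosen so each study box still contains grid-cell centers
    cfg = pt.ClimateConfig(lon_step=11.5, lat_step=7.5, noise_sd=0.0)
    return pt.make_climate(cfg)


@pytest.fixture(scope="session")
def default_field():
    """Full-resolution synthetic climate field (63 x 49 x 121)."""
    return pt.make_climate(pt.ClimateConfig())


@pytest.fixture
def toy_field():
    """2 x 2 x 2 field with hand-enumerable values."""
    T = np.arange(8, dtype=float).reshape(2, 2, 2)
    P = 100.0 + 10.0 * np.arange(8, dtype=float).reshape(2, 2, 2)
    return pt.ClimateField(
        lon=np.array([-90.0, 90.0]),
        lat=np.array([-45.0, 45.0]),
        time=np.array([100_000.0, 50_000.0]),
        T=T,
        P=P,
    )
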