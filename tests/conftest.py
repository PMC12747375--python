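import numpy as np
import pytest

from evcl.series_io import lezhi_series
from evcl.valuation import lezhi_constants


@pytest.fixture(scope="session")
def urban_pct():
    """Bundled urbanization-rate series, percent scale, 1979-2022."""
    return lezhi_series("urbanization_rate")


@pytest.fixture(scope="session")
def gdp_pct():
    """Bundled GDP-growth-rate series, percent scale, 1979-2022."""
    return lezhi_series("gdp_growth_rate")


@pytest.fixture(scope="session")
def consts():
    """Bundled county valuation constants."""
    return lezhi_constants()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
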