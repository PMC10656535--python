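import numpy as np
import pytest

from poplogistic import CensusSeries, LogisticParams, logistic_exact, paper_fixture

#: Fitted adjusted-census parameters (r per year, K and N0 in individuals)
ADJ_R = 0.0374286
ADJ_K = 225062093.9465337
ADJ_N0 = 76398000.0

BANGLADESH_CENSUS_YEARS = [1974, 1981, 1991, 2001, 2011, 2022]


@pytest.fixture(scope="session")
def adjusted_params() -> LogisticParams:
    """The adjusted-census fitted logistic parameters (from the fixtures file)."""
    params = paper_fixture("adjusted_params")
    assert (params.r, params.K, params.N0) == (ADJ_R, ADJ_K, ADJ_N0)
    return params


@pytest.fixture(scope="session")
def bangladesh_like_census(adjusted_params) -> CensusSeries:
    """A six-point census whose interior follows the fitted logistic curve.

    The full census table behind the study is unpublished, so this synthetic
    stand-in anchors the endpoints at the two printed observations (N0 and
    the adjusted 2022 count) and fills the interior from the fitted model.
    """
    years = BANGLADESH_CENSUS_YEARS
    counts = [float(logistic_exact(adjusted_params, y - 1974)) for y in years]
    counts[0] = ADJ_N0
    counts[-1] = float(paper_fixture("census_2022.adjusted"))
    return CensusSeries(years=tuple(years), counts=tuple(counts), epoch_year=1974)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
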