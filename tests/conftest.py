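import numpy as np
import pytest

from opennmix.count_data import CountDataset, PeriodScheme, SiteSeries


@pytest.fixture
def two_period_scheme() -> PeriodScheme:
    return PeriodScheme(((2000, 2001), (2002, 2003)), ("early", "late"))


@pytest.fixture
def one_period_scheme() -> PeriodScheme:
    return PeriodScheme(((2000, 2009),), ("all",))


@pytest.fixture
def small_dataset() -> CountDataset:
    return CountDataset((
        SiteSeries("a", (2000, 2001, 2002, 2003), (6, 9, 4, 7)),
        SiteSeries("b", (2000, 2002, 2003), (3, 5, 8)),   # gap at 2001
        SiteSeries("c", (2001, 2002), (12, 0)),           # zero is an observation
    ))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160913)
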