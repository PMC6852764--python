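import numpy as np
import pytest

from raredetect import FrequencyVector

# (rarest frequency, number of subpopulations, exact n*, independence n*)
# at c = 10 representatives each and target probability 0.95
TABLE2_SCENARIOS = [
    (0.1, 6, 186, 186),
    (0.2, 3, 85, 85),
    (0.3, 2, 53, 53),
    (0.1, 8, 191, 191),
    (0.2, 4, 87, 87),
    (0.4, 2, 39, 39),
    (0.1, 9, 193, 193),
    (0.3, 3, 55, 55),
    (0.1, 10, 195, 194),
    (0.2, 5, 89, 89),
    (0.5, 2, 30, 30),
]


@pytest.fixture(scope="session")
def table2_scenarios():
    return TABLE2_SCENARIOS


@pytest.fixture
def half_half():
    return FrequencyVector([0.5, 0.5])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
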