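import numpy as np
import pytest

from tprfam.patterns import ISRE_CONSENSUS, TPR_CONSENSUS, parse_pattern


@pytest.fixture(scope="session")
def tpr_pattern():
    return parse_pattern(TPR_CONSENSUS, "protein", name="TPR")


@pytest.fixture(scope="session")
def isre_pattern():
    return parse_pattern(ISRE_CONSENSUS, "dna", name="ISRE")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
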