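import numpy as np
import pytest

from cytosig import luminex
from cytosig.synthetic import CytokineSimConfig, gen_cytokine_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic plate (2 genotypes x 4 timepoints x 10 mice,
    32 cytokines, technical triplicates) with its ground truth."""
    return gen_cytokine_study(CytokineSimConfig(seed=1))


@pytest.fixture(scope="session")
def cleaned_matrix(default_study):
    plate, _ = default_study
    return luminex.clean_plate(plate)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
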