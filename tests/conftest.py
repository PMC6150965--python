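import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from karyometry import (
    make_metaphase,
    simulate_study,
    table1_dataset,
    table1_params,
)

#: published per-population karyotype lengths (μm); MC and CC printed sums
#: differ from the printed KL by 0.01 due to rounding of per-chromosome means
PRINTED_KL = {"CI": 83.06, "TO": 82.72, "BG": 73.38, "MC": 68.63, "CC": 66.08}
EXACT_KL_POPS = ("CI", "TO", "BG")


@pytest.fixture(scope="session")
def fixture_dataset():
    """Packaged summary table expanded to one metaphase per population."""
    return table1_dataset()


@pytest.fixture(scope="session")
def study_params():
    return table1_params()


@pytest.fixture(scope="session")
def synthetic_study(study_params):
    """Five populations x 10 metaphases simulated from packaged parameters."""
    return simulate_study(study_params, seed=20_260_921)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_metaphase():
    """Two-chromosome toy metaphase: (L,S) = (3,1) and (2,2)."""
    return make_metaphase("spec1", "POP", [(3.0, 1.0), (2.0, 2.0)])
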