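import numpy as np
import pytest

from fluorisk.exposure import exposure_parameters
from fluorisk.synthetic import paper_shaped_design, study_bundle

#: Observed fresh and end-of-roast (day 30) mean fluoride concentrations,
#: mg/kg, used as reference inputs throughout the tests.
FRESH = {"corn": 1.72, "chili": 8.56, "pork": 6.47, "tofu": 6.19}
PEAK = {"corn": 308.24, "chili": 869.82, "pork": 141.59, "tofu": 265.70}


@pytest.fixture(scope="session")
def children_params():
    return {food: exposure_parameters("children", food) for food in FRESH}


@pytest.fixture(scope="session")
def adults_params():
    return {food: exposure_parameters("adults", food) for food in FRESH}


@pytest.fixture(scope="session")
def default_design():
    return paper_shaped_design()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """One noisy synthetic study bundle shared by I/O and pipeline tests."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = study_bundle(20240409, out, paper_shaped_design(survey_n=300))
    return out, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
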