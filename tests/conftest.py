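import numpy as np
import pytest
from hypothesis import settings

from mycoscreen.config import Config
from mycoscreen.simulate import SurveyParams, gen_panel, gen_survey

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg() -> Config:
    return Config()


@pytest.fixture(scope="session")
def panel_bundle():
    return gen_panel(seed=7)


@pytest.fixture(scope="session")
def survey_small():
    """A small truth-annotated survey shared by pipeline-level tests."""
    return gen_survey(SurveyParams(n_hosts=10), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
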