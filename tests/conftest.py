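import numpy as np
import pytest

from freqtag.design import DesignParams, build_lexicon, plan_session
from freqtag.layout import make_layout


@pytest.fixture(scope="session")
def layout32():
    return make_layout(32, np.random.default_rng(0))


@pytest.fixture(scope="session")
def layout125():
    return make_layout(125, np.random.default_rng(0))


@pytest.fixture(scope="session")
def default_design():
    return DesignParams()


@pytest.fixture(scope="session")
def small_lexicon():
    return build_lexicon((8, 4, 4), np.random.default_rng(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def passive_plan(default_design, small_lexicon):
    return plan_session("passive", small_lexicon, default_design, np.random.default_rng(7))
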