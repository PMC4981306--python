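import logging

import pytest

from oabtree import load_parameters, point_estimates

logging.getLogger("oabtree").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ps():
    return load_parameters()


@pytest.fixture(scope="session")
def env(ps):
    return point_estimates(ps)
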