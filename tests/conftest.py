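import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: parameter pairs spanning the simulation-study settings
PARAM_GRID = [
    (0.5, 0.75),
    (0.75, 0.5),
    (1.5, 1.25),
    (1.75, 1.5),
    (2.0, 1.75),
    (2.5, 3.25),
]


@pytest.fixture(params=PARAM_GRID, ids=lambda p: f"a{p[0]}-b{p[1]}")
def params(request):
    return request.param
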