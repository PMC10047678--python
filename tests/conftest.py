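import warnings

import numpy as np
import pytest

from nlhrv.preprocess import RRSeries
from nlhrv.synthetic import GeneratorConfig, generate


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # embedding-selection fallbacks warn on purpose; keep test output clean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ar_series():
    """A stationary AR(2) null RR series at the default study conditions."""
    return generate(GeneratorConfig(kind="ar_null", seed=7))


@pytest.fixture
def constant_series():
    return RRSeries(np.full(300, 800.0), record_id="const")


def make_series(kind, seed=0, **params):
    return generate(GeneratorConfig(kind=kind, seed=seed, params=params))
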