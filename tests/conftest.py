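import numpy as np
import pytest

from catchbond import builtin_model, slip_model
from catchbond.recipes import generate_fixtures


@pytest.fixture(scope="session")
def type1():
    return builtin_model("type1")


@pytest.fixture(scope="session")
def type2():
    return builtin_model("type2")


@pytest.fixture(scope="session")
def slip14():
    """The slip bond used for analytic-strength checks: k_s0 = 1/s, Fb = 14 pN."""
    return slip_model(1.0, 14.0)


@pytest.fixture(scope="session")
def fixtures():
    return generate_fixtures(seed=1234)
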