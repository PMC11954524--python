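import numpy as np
import pytest

from ptckin.contexts import parse_context
from ptckin.simulate import GeneratorConfig


@pytest.fixture
def reference_ctx():
    return parse_context("CAA UGA CUA AUG ACC UUU", "Reference")


@pytest.fixture
def patient_ctx():
    return parse_context("AUG UGA UCU GUG AGC CGA", "CF-R1158X*")


@pytest.fixture
def gen_cfg():
    return GeneratorConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
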