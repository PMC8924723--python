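"""Shared fixtures built on the package's miniature reference models."""
import pytest
from hypothesis import settings

from ceasim.synthetic import generate_default_params
from ceasim.toy import (geometric_effect, make_break_even_scenario,
                        make_survival_chain)

__all__ = ["geometric_effect", "make_break_even_scenario",
           "make_survival_chain"]

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def survival_chain():
    return make_survival_chain(0.2)


@pytest.fixture
def break_even_scenario():
    return make_break_even_scenario()


@pytest.fixture(scope="session", params=["dermatology", "dentistry",
                                         "ophthalmology"])
def default_paramset(request):
    return generate_default_params(request.param, seed=7)


@pytest.fixture(scope="session")
def dentistry_paramset():
    return generate_default_params("dentistry", seed=7)
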