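import pytest

from brcacea import (
    build_testing_strategy,
    build_usual_care_strategy,
    default_parameters,
)


@pytest.fixture(scope="session")
def params():
    """The packaged default parameter set (published model inputs)."""
    return default_parameters()


@pytest.fixture(scope="session")
def testing_strategy(params):
    return build_testing_strategy(params)


@pytest.fixture(scope="session")
def usual_strategy(params):
    return build_usual_care_strategy(params)
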