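import pytest

from aftrial.cohort import fig1_fixture
from aftrial.design import DesignConfig


@pytest.fixture(scope="session")
def fig1_cohort():
    return fig1_fixture()


@pytest.fixture()
def design():
    return DesignConfig()
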