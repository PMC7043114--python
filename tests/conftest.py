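import pytest

from p2i import (
    P2I_V2_PARAMS,
    Candidate,
    Phase,
    aggregate_portfolio,
    evi_portfolio_fixture,
)


@pytest.fixture(scope="session")
def evi_portfolio():
    return evi_portfolio_fixture()


@pytest.fixture(scope="session")
def baseline_result(evi_portfolio):
    return aggregate_portfolio(evi_portfolio)


@pytest.fixture(scope="session")
def params():
    return P2I_V2_PARAMS


@pytest.fixture
def simple_phase1():
    return Candidate("Nipah 1", "Nipah", "simple", Phase.PHASE1)


@pytest.fixture
def unprecedented_preclinical():
    return Candidate("Malaria 6", "malaria", "unprecedented", Phase.PRECLINICAL)


@pytest.fixture
def unprecedented_phase2():
    return Candidate("Malaria 1", "malaria", "unprecedented", Phase.PHASE2)
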