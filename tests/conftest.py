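import logging

import pytest

from ezmt import build_paper_scenarios, run_scenario
from ezmt.synthesis import ParameterSpace, sample_scenarios

# the canonical low-concentration scenarios intentionally violate the
# linearization threshold; silence the (expected) warnings during tests
logging.getLogger("ezmt.fields").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper_scenarios():
    """The twelve canonical tubulin scenarios."""
    return {sc.scenario_id: sc for sc in build_paper_scenarios()}


@pytest.fixture(scope="session")
def paper_results(paper_scenarios):
    """Each canonical scenario run once, keyed by scenario id."""
    return {sid: run_scenario(sc) for sid, sc in paper_scenarios.items()}


@pytest.fixture(scope="session")
def synthetic_scenarios():
    """200 randomized physical scenarios for property checks."""
    return sample_scenarios(ParameterSpace(), n=200, seed=20220425)
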