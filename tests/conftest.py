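import pytest
from hypothesis import settings

from mepnet.fixtures import make_central_metabolism
from mepnet.kinetics import infer_rate_constants
from mepnet.maxent import optimize_to_steady_state
from mepnet.regulation import TargetAssignment, tune_regulation

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def glyc_tca():
    """Glycolysis+TCA fixture (20 variable metabolites x 20 reactions)."""
    model, state = make_central_metabolism(include_ppp=False)
    return model, state


@pytest.fixture(scope="session")
def glyc_tca_steady(glyc_tca):
    """Unregulated maximum-entropy-production steady state of the fixture."""
    model, state = glyc_tca
    result = optimize_to_steady_state(model, state)
    assert result.converged, result.message
    return result


@pytest.fixture(scope="session")
def regulated(glyc_tca):
    """PFK regulated by ATP, tuned until the loss table is satisfied."""
    model, state = glyc_tca
    rules, result, diag = tune_regulation(
        model, state, None, [TargetAssignment("PFK", "atp_c")]
    )
    assert result.converged, result.message
    return rules, result, diag


@pytest.fixture(scope="session")
def inferred_rates(glyc_tca, regulated):
    model, _ = glyc_tca
    rules, result, _ = regulated
    return infer_rate_constants(result, model, rules)
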