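import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nih3t3():
    from rhocycle.synthetic import nih3t3_fixture

    return nih3t3_fixture()


@pytest.fixture(scope="session")
def nih3t3_predictions(nih3t3):
    """Steady-state observables for all eight conditions (computed once)."""
    from rhocycle.fitting import predict_dataset

    return predict_dataset(
        nih3t3.rates, nih3t3.totals, nih3t3.conditions
    ).set_index("condition")


@pytest.fixture(scope="session")
def betacell_baseline_state():
    from rhocycle.betacell import baseline_state

    return baseline_state()
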