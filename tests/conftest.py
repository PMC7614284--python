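import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

warnings.filterwarnings("ignore", category=FutureWarning)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def single_scenario():
    from illnessdeath.synthetic import ScenarioConfig

    return ScenarioConfig(variant="single-area", seed=1)


@pytest.fixture(scope="session")
def single_truth(single_scenario):
    from illnessdeath.synthetic import make_true_rates

    return make_true_rates(single_scenario)


@pytest.fixture(scope="session")
def single_data(single_truth):
    from illnessdeath.synthetic import simulate_dataset

    return simulate_dataset(single_truth, seed=1)


@pytest.fixture(scope="session")
def single_model(single_scenario, single_data):
    from illnessdeath.model import assemble_model
    from illnessdeath.synthetic import matching_config

    return assemble_model(matching_config(single_scenario), single_data)


@pytest.fixture(scope="session")
def single_fit(single_model):
    from illnessdeath.engines import fit_mode_laplace

    return fit_mode_laplace(single_model, seed=1, n_draws=800)


@pytest.fixture(scope="session")
def informative_ages(single_truth):
    """Ages where the true prevalence exceeds 1%."""
    pi = single_truth.outcome_probs(("all", "all")).prev
    return np.nonzero(pi > 0.01)[0]
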