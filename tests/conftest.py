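import pytest

from lipidpulse.expansion import expand_network
from lipidpulse.inference import EstimationProblem
from lipidpulse.network import build_base_network
from lipidpulse.population import PopulationDistribution, generate_cohort, sample_parameters
from lipidpulse.simulate import LabelSchedule


@pytest.fixture(scope="session")
def base():
    return build_base_network()


@pytest.fixture(scope="session")
def models(base):
    """Expanded models for 0..4 labels, built once."""
    return {nl: expand_network(base, nl) for nl in range(5)}


@pytest.fixture(scope="session")
def theta_typical(base):
    """One parameter vector drawn from the default population."""
    dist = PopulationDistribution.default(base.n_rules)
    return sample_parameters(dist, 1, seed=2024)[0]


@pytest.fixture(scope="session")
def cohort_1label(base):
    """Tiny single-label cohort shared by inference tests."""
    return generate_cohort(base, 1, n_cells=2, seed=5)


@pytest.fixture(scope="session")
def problem_1label(models, cohort_1label):
    return EstimationProblem.from_measurement_set(
        models[1], LabelSchedule.default(1), cohort_1label.measurements[0]
    )
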