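import numpy as np
import pytest
from hypothesis import settings

from synapsim import presets
from synapsim.rulegen import generate_model
from synapsim.simulate import ExperimentSetup, simulate

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")

#: the two drug doses (nM) whose trajectories the flux audit is reported at
PRINTED_DOSES = (8.4e-4, 0.672)


@pytest.fixture(scope="session")
def minimal_model():
    return generate_model(presets.minimal_definition())


@pytest.fixture(scope="session")
def full_model():
    return generate_model(presets.trispecific_definition())


@pytest.fixture(scope="session")
def reduced_model():
    return generate_model(presets.reduced_blood_definition())


@pytest.fixture(scope="session")
def full_trajectories(full_model):
    """Full trispecific model integrated for 3 days at the two audit doses."""
    return {
        dose: simulate(full_model, None, ExperimentSetup(dose=dose, duration=72.0))
        for dose in PRINTED_DOSES
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
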