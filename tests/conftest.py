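import numpy as np
import pytest

from synthintake.backends import ScriptedMockBackend
from synthintake.patients import canonical_template, generate_patient
from synthintake.population import load_population_config, packaged_config_path
from synthintake.questionbank import load_question_bank, packaged_bank_path


@pytest.fixture(scope="session")
def cfg():
    return load_population_config(packaged_config_path())


@pytest.fixture(scope="session")
def bank():
    return load_question_bank(packaged_bank_path())


@pytest.fixture(scope="session")
def template():
    return canonical_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def patient(cfg, template):
    """One fully enriched mock patient, reused where its identity is irrelevant."""
    return generate_patient(cfg, template, ScriptedMockBackend(seed=11), master_seed=11, index=0)


@pytest.fixture()
def mock_backend():
    def factory(seed=0, **kwargs):
        return ScriptedMockBackend(seed=seed, **kwargs)

    return factory
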