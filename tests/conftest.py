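import numpy as np
import pytest

from coredisorder import lv
from coredisorder.synthetic import ScenarioConfig, generate_core


@pytest.fixture(scope="session")
def three_role_community():
    """Keystone / weed / canary reference parameters at pristine habitat."""
    return lv.reference_community(h=1.0)


@pytest.fixture(scope="session")
def anti_phase_core():
    return generate_core(ScenarioConfig(phase="anti-phase", seed=42), n_sections=120)


@pytest.fixture(scope="session")
def in_phase_core():
    return generate_core(ScenarioConfig(phase="in-phase", seed=42), n_sections=120)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
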