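import numpy as np
import pytest

from beamcascade import (forward, make_eeg_sensors, make_meg_sensors,
                         make_reference_sources, make_shell_model)


@pytest.fixture(scope="session")
def shells():
    return make_shell_model("reference")


@pytest.fixture(scope="session")
def eeg_sensors(shells):
    return make_eeg_sensors(40, shells)


@pytest.fixture(scope="session")
def meg_sensors():
    return make_meg_sensors(60)


@pytest.fixture(scope="session")
def reference_sources():
    return make_reference_sources(12, cortex_radius=70.0, seed=5)


@pytest.fixture(scope="session")
def source_space(shells, reference_sources):
    return forward.build_source_space(300, shells, reference_sources, seed=6,
                                      cortex_radius=70.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, n, cond_floor=0.5):
    a = rng.standard_normal((n, n))
    return a @ a.T / n + cond_floor * np.eye(n)
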