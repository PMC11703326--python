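import numpy as np
import pytest

from contrastnav.fingerprints import (
    build_dictionary,
    default_schedules,
    default_tissue_grid,
)


@pytest.fixture(scope="session")
def short_schedules():
    """Six default flip-angle patterns at a desk-scale train length."""
    return default_schedules(n_patterns=6, n_pulses=192)


@pytest.fixture(scope="session")
def dictionary(short_schedules):
    """Default parenchyma/CSF dictionary for pattern 1."""
    return build_dictionary(default_tissue_grid(), short_schedules[0])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
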