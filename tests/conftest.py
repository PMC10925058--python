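import dataclasses

import numpy as np
import pytest

from pulmopet.kinetics import InputFunction
from pulmopet.phantom import PhantomConfig, make_input_function, simulate_study


@pytest.fixture(scope="session")
def const_input():
    """Constant plasma concentration C_p = 1 over 0..2000 s."""
    return InputFunction(np.array([0.0, 2000.0]), np.array([1.0, 1.0]))


@pytest.fixture(scope="session")
def infusion_input():
    return make_input_function("infusion", {"amplitude": 20.0},
                               np.arange(0.0, 961.0, 1.0))


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def noiseless_config():
    """Residual and TAC noise off (closed-loop conditions)."""
    return dataclasses.replace(PhantomConfig(), residual_sd_baseline=1e-12,
                               residual_sd_injury=0.0)


@pytest.fixture(scope="session")
def small_noiseless_bundle(noiseless_config):
    """Two animals, both conditions, no noise anywhere."""
    cfg = dataclasses.replace(noiseless_config, n_animals=2)
    return simulate_study(cfg, noiseless=True)
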