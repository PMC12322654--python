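import numpy as np
import pytest

from azoswitch.synthetic_data import PROFILES, gen_ensemble, gen_quantum_yield_experiment


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture(scope="session")
def small_trans_ensemble():
    """A modest dfdc-like trans ensemble with geometries, shared across tests."""
    frames, table = gen_ensemble(PROFILES["dfdc-like"], "trans", n=200, seed=11)
    return frames, table


@pytest.fixture(scope="session")
def qy_experiment():
    """One synthetic quantum-yield run (default planted yield, default noise)."""
    return gen_quantum_yield_experiment(seed=0)
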