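import numpy as np
import pytest

from hypercol.config import default_spec
from hypercol.inputs import Stimulus
from hypercol.simulate import Recorders, run


@pytest.fixture(scope="session")
def mini_spec():
    """Miniature network (200 E + 50 I per layer) with statistics-preserving
    scaling; probability clipping allowed at this size."""
    return default_spec(n_exc=200, n_inh=50, probability_overflow="clip",
                        master_seed=7)


@pytest.fixture(scope="session")
def mini_run_low(mini_spec):
    """3 s of the miniature network at low contrast, rich recording."""
    ids = tuple(range(0, 100, 10))
    return run(mini_spec, Stimulus(contrast=0.02), 3000,
               Recorders(chi_populations=("upper_E",), lfp_sectors=((0.0, 9.0),),
                         voltage_ids=ids, current_ids=ids, input_share=True,
                         background_rate=True, warmup_ms=500.0), seed=11)


@pytest.fixture(scope="session")
def mini_run_high(mini_spec):
    return run(mini_spec, Stimulus(contrast=0.95), 3000,
               Recorders(chi_populations=("upper_E",), lfp_sectors=((0.0, 9.0),),
                         warmup_ms=500.0), seed=11)


@pytest.fixture(scope="session")
def logistic_series():
    x = np.empty(20000)
    x[0] = 0.3
    for i in range(1, x.size):
        x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
    return x


@pytest.fixture(scope="session")
def ou_series():
    rng = np.random.default_rng(5)
    x = np.empty(30000)
    x[0] = 0.0
    a = np.exp(-1.0 / 10.0)
    sd = np.sqrt(1.0 - a * a)
    for i in range(1, x.size):
        x[i] = a * x[i - 1] + sd * rng.standard_normal()
    return x
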