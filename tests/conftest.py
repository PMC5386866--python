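import numpy as np
import pytest

from sibmap import synthdata as sd


@pytest.fixture(scope="session")
def small_pop():
    """Two-LG noiseless population shared by fast unit tests."""
    cfg = sd.SimConfig(
        n_lg=2, lg_lengths=[100.0, 90.0], n_progeny=150, marker_density=0.8, seed=101
    )
    return sd.simulate_population(cfg)


@pytest.fixture(scope="session")
def noisy_pop():
    """Population with 10% missing calls for imputation tests."""
    cfg = sd.SimConfig(
        n_lg=2, lg_lengths=[100.0, 90.0], n_progeny=200, marker_density=1.0,
        missing_rate=0.10, seed=202,
    )
    return sd.simulate_population(cfg)


@pytest.fixture(scope="session")
def biparental_pop():
    """Population including all five segregation types."""
    cfg = sd.SimConfig(
        n_lg=1,
        lg_lengths=[80.0],
        n_progeny=150,
        marker_density=1.0,
        type_mix={"lmxll": 0.3, "nnxnp": 0.3, "hkxhk": 0.2, "efxeg": 0.1, "abxcd": 0.1},
        seed=303,
    )
    return sd.simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
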