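import numpy as np
import pytest
from hypothesis import settings

import hitchdriver as hd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_tumor():
    """One small supercritical birth-death tumor with a k=2 driver."""
    cfg = hd.SimConfig(k=2.0)
    return hd.simulate_birth_death(cfg, seed=11)


@pytest.fixture(scope="session")
def small_tumor_spectrum(small_tumor):
    rng = np.random.default_rng(3)
    df = small_tumor.spectrum(coverage=1000, rng=rng)
    return hd.order_spectrum(df, sample_id="small")


@pytest.fixture(scope="session")
def single_driver_forward():
    """Noise-free single-driver spectrum plus its truth."""
    table, ranks = hd.forward_model_spectrum([(0.3, 2.0)], r=0.02, n_tot=1e6, tail=300)
    return hd.order_spectrum(table, "fm1"), ranks[0]


@pytest.fixture(scope="session")
def three_driver_forward():
    table, ranks = hd.forward_model_spectrum(
        [(0.55, 1.8), (0.3, 2.5), (0.12, 2.0)], r=0.02, n_tot=1e6, tail=300
    )
    return hd.order_spectrum(table, "fm3"), ranks
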