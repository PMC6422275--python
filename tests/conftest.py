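import numpy as np
import pytest

import mataboot as mb


@pytest.fixture
def design3():
    """Standard 2^3 layout with 5 replicates and the P/I/V factor names."""
    return mb.FactorialDesign(("P", "I", "V"), 5)


@pytest.fixture
def effects_pi():
    """Effect set dominated by P, I and their interaction."""
    return mb.EffectSet(
        mu=0.5,
        main=(1.0, 0.8, 0.05),
        two_way=(0.6, 0.02, 0.03),
        three_way=0.01,
        sigma2=0.4,
    )


@pytest.fixture
def dataset3(design3, effects_pi):
    rng = np.random.default_rng(42)
    return mb.simulate_dataset(effects_pi, design3, rng)


@pytest.fixture
def fits3(design3, dataset3):
    log_y = np.log(dataset3["response"].to_numpy())
    return mb.fit_all_models(design3, log_y, dataset3)


@pytest.fixture
def models3():
    return mb.enumerate_hierarchical_models(3, ("P", "I", "V"))
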