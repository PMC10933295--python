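import numpy as np
import pandas as pd
import pytest

from osteomix.simulate import SimulationConfig, generate_cohort


def small_config(seed=0, **kw):
    """A reduced cohort that keeps unit tests fast."""

    defaults = dict(
        n_normal=30, n_osteopenia=40, n_osteoporosis=40,
        n_features={"methylation": 60, "metabolite": 60, "microbiota": 60},
        n_signature={"methylation": 8, "metabolite": 8, "microbiota": 8},
        n_variants=50, n_qtl_effects=3, rewiring_pairs=4,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=0))


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (91/158/117) at the generator's defaults."""

    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
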