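import numpy as np
import pandas as pd
import pytest

from methage import synth


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions shared by the slower integration tests."""
    return synth.SimulationConfig(
        n_probes=400,
        n_samples=80,
        n_age_cpgs=30,
        n_ad_cpgs=20,
        n_ml_cpgs=60,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return synth.generate_reference_panel(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_panel, small_config):
    return synth.generate_mixture_cohort(small_panel, small_config)


@pytest.fixture()
def toy_beta():
    """5 probes x 4 samples, no missing values."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(5, 4)),
        index=[f"cg{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
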