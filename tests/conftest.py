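import numpy as np
import pytest

import paddyflux as pf


@pytest.fixture(scope="session")
def clean_dataset() -> pf.SyntheticDataset:
    """Noise-free pot experiment: exact-recovery fixtures."""
    return pf.simulate_pot_experiment(
        pf.ExperimentParams(noise_sd_permil=0.0, flux_noise_ppm=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def noisy_dataset() -> pf.SyntheticDataset:
    """Pot experiment at the default measurement noise."""
    return pf.simulate_pot_experiment(pf.ExperimentParams(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
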