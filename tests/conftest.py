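import dataclasses

import numpy as np
import pytest

from airkerma.surrogate import GridSpec, SurrogateParams, generate_dataset


@pytest.fixture(scope="session")
def noiseless_params() -> SurrogateParams:
    return dataclasses.replace(SurrogateParams(), noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_grid_dataset(noiseless_params):
    """Full default 8250-row grid with exact closed-form kerma values."""
    return generate_dataset(GridSpec(), noiseless_params, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230414)
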