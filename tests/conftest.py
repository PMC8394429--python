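import numpy as np
import pytest

from nixdry import KineticParams
from nixdry.synthetic import (ExperimentDesign, ZERO_NOISE, dataset_to_series,
                              generate_trajectories)

#: Published per-ST (k /min, ME %) rows of the drying-rate table, with the
#: package's synthetic stand-in M0 profile.
REFERENCE_ROWS = {
    0.0: dict(k=0.0185, me=5.088, m0=38.0),
    2.0: dict(k=0.0161, me=5.399, m0=45.0),
    4.0: dict(k=0.0158, me=5.792, m0=47.0),
    6.0: dict(k=0.0147, me=5.646, m0=46.5),
    8.0: dict(k=0.0140, me=5.836, m0=46.0),
}


@pytest.fixture
def st0_params():
    """Reference condition: ST = 0 h with the stand-in M0 = 47 % used in
    worked scalar examples."""
    return KineticParams(m0=47.0, me=5.088, k=0.0185)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Exact model trajectories at the full design (5 STs, 10 times, 5 reps)."""
    df = generate_trajectories(ExperimentDesign(seed=7), noise=ZERO_NOISE)
    return dataset_to_series(df)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise trajectories at the full design, fixed seed."""
    df = generate_trajectories(ExperimentDesign(seed=2024))
    return dataset_to_series(df)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
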