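import numpy as np
import pytest

from cardiossm.synthetic_ecg import SyntheticCohortConfig, synth_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """60 short records (1024 samples) shared by fast tests."""
    cfg = SyntheticCohortConfig(n_records=60, length=1024, seed=99)
    records, manifest = synth_dataset(cfg)
    return records, manifest, cfg
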