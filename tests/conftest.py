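import numpy as np
import pytest

from striaparc import SyntheticConfig, generate_dataset, subject_profiles


@pytest.fixture(scope="session")
def small_dataset():
    """Eight subjects, default planted structure, short series."""
    return generate_dataset(SyntheticConfig(n_subjects=8, T=100, rng_seed=42))


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    return [
        subject_profiles(s.roi_series, s.target_series, s.subject_id)
        for s in small_dataset.subjects
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
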