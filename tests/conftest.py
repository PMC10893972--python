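import numpy as np
import pytest

import orientwm as ow


@pytest.fixture(scope="session")
def design8():
    """A full-size 8-run counterbalanced trial design."""
    return ow.generate_design(8, seed=123)


@pytest.fixture(scope="session")
def small_signal_dataset():
    """A small high-SNR dataset: 4 runs, 80 voxels, phase grid of 90."""
    design = ow.generate_design(4, seed=7)
    profiles = ow.sample_tuning_profiles(80, grid_size=90, seed=8)
    voxels = ow.simulate_voxel_responses(profiles, design, snr=1.0, seed=9)
    return design, voxels, profiles


@pytest.fixture(scope="session")
def small_samples(small_signal_dataset):
    design, voxels, _ = small_signal_dataset
    return ow.extract_trial_samples(voxels, design)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
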