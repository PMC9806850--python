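import warnings

import numpy as np
import pytest

from microstates.io import build_spherical_montage, default_channel_names
from microstates.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def montage64():
    return build_spherical_montage(64)


@pytest.fixture(scope="session")
def names64():
    return default_channel_names(64)


@pytest.fixture(scope="session")
def montage8():
    return build_spherical_montage(8)


@pytest.fixture(scope="session")
def names8():
    return default_channel_names(8)


def four_class_config(**overrides) -> SyntheticConfig:
    """One-group scenario: both groups share classes A-D, no group effects."""
    base = dict(
        duration_s=120.0,
        snr=2.0,
        patient_classes=["A", "B", "C", "D"],
        control_classes=["A", "B", "C", "D"],
        group_effects={},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Small 4-class cohort at the default study conditions (SNR 2, 120 s,
    64 channels, 125 Hz), shared across recovery tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(four_class_config(), 2, 2, seed=2024)


@pytest.fixture(scope="session")
def two_group_cohort():
    """Default two-group scenario (patients carry E, controls carry F)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SyntheticConfig(duration_s=60.0), 8, 8, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
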