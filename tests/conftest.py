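import numpy as np
import pytest

from erpindiff.epochs import ELECTRODES_OF_INTEREST
from erpindiff.simulate import CohortConfig, ComponentTemplate, NoiseModel, sample_cohort, simulate_epochs

FLAT_TOPOGRAPHY = {e: 1.0 for e in ELECTRODES_OF_INTEREST}


def noiseless_config(**overrides) -> CohortConfig:
    """Small noiseless cohort: template waveforms only, no covariate effects."""
    defaults = dict(
        n_participants=2,
        trials_per_condition=6,
        effect_map={},
        latency_effect_map={},
        assignment_error_rate=0.0,
        noise=NoiseModel(trial_sd=0.0, item_sd=0.0, participant_sd=0.0, ar1=0.95),
        templates={
            "N400": ComponentTemplate(420.0, 80.0, {"Default": -3.0, "FeatureClash": -3.0}),
            "P600": ComponentTemplate(650.0, 150.0, {"Default": 2.0, "FeatureClash": 2.0}),
        },
        topography=dict(FLAT_TOPOGRAPHY),
        seed=3,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_epochs():
    cfg = noiseless_config()
    return simulate_epochs(sample_cohort(cfg), None, cfg), cfg


@pytest.fixture(scope="session")
def noisy_small_epochs():
    """Small noisy dataset reused by preprocessing and extraction tests."""
    cfg = noiseless_config(
        n_participants=3,
        trials_per_condition=12,
        noise=NoiseModel(trial_sd=6.0, item_sd=1.0, participant_sd=0.5, ar1=0.9),
        assignment_error_rate=0.1,
        seed=7,
    )
    return simulate_epochs(sample_cohort(cfg), None, cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
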