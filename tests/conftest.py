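import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from anchormi import SimConfig, TrialDataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def ten_patient_dataset() -> TrialDataset:
    """3 completers, 4 first-missing-at-visit-2, 3 first-missing-at-visit-3."""
    nan = np.nan
    outcomes = np.array(
        [
            [2.0, 2.1, 2.2],
            [1.9, 2.0, 2.1],
            [2.1, 2.2, 2.0],
            [2.0, nan, nan],
            [1.8, nan, nan],
            [2.2, nan, nan],
            [2.1, nan, nan],
            [2.0, 2.1, nan],
            [1.9, 1.8, nan],
            [2.3, 2.2, nan],
        ]
    )
    ids = np.array([f"p{i}" for i in range(10)], dtype=object)
    arms = np.array(["active"] * 10, dtype=object)
    return TrialDataset(ids, arms, outcomes)


@pytest.fixture
def two_arm_monotone() -> TrialDataset:
    """Small two-arm dataset with monotone dropout in the active arm."""
    rng = np.random.default_rng(7)
    cfg = SimConfig(n_per_arm=40, seed=7)
    from anchormi import generate_complete_trial, impose_mcar_monotone_dropout

    complete = generate_complete_trial(cfg, rng)
    return impose_mcar_monotone_dropout(complete, 0.3, rng)


@pytest.fixture(scope="session")
def trial_params():
    """The asthma-study generator parameters as fitted-parameter objects."""
    return SimConfig().true_params()
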