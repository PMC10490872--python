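"""Shared fixtures: small seeded simulations reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from mi_csp import (
    EpochSet,
    SimConfig,
    butter_bandpass,
    extract_epochs,
    simulate_mi_recording,
)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim20():
    """Default small session: 8 channels, 20 trials/class, blinks on."""
    config = SimConfig(n_channels=8, n_trials_per_class=20, seed=7)
    rec, truth = simulate_mi_recording(config)
    return config, rec, truth


@pytest.fixture(scope="session")
def epochs20(sim20):
    """Band-passed 0.5-2.5 s epochs of the default small session."""
    _, rec, _ = sim20
    return extract_epochs(butter_bandpass(rec))


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, artifact-free session for exact-recovery checks."""
    config = SimConfig(
        n_channels=8,
        n_trials_per_class=50,
        erd_ratio=4.0,
        snr_db=np.inf,
        artifact_rate=0.0,
        seed=21,
    )
    rec, truth = simulate_mi_recording(config)
    return config, rec, truth


@pytest.fixture
def toy_epochs():
    """Two-class toy with population trial covariances diag(4,1) / diag(1,4).

    The closed-form CSP solution has lambda_a = (0.8, 0.2) with axis-aligned
    filters, and the top filter's class-a/class-b variance ratio is 4.
    """
    rng = np.random.default_rng(12)
    n, ns = 40, 2000

    def make(var):
        sd = np.sqrt(np.asarray(var))[:, None]
        return np.stack([sd * rng.standard_normal((2, ns)) for _ in range(n)])

    data = np.concatenate([make([4.0, 1.0]), make([1.0, 4.0])])
    labels = np.r_[np.ones(n), 2 * np.ones(n)].astype(int)
    return EpochSet(data, labels, fs=100.0, window=(0.0, 20.0))
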