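"""Shared fixtures: the default codebook and small synthetic populations."""

import numpy as np
import pytest

from cveptl import codes, synthdata


@pytest.fixture(scope="session")
def codebook():
    return codes.default_codebook()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def spd(rng, n, scale=1.0):
    """A random well-conditioned SPD matrix."""
    A = rng.normal(size=(n, n))
    return scale * (A @ A.T + n * np.eye(n))


@pytest.fixture(scope="session")
def small_population(codebook):
    """Three noisy subjects, few trials — cheap end-to-end input."""
    return synthdata.simulate_population(
        n_subjects=3,
        similarity_clusters=1,
        seed=7,
        n_train=4,
        n_test_per_target=2,
        n_channels=4,
    )


@pytest.fixture(scope="session")
def noiseless_population(codebook):
    """Three subjects with zero noise and zero jitter."""
    return synthdata.simulate_population(
        n_subjects=3,
        similarity_clusters=1,
        seed=3,
        n_train=2,
        n_test_per_target=1,
        n_channels=4,
        snr_range=(np.inf, np.inf),
        trial_amp_jitter=0.0,
        trial_latency_jitter_s=0.0,
    )
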