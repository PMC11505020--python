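"""Shared fixtures: synthetic benchmarks at two scales.

The "small" fixtures (6 channels, 4 s epochs) keep unit tests fast; the
"benchmark" fixtures are the full-scale easy two-class set (24 channels,
10 s epochs at 250 Hz, 100 epochs per class) used by the end-to-end
accuracy checks.  Everything is session-scoped because feature
extraction dominates runtime.
"""

import warnings

import numpy as np
import pytest

from eegens.eegdata import SynthSpec, generate_synthetic, split_train_test
from eegens.featurebank import extract_features
from eegens.hht import hht_features

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture(scope="session")
def small_epochs():
    return generate_synthetic(
        SynthSpec(n_epochs_per_class=100, n_channels=6, epoch_seconds=4.0, seed=0)
    )


@pytest.fixture(scope="session")
def small_features(small_epochs):
    return extract_features(small_epochs)


@pytest.fixture(scope="session")
def small_split(small_epochs):
    return split_train_test(small_epochs, 0.75, seed=1)


@pytest.fixture(scope="session")
def benchmark_epochs():
    return generate_synthetic(SynthSpec(n_epochs_per_class=100, seed=0))


@pytest.fixture(scope="session")
def benchmark_features(benchmark_epochs):
    return extract_features(benchmark_epochs)


@pytest.fixture(scope="session")
def benchmark_hht_features(benchmark_epochs):
    return hht_features(benchmark_epochs, max_imfs=4)


@pytest.fixture(scope="session")
def permuted_noise_table():
    """Pure-noise feature table with shuffled balanced labels."""
    from eegens.featurebank import FeatureTable

    rng = np.random.default_rng(7)
    n, q = 200, 50
    labels = rng.permutation(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)])
    return FeatureTable(
        values=rng.standard_normal((n, q)),
        feature_names=[f"f{i:02d}" for i in range(q)],
        labels=labels,
    )
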