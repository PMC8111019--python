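import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from thoraxsearch import (FeatureSimSpec, PhantomSpec, StubBackbone,
                          generate_feature_clusters, generate_phantoms)


@pytest.fixture(scope="session")
def stub_backbone():
    return StubBackbone(seed=0)


@pytest.fixture(scope="session")
def phantom_batch():
    """Small noisy phantom collection shared across modules."""
    return generate_phantoms(PhantomSpec(n_images=24, positive_fraction=0.25,
                                         noise_sd=0.01, seed=11))


@pytest.fixture(scope="session")
def clean_negative_phantom():
    """A noise-free negative: exactly mirror-symmetric by construction."""
    spec = PhantomSpec(n_images=4, positive_fraction=0.1, noise_sd=0.0, seed=5)
    images = generate_phantoms(spec)
    return next(p for p in images if p.label == 0)


@pytest.fixture(scope="session")
def small_cluster_store():
    """Low-dimensional separable clusters for fast retrieval/encoder tests."""
    return generate_feature_clusters(FeatureSimSpec(
        n_samples=400, dim=32, informative_dim=8, separation=6.0,
        positive_fraction=0.15, seed=21))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
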