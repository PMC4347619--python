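import numpy as np
import pytest

from omicstack.synth import SubtypeSpec, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small paired dataset with one strong GEP-only subtype and one split
    subtype; shared across tests that only read it."""
    cfg = SyntheticConfig(
        n_samples=80,
        n_features_gep=60,
        n_features_dmp=60,
        subtypes=[
            SubtypeSpec("gep_sig", 0.25, 10, 0, 3.0, 0.0, "gep_only"),
            SubtypeSpec("split_sig", 0.30, 8, 8, 2.5, 2.5, "split"),
        ],
        seed=3,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_logistic_instance(rng, m, p, sparsity=0.5, scale=1.2):
    """Random design + sparse-truth binary response; regenerates until both
    classes appear."""
    while True:
        X = rng.standard_normal((m, p))
        beta = rng.standard_normal(p) * (rng.random(p) < sparsity) * scale
        eta = np.clip(X @ beta, -30, 30)
        y = (rng.random(m) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        if y.min() != y.max():
            return X, y
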