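import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import twascal as tc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genotypes_1k():
    """Minimal-example genotypes: 1,000 samples x 999 independent SNPs, MAF 0.4."""
    return tc.standardize(tc.simulate_genotypes(1000, 999, maf=0.4, seed=11))


@pytest.fixture(scope="session")
def mediator_1k(genotypes_1k):
    w = tc.simulate_true_weights(999, sparsity=1.0, seed=12, template=genotypes_1k)
    return tc.predict_mediator(genotypes_1k, w)


@pytest.fixture(scope="session")
def genotypes_small():
    return tc.standardize(tc.simulate_genotypes(200, 40, maf=0.3, seed=21))


@pytest.fixture(scope="session")
def mediators_small(genotypes_small):
    sets = [
        tc.simulate_true_weights(
            40, sparsity=0.5, seed=100 + i, template=genotypes_small,
            mediator_id=f"gene_{i:03d}",
        )
        for i in range(8)
    ]
    return [tc.predict_mediator(genotypes_small, w) for w in sets]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
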