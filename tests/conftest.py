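import numpy as np
import pytest

from mhto.core_estimation import GenotypeVector, PhenotypeMatrix, variance_components


def make_dataset(n=200, k=5, seed=0, beta=0.0, maf=0.3, corr=0.3):
    """Small correlated-trait dataset with an optional uniform genotype effect."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(2, maf, n).astype(float)
    shared = rng.standard_normal(n)
    eps = rng.standard_normal((n, k))
    y = beta * x[:, None] + np.sqrt(corr) * shared[:, None] + np.sqrt(1 - corr) * eps
    ids = [f"S{i}" for i in range(n)]
    return (
        PhenotypeMatrix(y, ids, [f"T{j}" for j in range(k)]),
        GenotypeVector(x, ids),
    )


@pytest.fixture
def small_dataset():
    return make_dataset(n=200, k=5, seed=42, beta=0.15)


@pytest.fixture
def small_vc(small_dataset):
    return variance_components(*small_dataset)
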