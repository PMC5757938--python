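import numpy as np
import pytest

from wflm import (
    BasisSpec,
    PhenotypeData,
    RegionGenotypes,
    WeightSpec,
    fit_null,
    simulate_population_genotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_region(rng):
    """Unrelated sample, 40 variants, mixed MAF spectrum."""
    return simulate_population_genotypes(300, 40, seed=rng, min_rare=10)


@pytest.fixture
def small_dataset(small_region, rng):
    """Null-trait phenotype aligned with `small_region`, intercept-only X."""
    y = rng.standard_normal(small_region.n)
    data = PhenotypeData(small_region.ids, y, np.ones((small_region.n, 1)))
    return small_region, data, fit_null(data, None)


def make_dense_region(rng, n, m, low=0.1, high=0.4, region_id="dense"):
    """Small region with common variants only (full-rank G almost surely)."""
    mafs = rng.uniform(low, high, size=m)
    G = rng.binomial(2, mafs, size=(n, m)).astype(float)
    positions = np.sort(rng.choice(10_000, size=m, replace=False))
    return RegionGenotypes.from_dosages(
        np.array([f"s{i}" for i in range(n)]), positions, G, region_id
    )
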